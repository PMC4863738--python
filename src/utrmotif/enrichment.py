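"""Enrichment of motif-bearing transcripts in differential-expression data.

Three statistics, mirroring the analyses run on knockdown RNA-seq of the
motif's trans-acting readers: (i) exact upper-tail hypergeometric overlap
between the motif gene set and the up-regulated set; (ii) one-sided
two-sample Kolmogorov-Smirnov comparisons of log2 fold-change CDFs (motif
genes vs all other expressed genes, or vs genes carrying shuffled versions
of the motif); (iii) the same CDF tests restricted to genes whose motif
instance lies in a positional stratum (terminal / central / proximal /
distal).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import dna_to_rna, expand_iupac, normalize_pattern
from .controls import ShuffleSpec, generate_shuffle_controls
from .errors import ConfigError, DataError
from .io import ExpressionRecord, UtrRecord
from .motifs import DEFAULT_TERMINAL_WINDOW, MotifInstance

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact hypergeometric overlap test between two gene sets."""

    overlap_k: int
    motif_set_K: int
    de_set_n: int
    universe_N: int
    p_value: float
    direction: str


@dataclass(frozen=True)
class CdfComparison:
    """One-sided two-sample KS comparison of fold-change distributions."""

    sample_label: str
    background_label: str
    n_sample: int
    n_background: int
    statistic: float
    p_value: float
    shift_direction: str
    low_power: bool = False
    testable: bool = True


def upper_tail_hypergeom(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ConfigError(f"invalid hypergeometric configuration N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ConfigError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    motif_genes: Iterable[str],
    de_genes: Iterable[str],
    universe_genes: Iterable[str],
    direction: str = "up",
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap of motif genes with a DE set.

    Genes outside the universe are dropped (logged); the universe is all
    expressed genes in the consumed table.
    """
    universe = set(universe_genes)
    if not universe:
        raise DataError("empty gene universe")
    motif = set(motif_genes)
    de = set(de_genes)
    out = (motif - universe) | (de - universe)
    if out:
        log.info("hypergeometric_enrichment: dropped %d gene(s) outside universe", len(out))
    motif &= universe
    de &= universe
    k = len(motif & de)
    p = upper_tail_hypergeom(k, len(universe), len(motif), len(de))
    return EnrichmentResult(
        overlap_k=k,
        motif_set_K=len(motif),
        de_set_n=len(de),
        universe_N=len(universe),
        p_value=p,
        direction=direction,
    )


def cdf_fold_change_comparison(
    sample_fc: Sequence[float],
    background_fc: Sequence[float],
    alternative: str = "greater",
    sample_label: str = "sample",
    background_label: str = "background",
) -> CdfComparison:
    """One-sided two-sample KS test on fold-change distributions.

    ``alternative='greater'`` tests that the sample is shifted toward
    *higher* fold changes (its CDF lies below the background's);
    ``'less'`` tests the opposite shift.  Samples of fewer than three
    values are still tested but flagged low-power.
    """
    if alternative not in ("greater", "less"):
        raise ConfigError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    s = np.asarray(sample_fc, dtype=float)
    b = np.asarray(background_fc, dtype=float)
    if s.size == 0 or b.size == 0:
        return CdfComparison(sample_label, background_label, int(s.size), int(b.size),
                             float("nan"), float("nan"), alternative, testable=False)
    if not (np.isfinite(s).all() and np.isfinite(b).all()):
        raise DataError("non-finite fold changes must be filtered before CDF tests")
    # scipy's 'less' alternative is: CDF(sample) < CDF(background), i.e. the
    # sample is stochastically larger -- our 'greater'.
    scipy_alt = "less" if alternative == "greater" else "greater"
    res = stats.ks_2samp(s, b, alternative=scipy_alt, method="auto")
    return CdfComparison(
        sample_label=sample_label,
        background_label=background_label,
        n_sample=int(s.size),
        n_background=int(b.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shift_direction=alternative,
        low_power=min(s.size, b.size) < 3,
    )


# ---------------------------------------------------------------------------
# gene-set plumbing
# ---------------------------------------------------------------------------

def expressed_universe(expression: Sequence[ExpressionRecord],
                       min_expr: float = 0.0) -> list[str]:
    """Genes considered expressed: finite log2FC and abundance above
    ``min_expr`` in at least one condition (default: any positive signal)."""
    return [
        r.gene_id
        for r in expression
        if np.isfinite(r.log2_fold_change)
        and max(r.mean_expr_control, r.mean_expr_treated) > min_expr
    ]


def genes_with_subsequence(utrs: Sequence[UtrRecord], needle_dna: str) -> set[str]:
    return {u.gene_id for u in utrs if needle_dna in u.sequence}


def genes_with_pattern(utrs: Sequence[UtrRecord], pattern: str) -> set[str]:
    """Genes whose UTR contains >= 1 match of the IUPAC pattern."""
    hits: set[str] = set()
    for exp in expand_iupac(pattern):
        hits |= genes_with_subsequence(utrs, exp)
    return hits


def fold_changes(expression: Sequence[ExpressionRecord],
                 genes: Iterable[str] | None = None) -> np.ndarray:
    gene_set = set(genes) if genes is not None else None
    return np.array(
        [
            r.log2_fold_change
            for r in expression
            if np.isfinite(r.log2_fold_change)
            and (gene_set is None or r.gene_id in gene_set)
        ],
        dtype=float,
    )


def up_genes(expression: Sequence[ExpressionRecord]) -> set[str]:
    return {r.gene_id for r in expression if r.de_class == "up"}


# ---------------------------------------------------------------------------
# shuffled-motif background spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlComparison:
    """Results for one shuffled-control sequence."""

    control: str  # RNA rendering
    n_genes: int
    cdf: CdfComparison
    enrichment: EnrichmentResult


@dataclass(frozen=True)
class SpectrumResult:
    """Motif enrichment/CDF results next to the spectrum of its controls."""

    motif_enrichment: EnrichmentResult
    motif_cdf: CdfComparison
    controls: tuple[ControlComparison, ...]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence": "motif",
                "n_genes": self.motif_enrichment.motif_set_K,
                "enrichment_p": self.motif_enrichment.p_value,
                "overlap_k": self.motif_enrichment.overlap_k,
                "cdf_p": self.motif_cdf.p_value,
                "cdf_D": self.motif_cdf.statistic,
            }
        ]
        for c in self.controls:
            rows.append(
                {
                    "sequence": c.control,
                    "n_genes": c.n_genes,
                    "enrichment_p": c.enrichment.p_value,
                    "overlap_k": c.enrichment.overlap_k,
                    "cdf_p": c.cdf.p_value,
                    "cdf_D": c.cdf.statistic,
                }
            )
        return pd.DataFrame(rows)


def shuffled_motif_background(
    utrs: Sequence[UtrRecord],
    pattern: str,
    spec: ShuffleSpec,
    expression: Sequence[ExpressionRecord],
) -> SpectrumResult:
    """Compare the motif gene set against each shuffled-control gene set.

    For every control sequence (generated per concrete expansion of the
    pattern) the genes carrying it — minus genes that also carry the motif —
    form a background set; the motif set's fold changes are KS-compared
    against it and the control set's own enrichment in up-regulated genes is
    computed, yielding the enrichment spectrum in which a functional motif
    stands out from all of its shuffles.
    """
    pat_dna = normalize_pattern(pattern)
    universe = set(expressed_universe(expression))
    if not universe:
        raise DataError("empty expression universe")
    expr_in = [r for r in expression if r.gene_id in universe]
    motif_genes = genes_with_pattern(utrs, pat_dna) & universe
    up = up_genes(expr_in) & universe
    motif_fc = fold_changes(expr_in, motif_genes)
    rest_fc = fold_changes(expr_in, universe - motif_genes)
    motif_enr = hypergeometric_enrichment(motif_genes, up, universe)
    motif_cdf = cdf_fold_change_comparison(
        motif_fc, rest_fc, "greater", "motif", "all_other_genes"
    )

    controls: list[ControlComparison] = []
    seen: set[str] = set()
    for exp in expand_iupac(pat_dna):
        for ctrl in generate_shuffle_controls(exp, spec, utrs=utrs):
            if ctrl in seen:
                continue
            seen.add(ctrl)
            ctrl_genes = (genes_with_subsequence(utrs, ctrl) & universe) - motif_genes
            if not ctrl_genes:
                log.info("control %s has no host genes; skipped", dna_to_rna(ctrl))
                continue
            cdf = cdf_fold_change_comparison(
                motif_fc,
                fold_changes(expr_in, ctrl_genes),
                "greater",
                "motif",
                dna_to_rna(ctrl),
            )
            enr = hypergeometric_enrichment(ctrl_genes, up, universe)
            controls.append(
                ControlComparison(dna_to_rna(ctrl), len(ctrl_genes), cdf, enr)
            )
    if not controls:
        raise DataError(
            "control set empty after filters; relax the shuffle spec "
            "(abundance_tolerance / exclusion lists)"
        )
    return SpectrumResult(motif_enr, motif_cdf, tuple(controls))


# ---------------------------------------------------------------------------
# position-stratified CDF comparisons
# ---------------------------------------------------------------------------

_STRATA = ("terminal", "central", "proximal", "distal")


def stratum_gene_sets(
    instances: Sequence[MotifInstance],
) -> dict[str, set[str]]:
    """Genes with >= 1 instance in each positional stratum.

    A gene may enter several strata (one instance proximal, another
    central); this is logged.
    """
    sets: dict[str, set[str]] = {s: set() for s in _STRATA}
    for i in instances:
        sets[i.region].add(i.gene_id)
        if i.terminal:
            sets["terminal"].add(i.gene_id)
    multi = (sets["terminal"] & sets["central"])
    if multi:
        log.info("%d gene(s) have instances in both terminal and central strata", len(multi))
    return sets


def position_stratified_cdf(
    instances: Sequence[MotifInstance],
    expression: Sequence[ExpressionRecord],
    stratum: str,
    window: int = DEFAULT_TERMINAL_WINDOW,
) -> CdfComparison:
    """CDF comparison of genes with an instance in ``stratum`` vs the rest.

    ``stratum`` is one of terminal / central / proximal / distal; instances
    must have been scanned with the same ``window``.  An empty stratum
    yields an untestable result.
    """
    if stratum not in _STRATA:
        raise ConfigError(f"stratum must be one of {_STRATA}, got {stratum!r}")
    universe = set(expressed_universe(expression))
    expr_in = [r for r in expression if r.gene_id in universe]
    genes = stratum_gene_sets(instances)[stratum] & universe
    if not genes:
        return CdfComparison(stratum, "all_other_genes", 0, len(universe),
                             float("nan"), float("nan"), "greater", testable=False)
    return cdf_fold_change_comparison(
        fold_changes(expr_in, genes),
        fold_changes(expr_in, universe - genes),
        "greater",
        stratum,
        "all_other_genes",
    )
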