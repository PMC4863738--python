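"""IUPAC motif scanning, co-occurrence, positional profiles and context.

The degenerate element studied here, UAASUUAU (S = C/G), is scanned over
gap-free reference UTRs; every overlapping match is reported.  Positional
analyses use the instance midpoint relative to UTR length, a 300-nt
proximal/distal window by default, and equal-width bins on [0, 1].
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import dna_to_rna, expand_iupac, iupac_regex, normalize_pattern
from .conservation import find_conserved_instances
from .errors import ConfigError, DataError
from .io import UtrAlignment, UtrRecord

log = logging.getLogger(__name__)

DEFAULT_TERMINAL_WINDOW = 300


@dataclass(frozen=True)
class MotifInstance:
    """One match of an IUPAC pattern in one UTR.

    ``start``/``end`` are 0-based half-open on the ungapped reference UTR;
    ``relative_position`` is the match midpoint divided by UTR length;
    ``conserved`` is None when no alignment was available for the UTR.
    ``spans_both_ends`` marks instances that satisfy both the proximal and
    the distal rule (possible only when the UTR is at most twice the window).
    """

    utr_id: str
    gene_id: str
    pattern: str
    matched_seq: str
    start: int
    end: int
    utr_length: int
    relative_position: float
    region: str
    spans_both_ends: bool = False
    conserved: bool | None = None

    @property
    def terminal(self) -> bool:
        return self.region in ("proximal", "distal")


def classify_region(
    start: int, end: int, utr_length: int, window: int = DEFAULT_TERMINAL_WINDOW
) -> tuple[str, bool]:
    """Region of an instance: proximal / central / distal.

    Proximal: starts within the first ``window`` nt.  Distal: ends within
    the last ``window`` nt.  When both apply (short UTRs) the instance is
    classified proximal and flagged.  Returns ``(region, spans_both_ends)``.
    """
    proximal = start < window
    distal = end > utr_length - window
    if proximal and distal:
        return "proximal", True
    if proximal:
        return "proximal", False
    if distal:
        return "distal", False
    return "central", False


def scan_motif(
    utrs: Sequence[UtrRecord],
    pattern: str,
    alignments: Sequence[UtrAlignment] | None = None,
    window: int = DEFAULT_TERMINAL_WINDOW,
) -> list[MotifInstance]:
    """All (possibly overlapping) matches of ``pattern`` across the UTRs.

    Ordering is deterministic: (utr_id, start).  When ``alignments`` are
    given, each instance's ``conserved`` flag is filled by the strict
    column-exact rule on the matched concrete k-mer.
    """
    pat_dna = normalize_pattern(pattern)
    rx = iupac_regex(pattern)
    aln_by_id = {a.utr_id: a for a in alignments} if alignments else {}
    instances: list[MotifInstance] = []
    for u in sorted(utrs, key=lambda r: r.utr_id):
        L = u.length
        conserved_at: dict[int, bool] = {}
        aln = aln_by_id.get(u.utr_id)
        if aln is not None:
            for exp in expand_iupac(pat_dna):
                for call in find_conserved_instances(aln, exp):
                    conserved_at[call.reference_start] = call.conserved
        pos = 0
        while True:
            m = rx.search(u.sequence, pos)
            if m is None:
                break
            start = m.start()
            pos = start + 1  # overlapping matches
            end = start + len(pat_dna)
            region, both = classify_region(start, end, L, window)
            instances.append(
                MotifInstance(
                    utr_id=u.utr_id,
                    gene_id=u.gene_id,
                    pattern=pattern,
                    matched_seq=u.sequence[start:end],
                    start=start,
                    end=end,
                    utr_length=L,
                    relative_position=(start + len(pat_dna) / 2) / L,
                    region=region,
                    spans_both_ends=both,
                    conserved=conserved_at.get(start) if aln is not None else None,
                )
            )
    return instances


def instances_frame(instances: Iterable[MotifInstance]) -> pd.DataFrame:
    """Tabular view of motif instances (sequences rendered in RNA)."""
    rows = [
        {
            "utr_id": i.utr_id,
            "gene_id": i.gene_id,
            "pattern": dna_to_rna(i.pattern),
            "matched_seq": dna_to_rna(i.matched_seq),
            "start": i.start,
            "end": i.end,
            "utr_length": i.utr_length,
            "relative_position": i.relative_position,
            "region": i.region,
            "spans_both_ends": i.spans_both_ends,
            "conserved": i.conserved,
        }
        for i in instances
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multi-copy and co-occurrence statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiCopyStats:
    """Single- vs multi-copy UTR counts for one motif.

    ``median_spacing`` is the median start-to-start distance between
    adjacent instances within multi-copy UTRs (NaN when there are none).
    """

    n_single: int
    n_multi: int
    fraction_multi: float
    median_spacing: float


def multi_copy_stats(instances: Sequence[MotifInstance]) -> MultiCopyStats:
    starts: dict[str, set[int]] = {}
    for i in instances:
        starts.setdefault(i.utr_id, set()).add(i.start)
    n_single = sum(1 for s in starts.values() if len(s) == 1)
    n_multi = sum(1 for s in starts.values() if len(s) >= 2)
    spacings: list[int] = []
    for s in starts.values():
        if len(s) >= 2:
            ordered = sorted(s)
            spacings.extend(b - a for a, b in zip(ordered, ordered[1:]))
    total = n_single + n_multi
    return MultiCopyStats(
        n_single=n_single,
        n_multi=n_multi,
        fraction_multi=(n_multi / total) if total else float("nan"),
        median_spacing=float(np.median(spacings)) if spacings else float("nan"),
    )


def multi_copy_fraction(n_single: int, n_multi: int) -> float:
    """Fraction of motif-containing UTRs that carry multiple copies."""
    return n_multi / (n_single + n_multi)


def cooccurrence_hypergeometric(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
):
    """Upper-tail hypergeometric P(X >= |A ∩ B|) for two UTR sets.

    Used e.g. for whether UTRs carrying one motif variant carry the other
    more often than chance.  Returns an :class:`~utrmotif.enrichment.EnrichmentResult`.
    """
    from .enrichment import EnrichmentResult, upper_tail_hypergeom

    a, b = set(set_a), set(set_b)
    if max(len(a), len(b)) > universe_size:
        raise ConfigError("set larger than universe")
    k = len(a & b)
    p = upper_tail_hypergeom(k, universe_size, len(a), len(b))
    return EnrichmentResult(
        overlap_k=k, motif_set_K=len(a), de_set_n=len(b),
        universe_N=universe_size, p_value=p, direction="overlap",
    )


# ---------------------------------------------------------------------------
# positional profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionalProfile:
    """Binned counts of total and conserved instances over relative position.

    ``uniform_total``/``uniform_conserved`` are the per-bin expectations if
    occurrence were uniformly distributed (total / n_bins).
    """

    n_bins: int
    bin_edges: np.ndarray
    total_counts: np.ndarray
    conserved_counts: np.ndarray
    uniform_total: float
    uniform_conserved: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "total_count": self.total_counts,
                "conserved_count": self.conserved_counts,
                "uniform_total": self.uniform_total,
                "uniform_conserved": self.uniform_conserved,
            }
        )


def positional_profile(
    instances: Sequence[MotifInstance], n_bins: int = 20
) -> PositionalProfile:
    """Equal-width bins of relative positions on [0, 1] (last bin closed)."""
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    rel = np.array([i.relative_position for i in instances], dtype=float)
    if rel.size and (rel.min() < 0 or rel.max() > 1):
        raise DataError("relative position outside [0, 1]; UTR length mismatch?")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    total, _ = np.histogram(rel, bins=edges)
    cons_rel = np.array(
        [i.relative_position for i in instances if i.conserved], dtype=float
    )
    conserved, _ = np.histogram(cons_rel, bins=edges)
    return PositionalProfile(
        n_bins=n_bins,
        bin_edges=edges,
        total_counts=total,
        conserved_counts=conserved,
        uniform_total=float(rel.size) / n_bins,
        uniform_conserved=float(cons_rel.size) / n_bins,
    )


# ---------------------------------------------------------------------------
# sequence context (web-logo input)
# ---------------------------------------------------------------------------

def context_matrix(
    instances: Sequence[MotifInstance],
    utrs: Sequence[UtrRecord],
    flank: int = 10,
) -> pd.DataFrame:
    """Position-frequency matrix of instances with ``flank`` nt on each side.

    Rows A/C/G/U; one column per position, frequencies summing to 1.
    Instances whose flanks would be clipped at a UTR boundary are dropped
    (logged).  Raises :class:`DataError` when no usable instance remains.
    """
    if flank < 0:
        raise ConfigError("flank must be >= 0")
    seq_by_id = {u.utr_id: u.sequence for u in utrs}
    windows: list[str] = []
    dropped = 0
    for inst in instances:
        seq = seq_by_id.get(inst.utr_id)
        if seq is None:
            raise DataError(f"instance references unknown UTR {inst.utr_id!r}")
        lo, hi = inst.start - flank, inst.end + flank
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        windows.append(seq[lo:hi])
    if dropped:
        log.info("context_matrix: dropped %d boundary-clipped instance(s)", dropped)
    if not windows:
        raise DataError("no usable instances for the context matrix")
    width = len(windows[0])
    counts = np.zeros((4, width), dtype=float)
    index = {b: i for i, b in enumerate("ACGT")}
    for w in windows:
        for j, c in enumerate(w):
            if c in index:
                counts[index[c], j] += 1
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    freqs = counts / colsum
    positions = list(range(-flank, width - flank))
    return pd.DataFrame(freqs, index=list("ACGU"), columns=positions)


# ---------------------------------------------------------------------------
# conservation-position bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionBiasResult:
    """Two-proportion comparison of conservation in terminal vs central instances."""

    n_terminal: int
    n_central: int
    conserved_terminal: int
    conserved_central: int
    fraction_terminal: float
    fraction_central: float
    z: float
    p_value: float
    testable: bool


def conservation_position_bias(
    instances: Sequence[MotifInstance], window: int = DEFAULT_TERMINAL_WINDOW
) -> PositionBiasResult:
    """One-sided pooled two-proportion z test: terminal instances are more
    often conserved than central ones.

    Instances must carry conservation flags; flags of ``None`` are skipped.
    A stratum with zero instances makes the result untestable.
    """
    term = [i for i in instances if i.conserved is not None and i.terminal]
    cent = [i for i in instances if i.conserved is not None and not i.terminal]
    n_t, n_c = len(term), len(cent)
    k_t = sum(1 for i in term if i.conserved)
    k_c = sum(1 for i in cent if i.conserved)
    if n_t == 0 or n_c == 0:
        return PositionBiasResult(
            n_t, n_c, k_t, k_c, float("nan"), float("nan"),
            float("nan"), float("nan"), testable=False,
        )
    f_t, f_c = k_t / n_t, k_c / n_c
    pooled = (k_t + k_c) / (n_t + n_c)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n_t + 1 / n_c))
    if se == 0:
        z = 0.0
    else:
        z = (f_t - f_c) / se
    p = float(norm.sf(z))
    return PositionBiasResult(n_t, n_c, k_t, k_c, f_t, f_c, z, p, testable=True)
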