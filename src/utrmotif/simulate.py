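"""Synthetic aligned 3' UTR sets with planted motifs and matched expression.

The generator emulates the inputs of the real analysis — four-species 3' UTR
alignments and a CuffDiff-style knockdown expression table — with a complete
ground-truth ledger, so that every pipeline stage is testable without
external annotation downloads.

Model, per gene: a reference UTR of log-normal length (mean ~1700 nt, the
typical mammalian 3' UTR length) is drawn from the background composition;
orthologous rows diverge from it by i.i.d. per-column substitutions and
geometric-length indels (indels live only in non-reference rows so
reference coordinates stay exact).  A fraction of genes receives one (or,
with some probability, two) planted motif instances, overwritten into every
species and then independently "broken" by a single random substitution
with probability 1 - retention_prob per non-reference species; an instance
is truly conserved when every species retained it.  Expression: control
abundances are log-normal; the treated condition shifts motif-bearing genes
by ``effect_log2fc`` (optionally only genes whose planted instance is
terminal); per-condition replicates receive measurement noise, p-values
come from a per-gene test with pooled dispersion, and q-values from
Benjamini-Hochberg.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .alphabet import decode_digits, encode_sequence, expand_iupac, normalize_pattern
from .errors import ConfigError
from .io import ExpressionRecord, UtrAlignment, UtrRecord, classify_de

_GAP = ord("-")
_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic data set.

    Lengths are log-normal with arithmetic mean ``utr_length_mean``;
    ``per_species_substitution_rate`` and ``indel_rate`` are per-column
    probabilities applied independently to each non-reference species;
    ``retention_prob`` is the per-species probability that a planted
    instance survives intact.  ``noise_sd`` adds per-gene biological
    heterogeneity to the treated/control log2 ratio (0 keeps the null
    exactly calibrated); ``replicate_sd`` is per-replicate measurement
    noise on the log2 scale.
    """

    n_genes: int = 2000
    utr_length_mean: float = 1700.0
    utr_length_sigma: float = 0.75
    min_length: int = 100
    background_composition: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    species: tuple[str, ...] = ("human", "mouse", "rat", "dog")
    per_species_substitution_rate: float = 0.3
    indel_rate: float = 0.01
    planted_pattern: str = "UAASUUAU"
    plant_fraction: float = 0.1
    multi_copy_prob: float = 0.1
    retention_prob: float = 0.9
    positional_bias: str = "uniform"  # or "terminal"
    bias_window: int = 300
    effect_log2fc: float = 0.5
    effect_scope: str = "all"  # or "terminal"
    noise_sd: float = 0.0
    replicate_sd: float = 0.15
    n_replicates: int = 2
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 2.0
    q_threshold: float = 0.05
    q_model: str = "pooled_z"  # or "welch_t"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ConfigError("background_composition must sum to 1")
        for name in ("plant_fraction", "multi_copy_prob", "retention_prob",
                     "per_species_substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.indel_rate < 0:
            raise ConfigError("indel_rate must be >= 0")
        if self.positional_bias not in ("uniform", "terminal"):
            raise ConfigError(f"unknown positional_bias {self.positional_bias!r}")
        if self.effect_scope not in ("all", "terminal"):
            raise ConfigError(f"unknown effect_scope {self.effect_scope!r}")
        if self.q_model not in ("pooled_z", "welch_t"):
            raise ConfigError(f"unknown q_model {self.q_model!r}")
        if len(self.species) < 2:
            raise ConfigError("need at least two species")
        normalize_pattern(self.planted_pattern)


@dataclass
class PlantedInstance:
    """Ground truth for one planted motif instance."""

    start: int
    variant: str  # concrete DNA k-mer written into the reference
    retained: dict[str, bool] | None = None  # per non-reference species
    conserved: bool | None = None


@dataclass
class GeneTruth:
    gene_id: str
    utr_id: str
    length: int
    planted: bool
    instances: list[PlantedInstance] = field(default_factory=list)
    chance_starts: list[int] = field(default_factory=list)
    true_log2fc: float = float("nan")

    def has_terminal_instance(self, window: int) -> bool:
        return any(
            inst.start < window or inst.start + len(inst.variant) > self.length - window
            for inst in self.instances
        )


@dataclass
class SyntheticTruth:
    """Complete ground-truth ledger for a generated data set."""

    config: SyntheticConfig
    genes: list[GeneTruth]

    def planted_gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.planted}

    def motif_gene_ids(self, include_chance: bool = True) -> set[str]:
        """Genes whose UTR carries the pattern (planted and/or by chance)."""
        out = set()
        for g in self.genes:
            if g.planted or (include_chance and g.chance_starts):
                out.add(g.gene_id)
        return out

    def terminal_planted_gene_ids(self, window: int | None = None) -> set[str]:
        w = self.config.bias_window if window is None else window
        return {g.gene_id for g in self.genes if g.planted and g.has_terminal_instance(w)}

    def frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "utr_id": g.utr_id,
                    "length": g.length,
                    "planted": g.planted,
                    "instance_starts": ";".join(str(i.start) for i in g.instances),
                    "instance_variants": ";".join(i.variant for i in g.instances),
                    "instance_conserved": ";".join(
                        "NA" if i.conserved is None else str(i.conserved)
                        for i in g.instances
                    ),
                    "chance_starts": ";".join(str(s) for s in g.chance_starts),
                    "true_log2fc": g.true_log2fc,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UTR + alignment generation
# ---------------------------------------------------------------------------

def _draw_lengths(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    sigma = cfg.utr_length_sigma
    mu = math.log(cfg.utr_length_mean) - sigma * sigma / 2.0
    lengths = rng.lognormal(mu, sigma, cfg.n_genes)
    floor = max(cfg.min_length, 4 * len(normalize_pattern(cfg.planted_pattern)))
    for _ in range(100):
        short = lengths < floor
        if not short.any():
            break
        lengths[short] = rng.lognormal(mu, sigma, int(short.sum()))
    lengths = np.maximum(lengths, floor)
    return lengths.astype(np.int64)


def _draw_sequence(rng: np.random.Generator, length: int, comp: np.ndarray) -> np.ndarray:
    cum = np.cumsum(comp)
    return np.searchsorted(cum, rng.random(length), side="right").astype(np.uint8)


def _plant_positions(
    rng: np.random.Generator, length: int, k: int, n_inst: int, cfg: SyntheticConfig
) -> list[int]:
    w = cfg.bias_window

    def draw_one() -> int:
        if cfg.positional_bias == "terminal" and length > k:
            lo_hi = min(w, length) - k
            if rng.random() < 0.5 or length <= w:
                return int(rng.integers(0, max(lo_hi, 0) + 1))
            return int(rng.integers(max(length - w, 0), length - k + 1))
        return int(rng.integers(0, length - k + 1))

    positions: list[int] = []
    for _ in range(n_inst):
        for _attempt in range(50):
            p = draw_one()
            if all(abs(p - q) >= k for q in positions):
                positions.append(p)
                break
        # instance dropped if no non-overlapping slot was found
    return sorted(positions)


def _assemble_rows(
    base_rows: dict[str, np.ndarray],
    insertions: list[tuple[int, str, str]],
    order: Sequence[str],
) -> dict[str, str]:
    """Interleave species-private insertion columns into per-species rows.

    ``base_rows`` maps species -> uint8 char array over reference positions
    (gap bytes where the species deleted).  ``insertions`` is a list of
    (reference position, species, inserted string); every other row gets a
    gap run at those columns.
    """
    texts = {sp: arr.tobytes().decode("ascii") for sp, arr in base_rows.items()}
    if not insertions:
        return texts
    events = sorted(insertions, key=lambda e: (e[0], order.index(e[1])))
    parts: dict[str, list[str]] = {sp: [] for sp in order}
    prev = 0
    for pos, owner, content in events:
        for sp in order:
            parts[sp].append(texts[sp][prev:pos])
            parts[sp].append(content if sp == owner else "-" * len(content))
        prev = pos
    for sp in order:
        parts[sp].append(texts[sp][prev:])
    return {sp: "".join(parts[sp]) for sp in order}


def generate_utr_set(
    config: SyntheticConfig, with_alignments: bool = True
) -> tuple[list[UtrRecord], list[UtrAlignment], SyntheticTruth]:
    """Generate reference UTRs, orthologous alignments and the truth ledger.

    Randomness is split into independent streams keyed on the seed, so the
    reference sequences (and hence the truth) are identical whether or not
    alignments are generated.  With ``with_alignments=False`` the alignment
    list is empty and per-species retention outcomes are left undetermined.
    """
    cfg = config
    k = len(normalize_pattern(cfg.planted_pattern))
    expansions = [encode_sequence(e) for e in expand_iupac(cfg.planted_pattern)]
    expansion_strs = expand_iupac(cfg.planted_pattern)
    comp = np.asarray(cfg.background_composition, dtype=float)
    ref_sp = cfg.species[0]
    others = list(cfg.species[1:])

    rng_ref = np.random.default_rng([cfg.seed, 0])
    lengths = _draw_lengths(rng_ref, cfg)
    planted_mask = rng_ref.random(cfg.n_genes) < cfg.plant_fraction
    second_copy = rng_ref.random(cfg.n_genes) < cfg.multi_copy_prob

    utrs: list[UtrRecord] = []
    alignments: list[UtrAlignment] = []
    genes: list[GeneTruth] = []

    for i in range(cfg.n_genes):
        L = int(lengths[i])
        gene_id = f"G{i:05d}"
        utr_id = f"U{i:05d}"
        ref = _draw_sequence(rng_ref, L, comp)

        truth = GeneTruth(gene_id, utr_id, L, bool(planted_mask[i]))
        if truth.planted:
            n_inst = 1 + int(second_copy[i])
            positions = _plant_positions(rng_ref, L, k, n_inst, cfg)
            for p in positions:
                v = int(rng_ref.integers(0, len(expansions)))
                ref[p : p + k] = expansions[v]
                truth.instances.append(PlantedInstance(start=p, variant=expansion_strs[v]))
        seq = decode_digits(ref)
        planted_starts = {inst.start for inst in truth.instances}
        for exp in expansion_strs:
            start = 0
            while True:
                j = seq.find(exp, start)
                if j < 0:
                    break
                start = j + 1
                if j not in planted_starts:
                    truth.chance_starts.append(j)
        truth.chance_starts.sort()
        utrs.append(UtrRecord(utr_id, gene_id, seq))

        if with_alignments:
            alignments.append(
                _diverge_gene(cfg, i, ref, truth, ref_sp, others, utr_id, seq, k)
            )
        genes.append(truth)

    return utrs, alignments, SyntheticTruth(cfg, genes)


def _diverge_gene(
    cfg: SyntheticConfig,
    i: int,
    ref: np.ndarray,
    truth: GeneTruth,
    ref_sp: str,
    others: list[str],
    utr_id: str,
    seq: str,
    k: int,
) -> UtrAlignment:
    L = len(ref)
    protected = np.zeros(L, dtype=bool)
    for inst in truth.instances:
        protected[inst.start : inst.start + k] = True

    rng_div = np.random.default_rng([cfg.seed, 1, i])
    rng_break = np.random.default_rng([cfg.seed, 1, i, 9])

    base_rows: dict[str, np.ndarray] = {ref_sp: _CHAR[ref].copy()}
    insertions: list[tuple[int, str, str]] = []
    retained_by_species: dict[str, list[bool]] = {}

    for j, sp in enumerate(others):
        u_sub = rng_div.random(L)
        shifts = rng_div.integers(1, 4, L).astype(np.uint8)
        u_del = rng_div.random(L)
        del_len = rng_div.geometric(0.5, L)
        u_ins = rng_div.random(L)
        ins_len = rng_div.geometric(0.5, L)

        digits = ref.copy()
        sub_mask = (u_sub < cfg.per_species_substitution_rate) & ~protected
        digits[sub_mask] = (ref[sub_mask] + shifts[sub_mask]) % 4

        gap_mask = np.zeros(L, dtype=bool)
        half = cfg.indel_rate / 2.0
        for s in np.flatnonzero((u_del < half) & ~protected):
            span = slice(int(s), min(int(s) + int(del_len[s]), L))
            gap_mask[span] |= ~protected[span]

        rng_ins = np.random.default_rng([cfg.seed, 1, i, j, 7])
        for p in np.flatnonzero((u_ins < half) & ~protected):
            content = decode_digits(rng_ins.integers(0, 4, int(ins_len[p])).astype(np.uint8))
            insertions.append((int(p), sp, content))

        row = _CHAR[digits].copy()
        row[gap_mask] = _GAP
        base_rows[sp] = row
        retained_by_species[sp] = []

    # break planted instances per species with prob 1 - retention_prob
    for inst in truth.instances:
        retained_all = True
        retained: dict[str, bool] = {}
        for sp in others:
            u = float(rng_break.random())
            pos = int(rng_break.integers(0, k))
            shift = int(rng_break.integers(1, 4))
            keep = u < cfg.retention_prob
            retained[sp] = keep
            retained_all &= keep
            if not keep:
                broken = (int(ref[inst.start + pos]) + shift) % 4
                base_rows[sp][inst.start + pos] = _CHAR[broken]
        inst.retained = retained
        inst.conserved = retained_all

    order = [ref_sp] + others
    rows = _assemble_rows(base_rows, insertions, order)
    assert rows[ref_sp].replace("-", "") == seq
    return UtrAlignment(utr_id, rows, ref_sp)


# ---------------------------------------------------------------------------
# expression table generation
# ---------------------------------------------------------------------------

def generate_expression_table(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> list[ExpressionRecord]:
    """CuffDiff-style expression records matched to a truth ledger.

    Control abundances are log-normal; treated abundances shift planted
    genes (all of them, or only those with a terminal instance, per
    ``effect_scope``) by ``effect_log2fc`` plus per-gene noise.  P-values
    come from per-gene two-sample tests on ``n_replicates`` simulated
    replicates per condition — by default a z test whose dispersion is
    pooled across all genes, in the spirit of DE callers that share
    dispersion information at low replicate number — and q-values from
    Benjamini-Hochberg.  Fills ``true_log2fc`` in the truth ledger.
    """
    cfg = config or truth.config
    n = len(truth.genes)
    rng = np.random.default_rng([cfg.seed, 2])

    base = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, n)
    eps = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)

    in_scope = np.zeros(n, dtype=bool)
    for idx, g in enumerate(truth.genes):
        if not g.planted:
            continue
        if cfg.effect_scope == "all" or g.has_terminal_instance(cfg.bias_window):
            in_scope[idx] = True
    delta = cfg.effect_log2fc * in_scope + eps

    m = cfg.n_replicates
    reps_c = base[:, None] + rng.normal(0.0, cfg.replicate_sd, (n, m))
    reps_t = (base + delta)[:, None] + rng.normal(0.0, cfg.replicate_sd, (n, m))

    value_1 = np.power(2.0, reps_c).mean(axis=1)
    value_2 = np.power(2.0, reps_t).mean(axis=1)
    lfc = np.log2(value_2 / value_1)

    d = reps_t.mean(axis=1) - reps_c.mean(axis=1)
    if cfg.q_model == "pooled_z":
        var_c = reps_c.var(axis=1, ddof=1)
        var_t = reps_t.var(axis=1, ddof=1)
        pooled = float(np.mean((var_c + var_t) / 2.0))
        se = math.sqrt(pooled * 2.0 / m)
        z = d / se
        p = 2.0 * sps.norm.sf(np.abs(z))
    else:
        res = sps.ttest_ind(reps_t, reps_c, axis=1, equal_var=False)
        p = np.nan_to_num(res.pvalue, nan=1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    records: list[ExpressionRecord] = []
    for idx, g in enumerate(truth.genes):
        g.true_log2fc = float(delta[idx])
        records.append(
            ExpressionRecord(
                gene_id=g.gene_id,
                mean_expr_control=float(value_1[idx]),
                mean_expr_treated=float(value_2[idx]),
                log2_fold_change=float(lfc[idx]),
                p_value=float(p[idx]),
                q_value=float(q[idx]),
                de_class=classify_de(float(lfc[idx]), float(q[idx]), cfg.q_threshold),
            )
        )
    return records


# ---------------------------------------------------------------------------
# frozen fixture profiles
# ---------------------------------------------------------------------------

#: Versioned study-condition profiles.  ``default`` reflects the documented
#: conditions of the recovery analyses; the others vary one aspect at a time.
PROFILES: dict[str, dict] = {
    "default": {},
    "null-expression": {"effect_log2fc": 0.0},
    "terminal-effect": {"effect_scope": "terminal"},
    "terminal-bias": {"positional_bias": "terminal"},
    "neutral-conservation": {
        "n_genes": 200,
        "plant_fraction": 0.0,
        "multi_copy_prob": 0.0,
        "per_species_substitution_rate": 0.02,
        "indel_rate": 0.002,
        "effect_log2fc": 0.0,
        # uniform composition: the null-median diagnostic averages over all
        # 4^k k-mers and wants them exchangeable
        "background_composition": (0.25, 0.25, 0.25, 0.25),
    },
    "tiny": {
        "n_genes": 40,
        "utr_length_mean": 400.0,
        "utr_length_sigma": 0.4,
        "per_species_substitution_rate": 0.1,
    },
}


def profile(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """A frozen fixture profile by name, with optional field overrides."""
    if name not in PROFILES:
        raise ConfigError(f"unknown profile {name!r}; available: {sorted(PROFILES)}")
    params = dict(PROFILES[name])
    params.update(overrides)
    return replace(SyntheticConfig(seed=seed), **params)


def config_frame(cfg: SyntheticConfig) -> pd.DataFrame:
    d = asdict(cfg)
    return pd.DataFrame({"parameter": list(d), "value": [repr(v) for v in d.values()]})
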