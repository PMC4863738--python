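"""Conserved k-mer counting and the normalized conservation signal.

An instance of a k-mer in the reference UTR is *conserved* when, over the k
alignment columns its nucleotides occupy, every non-reference species row is
gap-free and spells the same k-mer (strict, column-exact reading).  A
relaxed mode instead asks whether the k-mer occurs anywhere in the
orthologous row within a window of alignment columns around the instance.

The ranking statistic for a k-mer is its count of UTRs with at least one
conserved instance, divided by the mean of the same count over its shuffled
controls (see :mod:`utrmotif.controls`).  A k-mer under selection retains
conserved instances in excess of its composition/abundance-matched nulls,
pushing the signal above 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    code_to_kmer,
    dna_to_rna,
    encode_sequence,
    kmer_to_code,
    rna_to_dna,
    rolling_kmer_codes,
)
from .controls import ControlFactory, ShuffleSpec
from .errors import ConfigError, DataError
from .io import UtrAlignment, UtrRecord

log = logging.getLogger(__name__)


@dataclass
class KmerConservationStat:
    """Per-k-mer conservation record (k-mer held in DNA internally)."""

    kmer: str
    utr_count: int
    conserved_utr_count: int
    conserved_instance_count: int
    shuffle_kmers: list[str] = field(default_factory=list)
    shuffle_conserved_mean: float = float("nan")
    signal: float = float("nan")
    flags: str = ""


@dataclass(frozen=True)
class ConservedCall:
    """One occurrence of a k-mer in a reference UTR with its conservation flag."""

    reference_start: int
    conserved: bool


def count_utrs_with_kmer(utrs: Sequence[UtrRecord], kmer: str, k: int = 8) -> int:
    """Number of distinct UTRs containing >= 1 exact occurrence of ``kmer``.

    Overlapping occurrences within a UTR still count that UTR once.
    """
    kmer = rna_to_dna(kmer)
    if len(kmer) != k:
        raise ConfigError(f"k-mer {kmer!r} has length {len(kmer)}, expected {k}")
    if set(kmer) - set("ACGT"):
        raise ConfigError(f"k-mer {kmer!r} must be concrete (A/C/G/T only)")
    return sum(1 for u in utrs if kmer in u.sequence)


def _reference_column_map(alignment: UtrAlignment) -> np.ndarray:
    """Alignment column index of each ungapped reference position."""
    row = np.frombuffer(alignment.reference_row.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero(row != ord("-"))


def find_conserved_instances(
    alignment: UtrAlignment, kmer: str, window: int = 0
) -> list[ConservedCall]:
    """All occurrences of ``kmer`` in the ungapped reference with flags.

    ``window=0`` is the strict column-exact rule.  With ``window=w > 0`` an
    occurrence is conserved in a species when the k-mer occurs anywhere in
    that species' gap-stripped sequence over the alignment columns of the
    instance widened by ``w`` columns on each side.
    """
    kmer = rna_to_dna(kmer)
    if set(kmer) - set("ACGT"):
        raise ConfigError(f"k-mer {kmer!r} must be concrete (A/C/G/T only)")
    k = len(kmer)
    ref = alignment.reference_ungapped
    colmap = _reference_column_map(alignment)
    others = [sp for sp in alignment.species_rows if sp != alignment.reference_species]
    calls: list[ConservedCall] = []
    start = 0
    while True:
        i = ref.find(kmer, start)
        if i < 0:
            break
        start = i + 1
        cols = colmap[i : i + k]
        conserved = True
        for sp in others:
            row = alignment.species_rows[sp]
            if window == 0:
                sub = "".join(row[c] for c in cols)
                if sub != kmer:  # any gap or mismatch (incl. N) breaks it
                    conserved = False
                    break
            else:
                lo = max(0, int(cols[0]) - window)
                hi = min(alignment.n_columns, int(cols[-1]) + 1 + window)
                if kmer not in row[lo:hi].replace("-", ""):
                    conserved = False
                    break
        calls.append(ConservedCall(i, conserved))
    return calls


# ---------------------------------------------------------------------------
# vectorized dataset-wide tallies
# ---------------------------------------------------------------------------

def kmer_utr_counts(utrs: Sequence[UtrRecord], k: int = 8) -> np.ndarray:
    """Array of length ``4**k``: number of UTRs containing each k-mer."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    for u in utrs:
        codes, valid = rolling_kmer_codes(encode_sequence(u.sequence), k)
        if len(codes):
            counts[np.unique(codes[valid])] += 1
    return counts


def _alignment_match_profile(alignment: UtrAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per ungapped-reference-position digits and all-species match flags.

    ``ok[i]`` is True when every non-reference row, at the alignment column
    of reference position ``i``, is gap-free and identical to the reference
    nucleotide (which must itself be A/C/G/T).
    """
    ref_row = np.frombuffer(alignment.reference_row.encode("ascii"), dtype=np.uint8)
    refmask = ref_row != ord("-")
    ref = ref_row[refmask]
    digits = encode_sequence(alignment.reference_ungapped)
    ok = digits <= 3
    for sp, row in alignment.species_rows.items():
        if sp == alignment.reference_species:
            continue
        r = np.frombuffer(row.encode("ascii"), dtype=np.uint8)[refmask]
        ok &= r == ref
    return digits, ok


def conserved_kmer_tallies(
    alignments: Sequence[UtrAlignment], k: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Dataset-wide conserved counts per k-mer code (strict rule).

    Returns ``(conserved_utr_count, conserved_instance_count)``, each of
    length ``4**k``.
    """
    utr_counts = np.zeros(4 ** k, dtype=np.int64)
    inst_counts = np.zeros(4 ** k, dtype=np.int64)
    for aln in alignments:
        digits, ok = _alignment_match_profile(aln)
        n = len(digits) - k + 1
        if n <= 0:
            continue
        codes, valid = rolling_kmer_codes(digits, k)
        cok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        conserved_win = (cok[k:] - cok[:-k]) == k
        sel = valid & conserved_win
        if sel.any():
            hit = codes[sel]
            np.add.at(inst_counts, hit, 1)
            utr_counts[np.unique(hit)] += 1
    return utr_counts, inst_counts


# ---------------------------------------------------------------------------
# signal and ranking
# ---------------------------------------------------------------------------

#: Floor for the control-mean denominator of the signal.  Control means
#: below one conserved UTR are too noisy to support a fold estimate: at
#: high divergence most control counts are 0 and a raw (or 1/n-pseudocount)
#: denominator would rank sparsely conserved k-mers above genuinely
#: conserved ones.  Floored k-mers effectively rank by their own conserved
#: count and are flagged ``unstable``.
SIGNAL_DENOMINATOR_FLOOR = 1.0


def conservation_signal(
    conserved_utr_count: int,
    control_conserved_counts: Sequence[float],
) -> tuple[float, str]:
    """Normalized signal = conserved count / mean control conserved count.

    The denominator is floored at one conserved UTR
    (:data:`SIGNAL_DENOMINATOR_FLOOR`); when the floor binds the result is
    flagged ``unstable`` — its ranking is meaningful, its magnitude is not.
    """
    controls = np.asarray(list(control_conserved_counts), dtype=float)
    if controls.size == 0:
        raise DataError("empty control set")
    mean = float(controls.mean())
    if mean >= SIGNAL_DENOMINATOR_FLOOR:
        return conserved_utr_count / mean, ""
    return conserved_utr_count / SIGNAL_DENOMINATOR_FLOOR, "unstable"


def rank_kmers(
    utrs: Sequence[UtrRecord],
    alignments: Sequence[UtrAlignment],
    spec: ShuffleSpec | None = None,
    k: int = 8,
    keep_stats: bool = False,
) -> pd.DataFrame:
    """Rank every k-mer occurring in the data by its conservation signal.

    One row per k-mer present in >= 1 UTR, sorted by descending signal
    (ties broken by k-mer, undefined signals last).  Exclusion lists apply
    to controls only; the scan itself covers every k-mer in the data.
    The ``kmer`` and ``controls`` columns are rendered in RNA.
    """
    spec = spec or ShuffleSpec()
    uc = kmer_utr_counts(utrs, k)
    cons_u, cons_i = conserved_kmer_tallies(alignments, k)
    present = np.flatnonzero(uc)
    factory = ControlFactory(spec, k=k, utr_count=uc)

    rows: list[dict] = []
    for code in present:
        code = int(code)
        cand = factory.candidate_codes(code)
        flags: list[str] = []
        if len(cand) == 0:
            chosen = np.empty(0, dtype=np.int64)
            mean = float("nan")
            signal = float("nan")
            flags.append("no_controls")
        else:
            if len(cand) <= spec.n_controls:
                chosen = cand
                if len(cand) < spec.n_controls:
                    flags.append("fewer_controls")
            else:
                rng = np.random.default_rng([spec.seed, code])
                chosen = rng.choice(cand, size=spec.n_controls, replace=False)
            signal, sig_flag = conservation_signal(int(cons_u[code]), cons_u[chosen])
            mean = float(cons_u[chosen].mean())
            if sig_flag:
                flags.append(sig_flag)
        rows.append(
            {
                "kmer": dna_to_rna(code_to_kmer(code, k)),
                "utr_count": int(uc[code]),
                "conserved_utr_count": int(cons_u[code]),
                "conserved_instance_count": int(cons_i[code]),
                "n_controls": int(len(chosen)),
                "shuffle_mean": mean,
                "signal": signal,
                "flags": ",".join(flags),
                **(
                    {"controls": ",".join(dna_to_rna(code_to_kmer(int(c), k)) for c in chosen)}
                    if keep_stats
                    else {}
                ),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["kmer", "utr_count", "conserved_utr_count", "conserved_instance_count",
                "n_controls", "shuffle_mean", "signal", "flags"]
        return pd.DataFrame(columns=cols)
    df = df.sort_values(
        ["signal", "kmer"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def stat_for_kmer(
    kmer: str,
    utrs: Sequence[UtrRecord],
    alignments: Sequence[UtrAlignment],
    spec: ShuffleSpec | None = None,
) -> KmerConservationStat:
    """Full :class:`KmerConservationStat` for a single concrete k-mer."""
    spec = spec or ShuffleSpec()
    kmer = rna_to_dna(kmer)
    k = len(kmer)
    uc = kmer_utr_counts(utrs, k)
    cons_u, cons_i = conserved_kmer_tallies(alignments, k)
    code = kmer_to_code(kmer)
    factory = ControlFactory(spec, k=k, utr_count=uc)
    chosen = factory.controls_for(code)
    signal, flag = conservation_signal(int(cons_u[code]), cons_u[chosen])
    return KmerConservationStat(
        kmer=kmer,
        utr_count=int(uc[code]),
        conserved_utr_count=int(cons_u[code]),
        conserved_instance_count=int(cons_i[code]),
        shuffle_kmers=[code_to_kmer(int(c), k) for c in chosen],
        shuffle_conserved_mean=float(cons_u[chosen].mean()),
        signal=signal,
        flags=flag,
    )
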