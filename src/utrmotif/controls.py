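"""Shuffled-control k-mers matched on composition, UGUA content and abundance.

For every source k-mer the null for its conservation count is a set of
control k-mers that (i) preserve its mononucleotide composition (anagrams)
or its exact dinucleotide multiset, (ii) carry the same number of
(overlapping) UGUA substrings — UGUA being the core of the pumilio
recognition element, whose strong conservation would otherwise contaminate
the null, (iii) contain no 7-nt match to the seed region of a deeply
conserved miRNA family, (iv) do not overlap the polyadenylation signal
AAUAAA, the pumilio site UGUAHAUA or the ARE consensus UUAUUUAWW (as a
substring for patterns up to k long, or as a containing string for longer
patterns), and (v) occur in a comparable number of UTRs (within a fold
tolerance of the source's UTR count).

Candidates are enumerated exhaustively, filtered, and then sampled without
replacement with a seeded RNG, so control sets are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import (
    all_kmer_digit_matrix,
    code_to_kmer,
    encode_sequence,
    expand_iupac,
    kmer_to_code,
    rna_to_dna,
)
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: Abridged default list of 7-nt 3' UTR seed matches (reverse complement of
#: miRNA positions 2-8) for broadly conserved miRNA families.  Supply a
#: project-specific list for serious use; this default keeps the most
#: prominent families out of control sets.
DEFAULT_MIRNA_SEED_MATCHES: tuple[str, ...] = (
    "CTACCTC",  # let-7
    "ACATTCC",  # miR-1/206
    "GTGCCTT",  # miR-124
    "ATAAGCT",  # miR-21
    "TGGTGCT",  # miR-29
    "AGCATTA",  # miR-155
    "GTCTTCC",  # miR-7
    "ACCAAAG",  # miR-9
    "TGCTGCT",  # miR-15/16/195
    "GCACTTT",  # miR-17/20/93/106
    "TTTGCAC",  # miR-19
    "TACTTGA",  # miR-26
    "TGTTTAC",  # miR-30
    "CACTGCC",  # miR-34/449
    "GTACTGT",  # miR-101
    "ACACTCC",  # miR-122
    "GGACCAA",  # miR-133
    "AAGCCAT",  # miR-135
    "CACCAGC",  # miR-138
    "AACTGGA",  # miR-145
    "TGAATGT",  # miR-181
    "CAGTATT",  # miR-200b/c/429
    "ATGTAGC",  # miR-221/222
    "AACTGAC",  # miR-223
)

#: Known 3' UTR elements excluded from control sets (IUPAC, RNA notation):
#: polyadenylation signal, pumilio-binding site, ARE consensus.
DEFAULT_EXCLUDED_PATTERNS: tuple[str, ...] = ("AAUAAA", "UGUAHAUA", "UUAUUUAWW")

_UGUA = "TGTA"


@dataclass(frozen=True)
class ShuffleSpec:
    """Configuration of the shuffled-control construction.

    ``mode`` is ``mononucleotide`` (anagrams) or ``dinucleotide`` (identical
    dinucleotide multiset).  ``abundance_tolerance`` is the allowed fold
    difference in UTR counts between a control and its source.
    """

    mode: str = "mononucleotide"
    n_controls: int = 10
    abundance_tolerance: float = 2.0
    require_equal_ugua: bool = True
    excluded_7mers: tuple[str, ...] = DEFAULT_MIRNA_SEED_MATCHES
    excluded_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_PATTERNS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mononucleotide", "dinucleotide"):
            raise ConfigError(f"unknown shuffle mode {self.mode!r}")
        if self.n_controls < 1:
            raise ConfigError("n_controls must be >= 1")
        if self.abundance_tolerance < 1.0:
            raise ConfigError("abundance_tolerance is a fold factor >= 1")


def count_overlapping(haystack: str, needle: str) -> int:
    """Number of (possibly overlapping) occurrences of ``needle``."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def dinucleotide_multiset(kmer: str) -> tuple[str, ...]:
    return tuple(sorted(kmer[i : i + 2] for i in range(len(kmer) - 1)))


class ControlFactory:
    """Precomputed candidate tables for fast per-k-mer control generation.

    ``utr_count`` is an array of length ``4**k`` with the number of UTRs
    containing each k-mer code (used by the abundance filter); pass ``None``
    to disable abundance matching.
    """

    def __init__(self, spec: ShuffleSpec, k: int = 8, utr_count: np.ndarray | None = None):
        if k < 2 or k > 12:
            raise ConfigError(f"k={k} outside supported range 2..12")
        self.spec = spec
        self.k = k
        self.utr_count = utr_count
        n = 4 ** k
        digits = all_kmer_digit_matrix(k)  # (n, k) uint8
        self._digits = digits

        # mononucleotide composition key per code
        comp = np.zeros(n, dtype=np.int64)
        for b in range(3):  # fourth count is implied
            comp = comp * (k + 1) + (digits == b).sum(axis=1)
        self._comp_key = comp

        # dinucleotide multiset id per code (sorted dinucleotide codes)
        dinuc = (digits[:, :-1].astype(np.int64) * 4 + digits[:, 1:]).astype(np.int64)
        dinuc.sort(axis=1)
        _, self._dinuc_id = np.unique(dinuc, axis=0, return_inverse=True)

        # overlapping UGUA count per code
        ug = encode_sequence(_UGUA)
        ugua = np.zeros(n, dtype=np.int16)
        for off in range(k - len(_UGUA) + 1):
            ugua += (digits[:, off : off + 4] == ug).all(axis=1)
        self._ugua = ugua

        # excluded-7mer flag: any 7-window of the k-mer is a listed seed match
        excl = np.zeros(n, dtype=bool)
        seeds = {rna_to_dna(s) for s in spec.excluded_7mers}
        bad_seed = [s for s in seeds if len(s) != 7]
        if bad_seed:
            raise ConfigError(f"excluded_7mers must be 7 nt: {bad_seed}")
        if k >= 7:
            for s in sorted(seeds):
                sd = encode_sequence(s)
                for off in range(k - 7 + 1):
                    excl |= (digits[:, off : off + 7] == sd).all(axis=1)

        # excluded-pattern flag: overlap as substring or containing-string
        for pat in spec.excluded_patterns:
            for exp in expand_iupac(pat):
                ed = encode_sequence(exp)
                if len(exp) <= k:
                    for off in range(k - len(exp) + 1):
                        excl |= (digits[:, off : off + len(exp)] == ed).all(axis=1)
                else:
                    for off in range(len(exp) - k + 1):
                        excl[_window_code(ed[off : off + k])] = True
        self._excluded = excl

        self._groups: dict[int, np.ndarray] = {}

    def _group(self, comp_key: int) -> np.ndarray:
        g = self._groups.get(comp_key)
        if g is None:
            g = np.flatnonzero(self._comp_key == comp_key)
            self._groups[comp_key] = g
        return g

    def candidate_codes(self, code: int) -> np.ndarray:
        """All codes passing every filter for the given source code."""
        spec = self.spec
        cand = self._group(int(self._comp_key[code]))
        mask = cand != code
        if spec.mode == "dinucleotide":
            mask &= self._dinuc_id[cand] == self._dinuc_id[code]
        if spec.require_equal_ugua:
            mask &= self._ugua[cand] == self._ugua[code]
        mask &= ~self._excluded[cand]
        if self.utr_count is not None:
            src = float(self.utr_count[code])
            lo = src / spec.abundance_tolerance
            hi = src * spec.abundance_tolerance
            uc = self.utr_count[cand]
            mask &= (uc >= lo) & (uc <= hi)
        return cand[mask]

    def controls_for(self, code: int) -> np.ndarray:
        """Up to ``n_controls`` codes sampled without replacement (seeded).

        Returns the survivors (with a logged warning) when fewer than
        ``n_controls`` candidates pass the filters; raises
        :class:`DataError` when none do.
        """
        cand = self.candidate_codes(code)
        kmer = code_to_kmer(code, self.k)
        if len(cand) == 0:
            raise DataError(
                f"no shuffled controls survive the filters for {kmer!r}; "
                "relax abundance_tolerance or the exclusion lists"
            )
        if len(cand) < self.spec.n_controls:
            log.warning("only %d/%d controls available for %s",
                        len(cand), self.spec.n_controls, kmer)
            return cand
        rng = np.random.default_rng([self.spec.seed, code])
        return rng.choice(cand, size=self.spec.n_controls, replace=False)


def generate_shuffle_controls(
    kmer: str,
    spec: ShuffleSpec,
    utrs: Sequence["UtrRecord"] | None = None,  # noqa: F821
    utr_count: np.ndarray | None = None,
) -> list[str]:
    """Control k-mers (DNA alphabet) for one source k-mer.

    Abundance matching uses ``utr_count`` if given, else it is computed from
    ``utrs``; with neither, the abundance filter is skipped.
    """
    kmer = rna_to_dna(kmer)
    k = len(kmer)
    if utr_count is None and utrs is not None:
        from .conservation import kmer_utr_counts

        utr_count = kmer_utr_counts(utrs, k)
    factory = ControlFactory(spec, k=k, utr_count=utr_count)
    return [code_to_kmer(int(c), k) for c in factory.controls_for(kmer_to_code(kmer))]


def _window_code(digits: np.ndarray) -> int:
    code = 0
    for v in digits:
        code = code * 4 + int(v)
    return code
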