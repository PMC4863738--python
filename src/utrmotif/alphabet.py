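"""Nucleotide alphabets, IUPAC degeneracy, and integer k-mer encoding.

Sequences are held internally as upper-case DNA (``T``).  Motif patterns in
the 3' UTR literature are written in RNA (``U``); they are converted on
input and rendered back as RNA in user-facing reports.  Ambiguity codes are
the standard IUPAC nucleotide codes.  ``N`` in a *sequence* never matches
any pattern and breaks conservation calls; ``N`` in a *pattern* matches the
four unambiguous bases only.
"""
from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np

DNA = "ACGT"

#: IUPAC ambiguity codes over the DNA alphabet.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def rna_to_dna(s: str) -> str:
    """Normalize a sequence or pattern to the internal DNA alphabet."""
    return s.upper().replace("U", "T")


def dna_to_rna(s: str) -> str:
    """Render an internal DNA string in RNA for reports."""
    return s.upper().replace("T", "U")


def normalize_pattern(pattern: str) -> str:
    """Validate an IUPAC pattern (RNA or DNA) and return it in DNA.

    Raises ``ValueError`` naming the offending character for anything
    outside the IUPAC code table.
    """
    p = rna_to_dna(pattern)
    bad = sorted(set(p) - set(IUPAC_DNA))
    if bad:
        raise ValueError(f"unknown IUPAC code(s) {bad!r} in pattern {pattern!r}")
    if not p:
        raise ValueError("empty pattern")
    return p


def expand_iupac(pattern: str) -> list[str]:
    """All concrete DNA expansions of an IUPAC pattern.

    The order is the lexicographic product order of the per-position
    choices, so it is deterministic.
    """
    p = normalize_pattern(pattern)
    return ["".join(letters) for letters in itertools.product(*(IUPAC_DNA[c] for c in p))]


@lru_cache(maxsize=256)
def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compiled regex (DNA alphabet) equivalent to the IUPAC pattern.

    Degenerate positions become character classes; plain ``N`` in the
    scanned sequence is therefore never matched by a concrete position.
    """
    p = normalize_pattern(pattern)
    parts = []
    for c in p:
        opts = IUPAC_DNA[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


# ---------------------------------------------------------------------------
# integer encoding of k-mers (A=0, C=1, G=2, T=3); 255 marks non-ACGT
# ---------------------------------------------------------------------------

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_CHAR_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> uint8 digits (A=0..T=3, 255 for N or anything else)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode_digits(digits: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for valid (0..3) digits."""
    return _CHAR_LUT[digits].tobytes().decode("ascii")


def kmer_to_code(kmer: str) -> int:
    d = encode_sequence(kmer)
    if (d > 3).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    code = 0
    for v in d:
        code = code * 4 + int(v)
    return code


def code_to_kmer(code: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(DNA[code & 3])
        code >>= 2
    return "".join(reversed(letters))


def rolling_kmer_codes(digits: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all length-``k`` windows of a digit array.

    Returns ``(codes, valid)`` where ``valid[i]`` is False whenever the
    window starting at ``i`` contains a non-ACGT character (its code is
    then meaningless and must be ignored).
    """
    n = len(digits) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    d = digits.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(d[j:j + n] > 3, 0, d[j:j + n])
    bad = (digits > 3).astype(np.int64)
    # window is invalid if it contains any bad position
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    return codes, valid


def all_kmer_digit_matrix(k: int) -> np.ndarray:
    """(4**k, k) uint8 matrix of the digits of every k-mer code, in order."""
    codes = np.arange(4 ** k, dtype=np.int64)
    cols = []
    for j in range(k):
        cols.append((codes >> (2 * (k - 1 - j))) & 3)
    return np.stack(cols, axis=1).astype(np.uint8)
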