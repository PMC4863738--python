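"""Readers/writers for UTR sequences, alignment blocks and expression tables.

All sequences are normalized on input to upper-case DNA (U -> T); gap
characters are stripped from plain UTR records but preserved in alignment
rows.  Coordinates everywhere are 0-based, half-open, on the ungapped
reference-species sequence, 5' -> 3'.

The alignment-block format is a plain multi-FASTA in which each UTR
contributes one consecutive block of ``len(species)`` equal-length rows with
headers ``utr_id|species``.  The expression table is a TSV in the shape of a
CuffDiff gene-level output; CuffDiff column names are accepted through a
column-name map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError
from .alphabet import rna_to_dna

log = logging.getLogger(__name__)

DEFAULT_SPECIES: tuple[str, ...] = ("human", "mouse", "rat", "dog")

_SEQ_ALLOWED = set("ACGTN")
_ALN_ALLOWED = set("ACGTN-")


@dataclass(frozen=True)
class UtrRecord:
    """One reference-species 3' UTR sequence.

    ``sequence`` is gap-free upper-case DNA over {A,C,G,T,N}; ``length`` is
    its number of nucleotides.
    """

    utr_id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UtrAlignment:
    """One UTR with aligned orthologous rows (gap character ``-``).

    All rows have identical column count; the reference row with gaps
    removed is the UTR sequence on which coordinates are defined.
    """

    utr_id: str
    species_rows: Mapping[str, str]
    reference_species: str

    def __post_init__(self) -> None:
        lengths = {sp: len(r) for sp, r in self.species_rows.items()}
        if len(set(lengths.values())) > 1:
            raise DataError(f"alignment {self.utr_id!r}: ragged rows {lengths}")
        if self.reference_species not in self.species_rows:
            raise DataError(
                f"alignment {self.utr_id!r}: reference species "
                f"{self.reference_species!r} missing"
            )

    @property
    def n_columns(self) -> int:
        return len(self.species_rows[self.reference_species])

    @property
    def reference_row(self) -> str:
        return self.species_rows[self.reference_species]

    @property
    def reference_ungapped(self) -> str:
        return self.reference_row.replace("-", "")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression measurements.

    ``de_class`` is ``up`` iff q < q_threshold and log2FC > 0, ``down`` iff
    q < q_threshold and log2FC < 0, and ``unchanged`` otherwise.
    """

    gene_id: str
    mean_expr_control: float
    mean_expr_treated: float
    log2_fold_change: float
    p_value: float
    q_value: float
    de_class: str


def classify_de(log2_fold_change: float, q_value: float, q_threshold: float) -> str:
    if q_value < q_threshold and log2_fold_change > 0:
        return "up"
    if q_value < q_threshold and log2_fold_change < 0:
        return "down"
    return "unchanged"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _check_fasta_shape(path: Path) -> None:
    """Cheap structural check so parse errors can name a line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if not s.startswith(">"):
                raise DataError(f"{path}: line {lineno}: expected FASTA header, got {s[:30]!r}")
            return  # first non-blank line is a header; SeqIO handles the rest


def _normalize_utr_sequence(raw: str, utr_id: str, path: Path) -> str:
    seq = rna_to_dna(str(raw))
    seq = seq.replace("-", "")  # UTR records are gap-free by definition
    bad = sorted(set(seq) - _SEQ_ALLOWED)
    if bad:
        raise DataError(f"{path}: entry {utr_id!r}: illegal characters {bad}")
    return seq


def read_utr_fasta(path: str | Path) -> list[UtrRecord]:
    """Read a FASTA of reference-species UTRs.

    The first ``|``- or whitespace-delimited header token is the ``utr_id``;
    a second token, if present, is the ``gene_id`` (else it defaults to the
    ``utr_id``).  Duplicate ``utr_id`` values are an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    _check_fasta_shape(path)
    records: list[UtrRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.replace("|", " ").split()
        utr_id = tokens[0]
        gene_id = tokens[1] if len(tokens) > 1 else utr_id
        if utr_id in seen:
            raise DataError(f"{path}: duplicate utr_id {utr_id!r}")
        seen.add(utr_id)
        records.append(UtrRecord(utr_id, gene_id, _normalize_utr_sequence(entry.seq, utr_id, path)))
    return records


def write_utr_fasta(records: Iterable[UtrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.utr_id}|{r.gene_id}\n{r.sequence}\n")


def dedupe_utrs(records: Sequence[UtrRecord]) -> list[UtrRecord]:
    """Keep one UTR per gene: the longest, ties broken by smallest utr_id."""
    best: dict[str, UtrRecord] = {}
    for r in records:
        cur = best.get(r.gene_id)
        if cur is None or (-r.length, r.utr_id) < (-cur.length, cur.utr_id):
            best[r.gene_id] = r
    return [best[g] for g in sorted(best)]


# ---------------------------------------------------------------------------
# alignment blocks
# ---------------------------------------------------------------------------

def read_alignment_blocks(
    path: str | Path, species_list: Sequence[str] = DEFAULT_SPECIES
) -> list[UtrAlignment]:
    """Read multi-FASTA alignment blocks (headers ``utr_id|species``).

    Each UTR contributes ``len(species_list)`` consecutive entries; the
    reference species is ``species_list[0]``.  Missing species, unknown
    species labels and ragged rows are errors.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    _check_fasta_shape(path)
    species_list = list(species_list)
    expected = set(species_list)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if len(entries) % len(species_list) != 0:
        raise DataError(
            f"{path}: {len(entries)} entries is not a multiple of "
            f"{len(species_list)} species"
        )
    alignments: list[UtrAlignment] = []
    seen: set[str] = set()
    for i in range(0, len(entries), len(species_list)):
        block = entries[i : i + len(species_list)]
        rows: dict[str, str] = {}
        utr_ids = set()
        for entry in block:
            header = entry.description.split()[0]
            if "|" not in header:
                raise DataError(f"{path}: header {header!r} lacks 'utr_id|species'")
            utr_id, species = header.rsplit("|", 1)
            if species not in expected:
                raise DataError(f"{path}: unknown species {species!r} in block {utr_id!r}")
            utr_ids.add(utr_id)
            row = rna_to_dna(str(entry.seq))
            bad = sorted(set(row) - _ALN_ALLOWED)
            if bad:
                raise DataError(f"{path}: entry {header!r}: illegal characters {bad}")
            rows[species] = row
        if len(utr_ids) != 1:
            raise DataError(f"{path}: block mixes utr_ids {sorted(utr_ids)}")
        utr_id = utr_ids.pop()
        missing = expected - set(rows)
        if missing:
            raise DataError(f"{path}: block {utr_id!r} missing species {sorted(missing)}")
        if len({len(r) for r in rows.values()}) > 1:
            raise DataError(
                f"{path}: block {utr_id!r} has ragged rows "
                f"{ {sp: len(r) for sp, r in rows.items()} }"
            )
        if utr_id in seen:
            raise DataError(f"{path}: duplicate alignment block for {utr_id!r}")
        seen.add(utr_id)
        alignments.append(UtrAlignment(utr_id, rows, species_list[0]))
    return alignments


def write_alignment_blocks(
    alignments: Iterable[UtrAlignment], path: str | Path, species_list: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            order = list(species_list) if species_list else list(aln.species_rows)
            for sp in order:
                fh.write(f">{aln.utr_id}|{sp}\n{aln.species_rows[sp]}\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

#: CuffDiff gene-level column names -> canonical names.
CUFFDIFF_COLUMN_MAP: dict[str, str] = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "value_1": "mean_expr_control",
    "value_2": "mean_expr_treated",
    "log2(fold_change)": "log2_fold_change",
    "log2_fold_change": "log2_fold_change",
    "p_value": "p_value",
    "q_value": "q_value",
}

_REQUIRED = ("gene_id", "mean_expr_control", "mean_expr_treated",
             "log2_fold_change", "p_value", "q_value")


def read_expression_table(
    path: str | Path,
    q_threshold: float = 0.05,
    column_map: Mapping[str, str] | None = None,
    keep_nonfinite: bool = False,
) -> list[ExpressionRecord]:
    """Read a CuffDiff-style gene-level differential-expression TSV.

    Rows with a non-finite log2 fold change are excluded (and logged)
    unless ``keep_nonfinite``; such rows cannot enter CDF analyses either
    way.  Non-numeric fields raise a :class:`DataError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[])
    cmap = dict(CUFFDIFF_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = df.rename(columns={c: cmap[c] for c in df.columns if c in cmap})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    numeric = list(_REQUIRED[1:])
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip().str.lower() != "nan")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: row {row + 2} (gene {df['gene_id'].iloc[row]!r}): "
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}"
            )
        # pd.to_numeric's fast parser is not round-trip exact; convert via
        # numpy/python float parsing once validation has passed
        df[col] = df[col].astype(float)
    nonfinite = ~np.isfinite(df["log2_fold_change"].to_numpy(dtype=float))
    if nonfinite.any():
        log.info("%s: %d row(s) with non-finite log2 fold change %s",
                 path, int(nonfinite.sum()),
                 "kept" if keep_nonfinite else "excluded")
        if not keep_nonfinite:
            df = df[~nonfinite]
    records = []
    for row in df.itertuples(index=False):
        rec = ExpressionRecord(
            gene_id=str(row.gene_id),
            mean_expr_control=float(row.mean_expr_control),
            mean_expr_treated=float(row.mean_expr_treated),
            log2_fold_change=float(row.log2_fold_change),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            de_class=classify_de(float(row.log2_fold_change), float(row.q_value), q_threshold),
        )
        records.append(rec)
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    df = expression_frame(records)
    df.to_csv(path, sep="\t", index=False)


def expression_frame(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    recs = list(records)
    cols = ("gene_id", "mean_expr_control", "mean_expr_treated",
            "log2_fold_change", "p_value", "q_value", "de_class")
    return pd.DataFrame({c: [getattr(r, c) for r in recs] for c in cols})


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    """Write a TSV with an optional leading ``#`` provenance comment line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)
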