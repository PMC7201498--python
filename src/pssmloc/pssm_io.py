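"""Reading FASTA and PSI-BLAST ASCII PSSM files into validated matrices.

The PSSM for a protein of length L is an L x 20 real matrix whose entry
(i, j) is the position-specific score of residue position i being
substituted by the j-th amino acid. Raw log-odds scores can be squashed
into (0, 1) with :func:`sigmoid_scale` before feature encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from pssmloc.errors import ParseError, UsageError, ValidationError

#: Column ordering emitted by PSI-BLAST in -out_ascii_pssm headers.
PSIBLAST_COLUMN_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Standard one-letter amino-acid codes plus common ambiguity codes.
AMINO_ACIDS = frozenset(PSIBLAST_COLUMN_ORDER)
AMBIGUITY_CODES = frozenset("BZXUJO*")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier plus amino-acid sequence."""

    id: str
    sequence: str
    has_ambiguity: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record has an empty id")
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PssmMatrix:
    """An L x 20 position-specific score matrix for one protein.

    ``scores`` holds raw PSI-BLAST log-odds (integers stored as floats)
    until :func:`sigmoid_scale` marks the matrix as scaled, after which
    every entry lies strictly in (0, 1).
    """

    id: str
    scores: np.ndarray
    column_order: tuple[str, ...] = PSIBLAST_COLUMN_ORDER
    scaled: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.id!r} must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValidationError(f"PSSM for {self.id!r} has zero rows")
        if not np.isfinite(self.scores).all():
            raise ValidationError(f"PSSM for {self.id!r} contains non-finite scores")
        if len(self.column_order) != 20:
            raise ValidationError("column_order must list exactly 20 symbols")
        if self.scaled and not ((self.scores > 0) & (self.scores < 1)).all():
            raise ValidationError(
                f"PSSM for {self.id!r} is flagged scaled but has entries outside (0, 1)"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Order is preserved; duplicate IDs and empty files are rejected.
    Ambiguity codes (B, Z, X, ...) are accepted and flagged on the record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise ParseError(f"{path}: record {i} has an empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - AMINO_ACIDS - AMBIGUITY_CODES
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains invalid symbols {sorted(bad)}"
            )
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                has_ambiguity=bool(set(seq) & AMBIGUITY_CODES),
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def parse_ascii_pssm(path: str | Path, id: str | None = None) -> PssmMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first score block (the 20 integer log-odds columns) is kept.
    Residue rows must carry 40 numeric fields after the residue letter
    (20 log-odds + 20 weighted percentages); the two trailing
    per-position statistics some PSI-BLAST builds append are tolerated.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    column_order: tuple[str, ...] = PSIBLAST_COLUMN_ORDER
    rows: list[list[float]] = []
    in_table = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            if in_table:
                break  # blank line terminates the residue table
            continue
        fields = stripped.split()
        # Column-header line: 40 single-letter amino-acid tokens.
        if not in_table and len(fields) >= 20 and all(
            len(f) == 1 and f in AMINO_ACIDS for f in fields[:20]
        ):
            column_order = tuple(fields[:20])
            in_table = True
            continue
        if not in_table:
            continue
        # Residue row: index, letter, then numeric fields.
        if not fields[0].isdigit():
            break  # trailing K/Lambda statistics block
        if len(fields) < 2 or len(fields[1]) != 1:
            raise ParseError(f"{path}:{lineno}: malformed residue row")
        numeric = fields[2:]
        if len(numeric) not in (40, 42):
            raise ParseError(
                f"{path}:{lineno}: residue row {fields[0]} has "
                f"{len(numeric)} numeric fields, expected 40"
            )
        try:
            values = [float(v) for v in numeric][:20]
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: non-numeric score in residue row {fields[0]}"
            ) from exc
        rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no PSSM residue rows found")
    return PssmMatrix(
        id=id if id is not None else path.stem,
        scores=np.array(rows, dtype=float),
        column_order=column_order,
        scaled=False,
    )


def sigmoid_scale(m: PssmMatrix) -> PssmMatrix:
    """Map every score x to 1 / (1 + e^(-x)), flagging the matrix scaled.

    Raises :class:`UsageError` if the matrix is already scaled.
    """
    if m.scaled:
        raise UsageError(f"PSSM for {m.id!r} is already sigmoid-scaled")
    with np.errstate(over="ignore"):
        scaled = 1.0 / (1.0 + np.exp(-m.scores))
    # Guard against saturation at exactly 0/1 for extreme raw scores.
    eps = np.finfo(float).tiny
    scaled = np.clip(scaled, eps, 1.0 - np.finfo(float).epsneg)
    return PssmMatrix(id=m.id, scores=scaled, column_order=m.column_order, scaled=True)


def check_against_sequence(m: PssmMatrix, record: ProteinRecord) -> None:
    """Warn when a PSSM's row count disagrees with its FASTA sequence length."""
    if m.id == record.id and m.length != len(record):
        warnings.warn(
            f"PSSM for {m.id!r} has {m.length} rows but the FASTA sequence "
            f"has {len(record)} residues",
            stacklevel=2,
        )


def write_pssm_tsv(matrices: Iterable[PssmMatrix], path: str | Path) -> None:
    """Dump matrices to TSV: id, row index, 20 tab-separated scores.

    Scores are written with full float precision so a round-trip through
    :func:`read_pssm_tsv` reproduces them exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\trow\t" + "\t".join(PSIBLAST_COLUMN_ORDER) + "\n")
        for m in matrices:
            for i, row in enumerate(m.scores, start=1):
                fh.write(
                    f"{m.id}\t{i}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )


def read_pssm_tsv(path: str | Path, scaled: bool = False) -> list[PssmMatrix]:
    """Re-read a TSV dump written by :func:`write_pssm_tsv`."""
    path = Path(path)
    per_id: dict[str, list[list[float]]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "row"]:
            raise ParseError(f"{path}:1: expected 'id<TAB>row<TAB>...' header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 22:
                raise ParseError(f"{path}:{lineno}: expected 22 fields")
            per_id.setdefault(fields[0], []).append([float(v) for v in fields[2:]])
    return [
        PssmMatrix(id=pid, scores=np.array(rows), scaled=scaled)
        for pid, rows in per_id.items()
    ]
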