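"""Sequence and distance-matrix I/O.

FASTA reading/writing is delegated to Biopython; distance matrices use the
square (symmetric) PHYLIP dialect: a header line with the taxon count, then
one row per taxon consisting of the label followed by whitespace-separated
values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sequence",
    "DistanceMatrix",
    "read_fasta",
    "write_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
]


@dataclasses.dataclass(frozen=True)
class Sequence:
    """An identified nucleotide (or amino-acid) string.

    Parameters
    ----------
    id : str
        Non-empty label, unique within a dataset.
    residues : str
        Residue string; uppercase after normalization.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class DistanceMatrix:
    """A labeled symmetric non-negative distance matrix.

    The diagonal is stored as computed rather than forced to zero; consumers
    that assume ``d(x, x) = 0`` (e.g. clustering) use off-diagonal entries
    only.  ``dialect`` records which normalized-compression-distance variant
    produced the values (``"max"`` or ``"min"``) or ``"external"`` for
    matrices read from disk.
    """

    labels: list[str]
    values: np.ndarray
    dialect: str = "external"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {self.values.shape}")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels but {self.values.shape[0]} matrix rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: TypingSequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.dialect)


def _normalize(raw: str, mode: str) -> str:
    if mode == "verbatim":
        return raw
    if mode == "dna":
        return raw.upper().replace("U", "T")
    raise ValueError(f"unknown normalization mode {mode!r} (expected 'dna' or 'verbatim')")


def read_fasta(path: str | Path, mode: str = "dna") -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Record order is preserved; ids are the header token before the first
    whitespace.  In the default ``"dna"`` mode residues are uppercased and U
    is mapped to T; ``"verbatim"`` keeps them untouched.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        On duplicate ids or an empty record, naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq), mode)
        if not residues:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seqs.append(Sequence(rec.id, residues))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    """Write sequences to *path* in FASTA format (fixed line width)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    """Write *D* in the square PHYLIP dialect with 6+ significant digits."""
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for label, row in zip(D.labels, D.values):
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label} {vals}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix.

    Raises
    ------
    ValueError
        On a malformed header, a label/row count mismatch, or rows of
        inconsistent width.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if not lines:
        raise ValueError(f"empty distance matrix file: {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError(f"malformed PHYLIP header {lines[0]!r} in {path}") from exc
    rows = lines[1:]
    if len(rows) != n:
        raise ValueError(f"header says {n} taxa but file has {len(rows)} rows")
    labels: list[str] = []
    values = np.empty((n, n), dtype=float)
    for i, row in enumerate(rows):
        parts = row.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"row {i} has {len(parts) - 1} values, expected {n} (label {parts[0]!r})"
            )
        labels.append(parts[0])
        values[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(labels, values)
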