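"""FASTA input, sequence cleaning, and PHYLIP/Newick interchange.

DNA sequences are reduced to the four-letter alphabet A/C/G/T before any
counting. Symbols outside the alphabet (IUPAC ambiguity codes such as N,
Y, M, gap characters, stray whitespace) are deleted, but each deletion is
recorded as an *adjacency break*: a dinucleotide pair is only ever counted
when the two residues were literally adjacent in the original sequence.
RNA input is accepted by mapping U to T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .dmatrix import DistanceMatrix
from .errors import (
    DuplicateIdError,
    EmptyInputError,
    PhylipFormatError,
    PhylipNameError,
    ShortSequenceError,
)

__all__ = [
    "SequenceRecord",
    "Dataset",
    "clean_sequence",
    "read_fasta",
    "write_fasta",
    "write_phylip_distance",
    "read_phylip_distance",
]

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One cleaned DNA sequence.

    ``residues`` contains only A/C/G/T. ``breaks`` holds indices ``i``
    such that the pair ``residues[i:i+2]`` was interrupted by a removed
    symbol in the raw input and must not be counted as adjacent.
    """

    id: str
    residues: str
    breaks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if set(self.residues) - _ALPHABET:
            raise ValueError("residues must be cleaned to A/C/G/T")


@dataclass
class Dataset:
    """An ordered collection of uniquely identified sequence records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sequence ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def clean_sequence(raw: str) -> tuple[str, frozenset[int]]:
    """Normalise a raw sequence string to A/C/G/T plus break positions.

    Upper-cases, maps U to T, drops every other non-A/C/G/T symbol and
    records an adjacency break where a symbol was dropped between two
    retained residues.
    """
    residues: list[str] = []
    breaks: set[int] = set()
    pending_break = False
    for ch in raw.upper():
        if ch == "U":
            ch = "T"
        if ch in _ALPHABET:
            if pending_break and residues:
                breaks.add(len(residues) - 1)
            pending_break = False
            residues.append(ch)
        else:
            pending_break = True
    return "".join(residues), frozenset(breaks)


def read_fasta(path: str | Path) -> Dataset:
    """Read a multi-FASTA file into a cleaned :class:`Dataset`.

    Raises
    ------
    EmptyInputError
        If the file holds no records.
    DuplicateIdError
        If two records share an identifier.
    ShortSequenceError
        If any record has fewer than two usable residues.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues, breaks = clean_sequence(str(entry.seq))
        if len(residues) < 2:
            raise ShortSequenceError(
                f"record {entry.id!r} has {len(residues)} usable residues; "
                "at least 2 are required"
            )
        records.append(SequenceRecord(id=entry.id, residues=residues, breaks=breaks))
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return Dataset(records)


def write_fasta(dataset: Dataset | Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write cleaned records back out as FASTA (breaks are not re-inserted)."""
    records = list(dataset)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def write_phylip_distance(matrix: DistanceMatrix, path: str | Path,
                          name_width: int = 10, relaxed: bool = False) -> None:
    """Write a square PHYLIP distance matrix with 6-decimal entries.

    In strict mode (default) names are truncated/padded to ``name_width``
    characters for bit-compatibility with PHYLIP's ``neighbor`` program;
    a truncation collision raises :class:`PhylipNameError`. Relaxed mode
    writes full names followed by two spaces.
    """
    if relaxed:
        names = list(matrix.labels)
    else:
        names = [lab[:name_width] for lab in matrix.labels]
        if len(set(names)) != len(names):
            raise PhylipNameError(
                f"taxon names collide after truncation to {name_width} "
                "characters; rename taxa or use relaxed mode"
            )
        names = [n.ljust(name_width) for n in names]
    with open(path, "w") as fh:
        fh.write(f"{matrix.n}\n")
        for name, row in zip(names, matrix.d):
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name}  {vals}\n")


def read_phylip_distance(path: str | Path, name_width: int = 10) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (inverse of the writer).

    Accepts both whitespace-delimited names and fixed-width name fields.
    Checks the taxon-count header, squareness, and symmetry to 1e-6.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise PhylipFormatError("empty PHYLIP file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise PhylipFormatError(f"bad taxon-count header: {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) != n:
        raise PhylipFormatError(f"header says {n} taxa but found {len(body)} rows")
    labels: list[str] = []
    d = np.zeros((n, n))
    for i, line in enumerate(body):
        tokens = line.split()
        if len(tokens) == n + 1:
            name, vals = tokens[0], tokens[1:]
        else:
            name = line[:name_width].strip()
            vals = line[name_width:].split()
        if not name:
            raise PhylipFormatError(f"row {i + 1}: missing taxon name")
        if len(vals) != n:
            raise PhylipFormatError(
                f"row {i + 1} ({name!r}): expected {n} distances, got {len(vals)}"
            )
        labels.append(name)
        d[i] = [float(v) for v in vals]
    if np.max(np.abs(d - d.T)) > 1e-6:
        raise PhylipFormatError("matrix body is not symmetric (tolerance 1e-6)")
    if np.max(np.abs(np.diag(d))) > 1e-6:
        raise PhylipFormatError("matrix diagonal is not zero")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)
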