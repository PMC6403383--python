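"""Markov-chain estimation from DNA sequences.

Each sequence is modelled as a first-order homogeneous Markov chain over
the state space S = (A, T, G, C). The 1-step transition probability from
state s_i to s_j is the observed count of the adjacent pair (s_i, s_j)
divided by the total count of pairs starting at s_i. Higher-order (k-step)
behaviour follows from the Chapman-Kolmogorov relation, i.e. the k-th
matrix power of the 1-step matrix.

The state order (A, T, G, C) is used everywhere: count grids, matrices,
and debug dumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord

__all__ = [
    "STATES",
    "DinucleotideCounts",
    "TransitionMatrix",
    "count_dinucleotides",
    "estimate_transition_matrix",
    "transition_matrix_from_record",
    "k_step",
]

STATES: tuple[str, ...] = ("A", "T", "G", "C")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class DinucleotideCounts:
    """4x4 grid of adjacent-pair counts N[s_i][s_j], state order (A,T,G,C)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (4, 4):
            raise ValueError("counts must be a 4x4 grid")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 transition matrix at a given step k."""

    p: np.ndarray
    step: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
            raise ValueError("every row must sum to 1 within 1e-12")
        if self.step < 1:
            raise ValueError("step must be a positive integer")
        object.__setattr__(self, "p", p)

    def to_tsv(self) -> str:
        """Debug dump with rows/columns labelled A, T, G, C."""
        lines = ["\t" + "\t".join(STATES)]
        for s, row in zip(STATES, self.p):
            lines.append(s + "\t" + "\t".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


def count_dinucleotides(record: SequenceRecord) -> DinucleotideCounts:
    """Count adjacent ordered nucleotide pairs, honouring adjacency breaks.

    Raises ``ValueError`` if the record yields zero countable pairs (for
    example a two-residue record whose only pair spans a removed symbol).
    """
    idx = np.fromiter((_STATE_INDEX[c] for c in record.residues),
                      dtype=np.int64, count=len(record.residues))
    if len(idx) < 2:
        raise ValueError(f"record {record.id!r} has no adjacent pairs")
    mask = np.ones(len(idx) - 1, dtype=bool)
    for b in record.breaks:
        if 0 <= b < len(mask):
            mask[b] = False
    if not mask.any():
        raise ValueError(
            f"record {record.id!r} has zero countable adjacent pairs "
            "(all pairs span removed symbols)"
        )
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (idx[:-1][mask], idx[1:][mask]), 1)
    return DinucleotideCounts(counts)


def estimate_transition_matrix(counts: DinucleotideCounts,
                               zero_row_policy: str = "uniform") -> TransitionMatrix:
    """Estimate the 1-step transition matrix from pair counts.

    Rows with at least one observed outgoing pair are normalised by their
    total. Rows never observed as a starting state are handled by policy:

    - ``"uniform"`` (default): the row becomes (0.25, 0.25, 0.25, 0.25);
    - ``"pseudocount"``: one is added to every cell of the grid before
      normalising, smoothing all rows.
    """
    if zero_row_policy not in ("uniform", "pseudocount"):
        raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")
    c = counts.counts.astype(float)
    if zero_row_policy == "pseudocount":
        c = c + 1.0
    totals = c.sum(axis=1)
    p = np.empty((4, 4))
    for i in range(4):
        if totals[i] > 0:
            p[i] = c[i] / totals[i]
        else:
            p[i] = 0.25
    return TransitionMatrix(p=p, step=1)


def transition_matrix_from_record(record: SequenceRecord,
                                  zero_row_policy: str = "uniform") -> TransitionMatrix:
    """Convenience: counts then estimation in one call."""
    return estimate_transition_matrix(count_dinucleotides(record), zero_row_policy)


def k_step(P: TransitionMatrix, k: int) -> TransitionMatrix:
    """Raise a 1-step matrix to its k-step version (Chapman-Kolmogorov).

    Computed by iterated multiplication; at 4x4 with small k this is exact
    enough and avoids eigendecomposition edge cases. Rows are renormalised
    by their (numerically near-1) sums to keep stochasticity to 1e-12.
    """
    if int(k) != k or k < 1:
        raise ValueError("k must be a positive integer >= 1")
    if P.step != 1:
        raise ValueError("k_step expects a 1-step matrix")
    if k == 1:
        return TransitionMatrix(p=P.p.copy(), step=1)
    q = P.p.copy()
    for _ in range(int(k) - 1):
        q = q @ P.p
    q = np.clip(q, 0.0, 1.0)
    q = q / q.sum(axis=1, keepdims=True)
    return TransitionMatrix(p=q, step=int(k))
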