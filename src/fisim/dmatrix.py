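"""Symmetric pairwise distance matrices with taxon labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances.

    Parameters
    ----------
    labels
        Ordered taxon names, one per row/column. Must be unique.
    d
        ``(n, n)`` array of distances in ``[0, 1]``; symmetric within
        1e-12 with an exactly zero diagonal.
    step
        The Markov step ``k`` the distances were computed at, if any.
    """

    labels: list[str]
    d: np.ndarray
    step: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.d.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("taxon labels must be unique")
        if n and not np.allclose(self.d, self.d.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix must be symmetric")
        if n and np.any(np.diag(self.d) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.d[self.labels.index(a), self.labels.index(b)])
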