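"""All-pairs distance matrices, optimal-step selection, end-to-end runs.

For a dataset of n sequences the pipeline estimates one 1-step transition
matrix per sequence, raises each to step k, and fills the symmetric n x n
matrix of fuzzy distances. The step k is chosen by convergence: k is
increased until the distance matrix stops changing, measured as the root
mean square difference (RMSD) over the strict upper triangle between the
matrices at consecutive steps. The smallest k whose RMSD against k+1
falls below a tolerance is the optimal step; because transition-matrix
powers of ergodic chains converge geometrically to their stationary
rows, this terminates quickly on non-pathological data.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .dmatrix import DistanceMatrix
from .fuzzy import fuzzy_distance
from .io import Dataset, write_phylip_distance
from .markov import TransitionMatrix, k_step, transition_matrix_from_record

__all__ = [
    "ConvergenceReport",
    "RunResult",
    "distance_matrix",
    "rmsd",
    "find_optimal_k",
    "run",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_K = 30


@dataclass
class ConvergenceReport:
    """Trace of the optimal-step search.

    ``rmsd_trace`` holds ``(k, RMSD(D_k, D_{k+1}))`` pairs in the order
    they were computed; ``converged`` is False when the search hit
    ``max_k`` without the RMSD dropping below ``tol``.
    """

    optimal_k: int
    rmsd_trace: list[tuple[int, float]]
    tol: float
    max_k: int
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "optimal_k": self.optimal_k,
            "rmsd_trace": [[k, v] for k, v in self.rmsd_trace],
            "tol": self.tol,
            "max_k": self.max_k,
            "converged": self.converged,
        }


@dataclass
class RunResult:
    """Everything an end-to-end run produced."""

    matrix: DistanceMatrix
    report: ConvergenceReport | None
    newick: str | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _step_matrices(dataset: Dataset, zero_row_policy: str) -> list[TransitionMatrix]:
    return [transition_matrix_from_record(r, zero_row_policy) for r in dataset]


def _pairwise(labels: list[str], mats: list[TransitionMatrix],
              step: int) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = fuzzy_distance(mats[a], mats[b])
            d[a, b] = d[b, a] = v
    return DistanceMatrix(labels=labels, d=d, step=step)


def distance_matrix(dataset: Dataset, k: int,
                    zero_row_policy: str = "uniform") -> DistanceMatrix:
    """Fuzzy-distance matrix of all sequence pairs at step k.

    Each unordered pair is computed once and mirrored; the diagonal is
    exactly zero by construction.
    """
    if len(dataset) < 2:
        raise ValueError("distance matrix requires at least 2 sequences")
    base = _step_matrices(dataset, zero_row_policy)
    mats = [k_step(P, k) for P in base]
    return _pairwise(dataset.ids, mats, step=k)


def rmsd(D1: DistanceMatrix, D2: DistanceMatrix) -> float:
    """Root mean square difference over the strict upper triangle.

    The diagonal is identically zero and excluded so it cannot dilute the
    statistic. Zero iff the two matrices are equal.
    """
    if D1.labels != D2.labels:
        raise ValueError("matrices must share labels in the same order")
    iu = np.triu_indices(D1.n, k=1)
    diff = D1.d[iu] - D2.d[iu]
    return float(math.sqrt(np.mean(diff * diff)))


def find_optimal_k(dataset: Dataset, tol: float = DEFAULT_TOL,
                   max_k: int = DEFAULT_MAX_K,
                   zero_row_policy: str = "uniform",
                   ) -> tuple[ConvergenceReport, DistanceMatrix]:
    """Smallest step h with RMSD(D_h, D_{h+1}) <= tol, and D_h itself.

    Exact matrix equality at consecutive steps is the idealised criterion;
    in floating point a tolerance is required, and the 1e-6 default
    mirrors the 6-decimal PHYLIP serialisation of the matrices. If no
    step up to ``max_k`` converges, the report carries
    ``converged=False`` and the matrix at ``max_k`` is returned.
    """
    if len(dataset) < 2:
        raise ValueError("optimal-step search requires at least 2 sequences")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    base = _step_matrices(dataset, zero_row_policy)
    labels = dataset.ids
    powers = list(base)  # current k-step matrices
    current = _pairwise(labels, powers, step=1)
    trace: list[tuple[int, float]] = []
    for k in range(1, max_k + 1):
        powers = [k_step(P, k + 1) for P in base]
        nxt = _pairwise(labels, powers, step=k + 1)
        r = rmsd(current, nxt)
        trace.append((k, r))
        if r <= tol:
            return (ConvergenceReport(optimal_k=k, rmsd_trace=trace, tol=tol,
                                      max_k=max_k, converged=True), current)
        if k < max_k:
            current = nxt
    report = ConvergenceReport(optimal_k=max_k, rmsd_trace=trace, tol=tol,
                               max_k=max_k, converged=False)
    return report, current


def run(dataset: Dataset, k: int | str = "auto",
        phylip_path: str | Path | None = None,
        newick_path: str | Path | None = None,
        report_path: str | Path | None = None,
        tree_method: str = "upgma",
        tol: float = DEFAULT_TOL, max_k: int = DEFAULT_MAX_K,
        zero_row_policy: str = "uniform",
        relaxed_phylip: bool = False) -> RunResult:
    """End-to-end: distances (fixed or auto step), tree, serialised outputs.

    Pure per-pair computation makes the result independent of evaluation
    order; running the same configuration twice produces byte-identical
    files.
    """
    from .tree import neighbor_joining, to_newick, upgma  # local: avoid cycle

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if k == "auto":
        report, matrix = find_optimal_k(dataset, tol=tol, max_k=max_k,
                                        zero_row_policy=zero_row_policy)
    else:
        kk = int(k)
        matrix = distance_matrix(dataset, kk, zero_row_policy)
        report = None
    timings["distances_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if tree_method == "upgma":
        tree = upgma(matrix)
    elif tree_method == "nj":
        tree = neighbor_joining(matrix)
    else:
        raise ValueError(f"unknown tree method {tree_method!r}")
    newick = to_newick(tree)
    timings["tree_s"] = time.perf_counter() - t0

    if phylip_path is not None:
        write_phylip_distance(matrix, phylip_path, relaxed=relaxed_phylip)
    if newick_path is not None:
        Path(newick_path).write_text(newick)
    if report_path is not None:
        payload = {
            "version": _pkg_version,
            "n_sequences": len(dataset),
            "k": matrix.step,
            "tree_method": tree_method,
            "zero_row_policy": zero_row_policy,
            "timings": timings,
        }
        if report is not None:
            payload["convergence"] = report.to_dict()
        Path(report_path).write_text(json.dumps(payload, indent=2) + "\n")
    return RunResult(matrix=matrix, report=report, newick=newick,
                     timings=timings)
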