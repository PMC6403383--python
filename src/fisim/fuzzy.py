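"""Sugeno fuzzy-integral similarity between transition matrices.

Two k-step transition matrices P1 and P2 are compared cell by cell. For
each of the 16 nucleotide-pair positions y_ij:

- the *evidence* h(y_ij) = 1 - |P1_ij - P2_ij| measures how close the two
  chains are at that position, and
- the *fuzzy density* mu(y_ij) = max(P1_ij, P2_ij) measures the maximum
  level of conservation of the pair, so better conserved positions carry
  more weight.

Within each matrix row i, the four densities induce a lambda-fuzzy
(Sugeno) measure: for disjoint X, Y,
``mu(X u Y) = mu(X) + mu(Y) + lambda_i mu(X) mu(Y)``, with lambda_i > -1
fixed by the normalisation ``prod_j (1 + lambda_i mu_ij) = 1 + lambda_i``
so that the full row has measure 1. The Sugeno integral of h against that
measure — evidence sorted descending, max over j of
min(h_(j), mu(A_ij)) — gives a per-row similarity; the overall similarity
is the maximum over the four rows, and distance is one minus similarity.

Row densities here are elementwise maxima of two stochastic rows, so
their sum is >= 1 and lambda lies in (-1, 0]. The inner loops are plain
Python scalars on purpose: at 4x4 this is faster than vectorising and
keeps the arithmetic order (hence bit-level reproducibility) fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import TransitionMatrix

__all__ = [
    "MembershipGrid",
    "DensityGrid",
    "FuzzyRowMeasure",
    "membership_grid",
    "density_grid",
    "solve_lambda",
    "row_measure",
    "sugeno_row",
    "fisim",
    "fuzzy_distance",
]

_SUM_ONE_TOL = 1e-9
_BISECT_EDGE = 1e-12
_BISECT_WIDTH = 1e-14
_MAX_BISECT = 200


@dataclass(frozen=True)
class MembershipGrid:
    """4x4 grid of evidence values h in [0, 1], one per pair position."""

    h: np.ndarray


@dataclass(frozen=True)
class DensityGrid:
    """4x4 grid of fuzzy densities mu in [0, 1], one per pair position."""

    mu: np.ndarray


@dataclass(frozen=True)
class FuzzyRowMeasure:
    """One row's sorted evidence, densities, lambda and cumulative measure.

    ``order`` maps sorted position j to the original column; ``h`` and
    ``densities`` are in sorted (descending-h) order; ``cumulative[j]`` is
    the measure of the set of the first j+1 positions, clamped to <= 1.
    """

    order: tuple[int, int, int, int]
    h: tuple[float, float, float, float]
    densities: tuple[float, float, float, float]
    lam: float
    cumulative: tuple[float, float, float, float]


def _check_same_step(P1: TransitionMatrix, P2: TransitionMatrix) -> None:
    if P1.step != P2.step:
        raise ValueError(
            f"step mismatch: cannot compare a {P1.step}-step with a "
            f"{P2.step}-step matrix"
        )


def membership_grid(P1: TransitionMatrix, P2: TransitionMatrix) -> MembershipGrid:
    """Evidence h = 1 - |P1 - P2| cellwise; symmetric in its inputs."""
    _check_same_step(P1, P2)
    return MembershipGrid(h=1.0 - np.abs(P1.p - P2.p))


def density_grid(P1: TransitionMatrix, P2: TransitionMatrix) -> DensityGrid:
    """Densities mu = max(P1, P2) cellwise: conservation of each pair."""
    _check_same_step(P1, P2)
    return DensityGrid(mu=np.maximum(P1.p, P2.p))


def _norm_residual(lam: float, mu: tuple[float, ...]) -> float:
    prod = 1.0
    for m in mu:
        prod *= 1.0 + lam * m
    return prod - 1.0 - lam


def solve_lambda(densities) -> float:
    """Solve the lambda-measure normalisation for one row of densities.

    Returns lambda > -1 with ``prod_j (1 + lambda mu_j) = 1 + lambda``.
    When the densities sum to 1 (within 1e-9) the measure is additive and
    lambda = 0. When the sum exceeds 1 the unique non-trivial root lies in
    (-1, 0) and is bracketed by bisection, then polished with Newton
    steps. When the sum is below 1 the root is positive and an expanding
    bracket is used. Degenerate density patterns (e.g. exact 0/1 rows)
    admit only the trivial roots 0 and -1; these fall back to lambda = 0,
    with normalisation restored downstream by clamping the cumulative
    measure at 1.
    """
    mu = tuple(float(m) for m in densities)
    if len(mu) != 4:
        raise ValueError("expected exactly 4 densities")
    for m in mu:
        if not (0.0 <= m <= 1.0):
            raise ValueError(f"density {m} outside [0, 1]")
    s = sum(mu)
    if abs(s - 1.0) <= _SUM_ONE_TOL:
        return 0.0
    if s > 1.0:
        lo, hi = -1.0 + _BISECT_EDGE, -_BISECT_EDGE
    else:
        # root is positive; expand until the residual changes sign
        lo, hi = _BISECT_EDGE, 1.0
        while _norm_residual(hi, mu) < 0.0 and hi < 1e12:
            hi *= 2.0
    flo, fhi = _norm_residual(lo, mu), _norm_residual(hi, mu)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        return 0.0  # degenerate pattern: no interior root
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        fmid = _norm_residual(mid, mu)
        if fmid == 0.0:
            lo = hi = mid
            break
        if (fmid > 0.0) == (flo > 0.0):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
        if hi - lo < _BISECT_WIDTH:
            break
    lam = 0.5 * (lo + hi)
    # Newton polish to push the residual to machine precision
    for _ in range(4):
        f = _norm_residual(lam, mu)
        h = 1e-7 * max(abs(lam), 1.0)
        df = (_norm_residual(lam + h, mu) - _norm_residual(lam - h, mu)) / (2 * h)
        if df == 0.0:
            break
        step = f / df
        cand = lam - step
        if not (-1.0 < cand):
            break
        lam = cand
        if abs(step) < 1e-16:
            break
    return lam


def row_measure(h_row, density_row) -> FuzzyRowMeasure:
    """Sort one row by descending evidence and build its cumulative measure.

    The (h, density) pairs are jointly sorted by descending h with a
    stable sort, so ties keep the original column order (A, T, G, C) —
    the integral value is tie-order invariant, but stable order makes the
    intermediates bit-reproducible. The cumulative measure follows the
    lambda-measure union recursion and is clamped to <= 1 (the clamp only
    engages in the degenerate lambda = 0 fallback).
    """
    h = [float(x) for x in h_row]
    mu = [float(x) for x in density_row]
    if len(h) != 4 or len(mu) != 4:
        raise ValueError("expected rows of 4 values")
    order = tuple(sorted(range(4), key=lambda j: -h[j]))
    hs = tuple(h[j] for j in order)
    ms = tuple(mu[j] for j in order)
    lam = solve_lambda(mu)
    cum = [ms[0]]
    for j in range(1, 4):
        nxt = cum[-1] + ms[j] + lam * cum[-1] * ms[j]
        cum.append(nxt)
    cum = tuple(min(1.0, max(0.0, c)) for c in cum)
    return FuzzyRowMeasure(order=order, h=hs, densities=ms, lam=lam,
                           cumulative=cum)


def sugeno_row(measure: FuzzyRowMeasure) -> float:
    """Sugeno integral of one row: max_j min(h_(j), mu(A_ij))."""
    best = 0.0
    for hj, cj in zip(measure.h, measure.cumulative):
        v = hj if hj < cj else cj
        if v > best:
            best = v
    return best


def fisim(P1: TransitionMatrix, P2: TransitionMatrix) -> float:
    """Fuzzy-integral similarity between two same-step matrices, in [0, 1].

    The per-row Sugeno integrals are aggregated by their maximum over the
    four rows: similarity 1 means at least one row is matched perfectly
    under a fully conserved measure; identical matrices always score 1.
    """
    _check_same_step(P1, P2)
    h = 1.0 - np.abs(P1.p - P2.p)
    mu = np.maximum(P1.p, P2.p)
    best = 0.0
    for i in range(4):
        s = sugeno_row(row_measure(h[i], mu[i]))
        if s > best:
            best = s
    return best


def fuzzy_distance(P1: TransitionMatrix, P2: TransitionMatrix) -> float:
    """Distance D = 1 - fisim(P1, P2); symmetric, zero iff similarity 1."""
    return 1.0 - fisim(P1, P2)
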