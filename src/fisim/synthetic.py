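"""Markov-chain sequence simulation and tree-guided family generation.

These generators make every pipeline stage testable without downloading
genomes. :func:`simulate_sequence` draws a DNA sequence from an explicit
first-order chain. :func:`evolve_family` simulates a root sequence and
evolves it along a guide tree under per-site uniform substitution (each
substituted base is replaced uniformly by one of the other three), with
per-branch substitution probability ``1 - exp(-rate * branch_length)``.

Under uniform substitution every lineage's base composition relaxes
toward uniform at a rate set by its total path length, so clades given
different depths acquire distinct, heritable compositional signatures —
the kind of signal (lineage-specific composition bias) that word-
statistic methods exploit in real genomes. The bundled default family
study uses a balanced 8-leaf guide tree whose four cherries sit at four
different depths for exactly this reason.

All randomness flows from explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import Dataset, SequenceRecord
from .markov import STATES, TransitionMatrix
from .tree import PhyloTree, from_newick

__all__ = [
    "ChainSpec",
    "simulate_sequence",
    "evolve_family",
    "stationary_distribution",
    "default_root_chain",
    "default_family_tree",
    "default_family",
    "DEFAULT_FAMILY_LENGTH",
    "DEFAULT_FAMILY_RATE",
]

# Study conditions for the bundled topology-recovery benchmark: 20 kb
# sequences, substitution rate 1 per unit branch length, guide tree below.
DEFAULT_FAMILY_LENGTH = 20_000
DEFAULT_FAMILY_RATE = 1.0

# Balanced 8-leaf guide tree. Cherry depths (0.17, 0.25, 0.60, 0.79)
# emulate lineage-specific rate variation: each clade equilibrates its
# composition to a different degree, giving clades distinct signatures.
_DEFAULT_FAMILY_NEWICK = (
    "(((t1:0.07,t2:0.07):0.05,(t3:0.15,t4:0.15):0.05):0.05,"
    "((t5:0.50,t6:0.50):0.05,(t7:0.69,t8:0.69):0.05):0.05);"
)

# Compositionally skewed (A/G-rich), fast-mixing root chain.
_DEFAULT_ROOT_P = np.array([
    [0.50, 0.10, 0.30, 0.10],
    [0.40, 0.18, 0.30, 0.12],
    [0.36, 0.10, 0.42, 0.12],
    [0.40, 0.16, 0.30, 0.14],
])


@dataclass(frozen=True)
class ChainSpec:
    """A fully specified chain simulation: matrix, initial law, length, seed."""

    P: TransitionMatrix
    initial: np.ndarray
    length: int
    seed: int
    record_id: str = field(default="")

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, dtype=float)
        if init.shape != (4,) or np.any(init < 0):
            raise ValueError("initial must be 4 non-negative probabilities")
        if abs(init.sum() - 1.0) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        object.__setattr__(self, "initial", init)


def stationary_distribution(P: TransitionMatrix) -> np.ndarray:
    """Stationary row vector pi with pi P = pi (ergodic chains)."""
    vals, vecs = np.linalg.eig(P.p.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _draw_states(P: np.ndarray, initial: np.ndarray, length: int,
                 rng: np.random.Generator) -> np.ndarray:
    cum_rows = np.cumsum(P, axis=1)
    cum_rows[:, -1] = 1.0  # guard against cumulative round-off
    cum_init = np.cumsum(initial)
    cum_init[-1] = 1.0
    u = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    s = states[0]
    for t in range(1, length):
        s = np.searchsorted(cum_rows[s], u[t], side="right")
        states[t] = s
    return states


def _states_to_str(states: np.ndarray) -> str:
    return "".join(STATES[s] for s in states)


def simulate_sequence(spec: ChainSpec) -> SequenceRecord:
    """Draw one sequence from the chain; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    states = _draw_states(spec.P.p, spec.initial, spec.length, rng)
    rid = spec.record_id or f"chain-{spec.seed}"
    return SequenceRecord(id=rid, residues=_states_to_str(states))


def evolve_family(root_spec: ChainSpec, guide_tree: PhyloTree,
                  subst_rate: float, seed: int) -> Dataset:
    """Evolve a simulated root sequence along a guide tree.

    Along each branch, every site is substituted independently with
    probability ``1 - exp(-subst_rate * branch_length)``; a substituted
    base becomes one of the other three bases uniformly. Leaf sequences
    are returned as a dataset labelled by the guide tree's taxa, in leaf
    iteration order. The ``seed`` argument drives all randomness
    (including the root simulation; ``root_spec.seed`` is ignored here).
    """
    if not (0.0 < subst_rate):
        raise ValueError("subst_rate must be positive")
    rng = np.random.default_rng(seed)
    root_states = _draw_states(root_spec.P.p, root_spec.initial,
                               root_spec.length, rng)
    states_at: dict[int, np.ndarray] = {id(guide_tree.seed_node): root_states}
    for node in guide_tree.preorder_node_iter():
        if node is guide_tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent_states = states_at[id(node.parent_node)]
        p_sub = 1.0 - np.exp(-subst_rate * bl)
        child = parent_states.copy()
        if p_sub > 0.0:
            mask = rng.random(len(child)) < p_sub
            n_sub = int(mask.sum())
            if n_sub:
                offsets = rng.integers(1, 4, size=n_sub)
                child[mask] = (child[mask] + offsets) % 4
        states_at[id(node)] = child
    records = []
    for leaf in guide_tree.leaf_node_iter():
        records.append(SequenceRecord(id=leaf.taxon.label,
                                      residues=_states_to_str(states_at[id(leaf)])))
    return Dataset(records)


def default_root_chain() -> TransitionMatrix:
    """The A/G-rich root chain used by the bundled family study."""
    return TransitionMatrix(p=_DEFAULT_ROOT_P.copy(), step=1)


def default_family_tree() -> PhyloTree:
    """The balanced 8-leaf guide tree of the bundled family study."""
    return from_newick(_DEFAULT_FAMILY_NEWICK)


def default_family(seed: int, length: int = DEFAULT_FAMILY_LENGTH,
                   rate: float = DEFAULT_FAMILY_RATE,
                   ) -> tuple[Dataset, PhyloTree]:
    """One replicate of the bundled family study: dataset plus guide tree."""
    chain = default_root_chain()
    spec = ChainSpec(P=chain, initial=stationary_distribution(chain),
                     length=length, seed=seed)
    tree = default_family_tree()
    return evolve_family(spec, tree, subst_rate=rate, seed=seed), tree
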