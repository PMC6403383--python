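"""Distance-based tree building: UPGMA and neighbor-joining.

Both methods are implemented natively (no external PHYLIP binary) on top
of :class:`dendropy.Tree` containers, so downstream Newick handling and
topology comparison use a standard library. Agglomeration ties are broken
deterministically by the lowest cluster-index pair, which makes output
byte-reproducible. The PHYLIP matrix writer in :mod:`fisim.io` remains
available for users who want to cross-check against PHYLIP itself.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

from .dmatrix import DistanceMatrix

__all__ = ["PhyloTree", "upgma", "neighbor_joining", "to_newick", "from_newick"]

PhyloTree = dendropy.Tree


def _leaf_nodes(labels: list[str]) -> tuple[dendropy.TaxonNamespace, list[dendropy.Node]]:
    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.new_taxon(lab))
        nodes.append(node)
    return tns, nodes


def _argmin_pair(d: np.ndarray, active: list[int]) -> tuple[int, int]:
    """Lowest-index pair attaining the minimum of d over active clusters."""
    best = None
    best_pair = (active[0], active[1])
    for ai, i in enumerate(active):
        for j in active[ai + 1:]:
            v = d[i, j]
            if best is None or v < best:
                best = v
                best_pair = (i, j)
    return best_pair


def upgma(D: DistanceMatrix) -> PhyloTree:
    """Rooted ultrametric tree by average-linkage agglomeration.

    At each step the two closest clusters are merged (ties: lowest index
    pair); the new node sits at height d/2 and inter-cluster distances
    are size-weighted arithmetic means, the classic UPGMA update. All
    root-to-leaf path lengths are equal by construction.
    """
    n = D.n
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    tns, nodes = _leaf_nodes(D.labels)
    size = 2 * n - 1
    d = np.zeros((size, size))
    d[:n, :n] = D.d
    heights = [0.0] * size
    node_of: list[dendropy.Node | None] = list(nodes) + [None] * (n - 1)
    cluster_size = [1] * n + [0] * (n - 1)
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = _argmin_pair(d, active)
        h = d[i, j] / 2.0
        parent = dendropy.Node()
        for child_idx in (i, j):
            child = node_of[child_idx]
            child.edge.length = h - heights[child_idx]
            parent.add_child(child)
        node_of[nxt] = parent
        heights[nxt] = h
        cluster_size[nxt] = cluster_size[i] + cluster_size[j]
        for m in active:
            if m in (i, j):
                continue
            v = (cluster_size[i] * d[i, m] + cluster_size[j] * d[j, m]) / \
                (cluster_size[i] + cluster_size[j])
            d[nxt, m] = d[m, nxt] = v
        # merged cluster takes the lower index's position (PHYLIP convention)
        active = [nxt if m == i else m for m in active if m != j]
        nxt += 1
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=node_of[active[0]])
    tree.is_rooted = True
    return tree


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Unrooted tree by the Saitou-Nei neighbor-joining algorithm.

    Standard Q-criterion with the same lowest-index tie-breaking as
    :func:`upgma`. On additive input the generating tree is recovered
    exactly. Negative branch lengths (possible on non-additive input)
    are clamped to zero with a warning.
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns, nodes = _leaf_nodes(D.labels)
    dist: dict[tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = float(D.d[a, b])

    def dget(a: int, b: int) -> float:
        if a == b:
            return 0.0
        return dist[(a, b)] if a < b else dist[(b, a)]

    def set_length(node: dendropy.Node, length: float) -> None:
        if length < 0.0:
            warnings.warn(
                f"negative branch length {length:.6g} clamped to 0",
                stacklevel=3,
            )
            length = 0.0
        node.edge.length = length

    node_of: dict[int, dendropy.Node] = dict(enumerate(nodes))
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(dget(i, m) for m in active) for i in active}
        best = None
        best_pair = (active[0], active[1])
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * dget(i, j) - row_sum[i] - row_sum[j]
                if best is None or q < best:
                    best = q
                    best_pair = (i, j)
        i, j = best_pair
        dij = dget(i, j)
        li = dij / 2.0 + (row_sum[i] - row_sum[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        set_length(node_of[i], li)
        set_length(node_of[j], lj)
        parent.add_child(node_of[i])
        parent.add_child(node_of[j])
        for m in active:
            if m in (i, j):
                continue
            v = (dget(i, m) + dget(j, m) - dij) / 2.0
            key = (m, nxt) if m < nxt else (nxt, m)
            dist[key] = v
        node_of[nxt] = parent
        active = [nxt if m == i else m for m in active if m != j]
        nxt += 1
    # resolve the last three clusters around a central node (three-point)
    a, b, c = active
    la = (dget(a, b) + dget(a, c) - dget(b, c)) / 2.0
    lb = dget(a, b) - la
    lc = dget(a, c) - la
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        set_length(node_of[idx], length)
        center.add_child(node_of[idx])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def to_newick(tree: PhyloTree, precision: int = 6,
              space_policy: str = "underscore") -> str:
    """Serialise a tree to a one-line Newick string with branch lengths.

    ``space_policy`` controls labels containing spaces: ``"underscore"``
    rewrites them with underscores, ``"quote"`` leaves quoting to the
    Newick writer.
    """
    if space_policy not in ("underscore", "quote"):
        raise ValueError(f"unknown space_policy {space_policy!r}")
    out = tree.clone(depth=1)
    if space_policy == "underscore":
        # clone shares the taxon namespace; relabel private taxa instead
        out.taxon_namespace = dendropy.TaxonNamespace()
        for node in out:
            if node.taxon is not None:
                node.taxon = out.taxon_namespace.new_taxon(
                    node.taxon.label.replace(" ", "_"))
    s = out.as_string(schema="newick",
                      real_value_format_specifier=f".{precision}f",
                      suppress_rooting=True,
                      preserve_spaces=(space_policy == "quote"))
    return s.strip()


def from_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick string (or path to a file) into a tree."""
    text = str(source)
    if "(" not in text and Path(text).exists():
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             taxon_namespace=dendropy.TaxonNamespace())
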