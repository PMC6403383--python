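"""Assessment instruments: Robinson-Foulds distance and distance-matrix ROC.

The RF distance counts bipartitions present in exactly one of two
unrooted trees on the same leaf set; zero means identical topology.

The ROC construction scores every unordered taxon pair by similarity
(one minus distance) and treats within-group pairs as positives under a
user-supplied taxon-to-group mapping; the curve comes from a threshold
sweep and the AUC from the trapezoid rule, which with midpoint tie
handling equals the normalised Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .dmatrix import DistanceMatrix
from .tree import PhyloTree

__all__ = ["LabeledPairs", "labeled_pairs", "rf_distance", "roc_auc",
           "read_groups_tsv"]


@dataclass
class LabeledPairs:
    """All unordered taxon pairs with their distance and group agreement."""

    pairs: list[tuple[str, str, float, bool]]

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, same in self.pairs if same)

    @property
    def n_negative(self) -> int:
        return sum(1 for *_, same in self.pairs if not same)


def labeled_pairs(D: DistanceMatrix, groups: dict[str, str]) -> LabeledPairs:
    """Expand a distance matrix into labelled pairs for ROC analysis."""
    missing = [lab for lab in D.labels if lab not in groups]
    if missing:
        raise ValueError(f"taxa missing from the group map: {missing}")
    pairs = []
    for a in range(D.n):
        for b in range(a + 1, D.n):
            la, lb = D.labels[a], D.labels[b]
            pairs.append((la, lb, float(D.d[a, b]), groups[la] == groups[lb]))
    return LabeledPairs(pairs)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition) distance.

    Rooted input trees are compared as unrooted; branch lengths are
    ignored. Raises ``ValueError`` on differing leaf sets.
    """
    labels1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    labels2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(labels1 - labels2)}, "
            f"only in second {sorted(labels2 - labels1)}"
        )
    tns = dendropy.TaxonNamespace()
    c1 = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    c2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    c1.is_rooted = False
    c2.is_rooted = False
    c1.encode_bipartitions()
    c2.encode_bipartitions()
    return int(treecompare.symmetric_difference(c1, c2))


def roc_auc(D: DistanceMatrix, groups: dict[str, str],
            ) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for recovering group co-membership from distances.

    Pairs are scored by similarity ``1 - d``; positives are within-group
    pairs. Returns ``(points, auc)`` where ``points`` is an array of
    (false positive rate, true positive rate) vertices.
    """
    lp = labeled_pairs(D, groups)
    if lp.n_positive == 0 or lp.n_negative == 0:
        raise ValueError(
            "ROC needs at least one within-group and one cross-group pair"
        )
    y = np.array([same for *_, same in lp.pairs], dtype=int)
    scores = np.array([1.0 - d for _, _, d, _ in lp.pairs])
    fpr, tpr, _ = _roc_curve(y, scores)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (taxon, group) TSV into a mapping."""
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        taxon, group = parts
        if taxon in groups:
            raise ValueError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
        groups[taxon] = group
    if not groups:
        raise ValueError(f"no group assignments found in {path}")
    return groups
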