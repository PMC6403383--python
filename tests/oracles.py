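"""Independent reference implementations used only to check the package.

Everything here deliberately takes a different computational route from
the library: polynomial root finding instead of bisection for lambda, the
closed-form lambda-measure of arbitrary subsets plus exhaustive subset
enumeration instead of the sorted-cumulative recursion for the Sugeno
integral, naive loops instead of vectorised counting, and repeated naive
multiplication for matrix powers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

STATE_ORDER = "ATGC"


def random_stochastic_matrix(rng: np.random.Generator) -> np.ndarray:
    p = rng.random((4, 4))
    return p / p.sum(axis=1, keepdims=True)


def lambda_root_oracle(mu) -> float:
    """Normalising lambda via the cubic's polynomial roots.

    prod_j (1 + lam mu_j) = 1 + lam expands to
    lam * (e4 lam^3 + e3 lam^2 + e2 lam + (e1 - 1)) = 0 with e_m the
    elementary symmetric polynomials of the densities. The non-trivial
    root in (-1, 0) (sum > 1) or (0, inf) (sum < 1) is returned; if only
    the trivial roots 0 and -1 exist the degenerate fallback is 0.
    """
    m = [float(x) for x in mu]
    e1 = sum(m)
    e2 = sum(a * b for a, b in itertools.combinations(m, 2))
    e3 = sum(a * b * c for a, b, c in itertools.combinations(m, 3))
    e4 = m[0] * m[1] * m[2] * m[3]
    if abs(e1 - 1.0) <= 1e-9:
        return 0.0
    roots = np.roots([e4, e3, e2, e1 - 1.0])
    real = [r.real for r in roots if abs(r.imag) < 1e-9]
    if e1 > 1.0:
        cands = [r for r in real if -1.0 + 1e-9 < r < -1e-12]
    else:
        cands = [r for r in real if r > 1e-12]
    if not cands:
        return 0.0
    return min(cands, key=abs)


def lambda_measure_of_subset(subset, mu, lam) -> float:
    """mu_lambda(A) from singleton densities, closed form, clamped to 1."""
    if not subset:
        return 0.0
    if lam == 0.0:
        val = sum(mu[j] for j in subset)
    else:
        prod = 1.0
        for j in subset:
            prod *= 1.0 + lam * mu[j]
        val = (prod - 1.0) / lam
    return min(1.0, max(0.0, val))


def sugeno_subset_oracle(h, mu) -> float:
    """Sugeno integral as a max over all 2^4 subsets.

    sup_A min( min_{j in A} h_j, mu_lambda(A) ) over non-empty subsets A.
    """
    lam = lambda_root_oracle(mu)
    best = 0.0
    for r in range(1, 5):
        for subset in itertools.combinations(range(4), r):
            v = min(min(h[j] for j in subset),
                    lambda_measure_of_subset(subset, mu, lam))
            best = max(best, v)
    return best


def naive_matrix_power(p: np.ndarray, k: int) -> np.ndarray:
    out = np.array(p, dtype=float)
    for _ in range(k - 1):
        nxt = np.zeros_like(out)
        for i in range(4):
            for j in range(4):
                nxt[i, j] = sum(out[i, r] * p[r, j] for r in range(4))
        out = nxt
    return out


def naive_counts(sequence: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(STATE_ORDER)}
    counts = np.zeros((4, 4))
    for a, b in zip(sequence, sequence[1:]):
        counts[idx[a], idx[b]] += 1
    return counts


def naive_transition(sequence: str) -> np.ndarray:
    counts = naive_counts(sequence)
    p = np.empty((4, 4))
    for i in range(4):
        tot = counts[i].sum()
        p[i] = counts[i] / tot if tot > 0 else 0.25
    return p


def oracle_pair_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Full fuzzy distance between two stochastic matrices, oracle route."""
    best = 0.0
    for i in range(4):
        h = [1.0 - abs(p1[i, j] - p2[i, j]) for j in range(4)]
        mu = [max(p1[i, j], p2[i, j]) for j in range(4)]
        best = max(best, sugeno_subset_oracle(h, mu))
    return 1.0 - best


def oracle_distance_matrix(sequences: list[str], k: int) -> np.ndarray:
    """Counts -> 1-step estimate -> naive power -> pairwise oracle distance."""
    mats = [naive_matrix_power(naive_transition(s), k) for s in sequences]
    n = len(sequences)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = oracle_pair_distance(mats[a], mats[b])
    return d


def naive_rmsd(d1: np.ndarray, d2: np.ndarray) -> float:
    n = d1.shape[0]
    acc, cnt = 0.0, 0
    for a in range(n):
        for b in range(a + 1, n):
            acc += (d1[a, b] - d2[a, b]) ** 2
            cnt += 1
    return math.sqrt(acc / cnt)


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """AUC by exhaustive positive/negative comparison with midpoint ties."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def random_ultrametric(labels, rng: np.random.Generator):
    """Random clock-like tree: returns (newick, distance ndarray).

    Clusters are merged in random order at strictly increasing heights;
    the pairwise distance is twice the height of the lowest common
    ancestor, which is exactly the matrix UPGMA must invert.
    """
    n = len(labels)
    clusters = [(lab, 0.0, {lab}) for lab in labels]  # (newick, height, members)
    height = 0.0
    dist = {}
    while len(clusters) > 1:
        height += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (nwk_i, h_i, mem_i) = clusters[i]
        (nwk_j, h_j, mem_j) = clusters[j]
        for a in mem_i:
            for b in mem_j:
                dist[frozenset((a, b))] = 2.0 * height
        merged = (f"({nwk_i}:{height - h_i},{nwk_j}:{height - h_j})",
                  height, mem_i | mem_j)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = dist[frozenset((labels[a], labels[b]))]
    return clusters[0][0] + ";", d


def random_additive(labels, rng: np.random.Generator):
    """Random binary tree with positive edge lengths and its path metric."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(lab)) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.1, 1.0))
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tns}
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = pdm.patristic_distance(taxa[labels[a]],
                                                       taxa[labels[b]])
    return tree, d
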