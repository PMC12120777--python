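"""Phylogenetic-signal diagnostics for niche breadth.

Blomberg's K compares the observed ratio of trait variance (around the
phylogenetically corrected mean) to its Brownian-motion expectation on the
given tree; K = 1 is the Brownian calibration, K near 0 indicates a random
or convergent pattern, K > 1 stronger-than-Brownian conservatism.
Significance comes from tip-label permutations of the variance of
phylogenetically independent contrasts (lower observed contrast variance
than permuted values indicates signal).

A Mantel-style matrix correlation between phylogenetic distance and pairwise
niche-breadth differences is provided as a complementary, tree-metric-free
diagnostic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloSignalResult",
    "tree_covariance",
    "pic_contrast_matrix",
    "blomberg_k",
    "distance_breadth_correlation",
]

#: Relative perturbation applied to zero-length branches (× tree height).
ZERO_BRANCH_EPS = 1e-8


@dataclass
class PhyloSignalResult:
    k: float
    p_perm: float
    n_tips: int
    n_permutations: int
    seed: int


def _prepare_tree(tree: dendropy.Tree, taxa: list[str]) -> dendropy.Tree:
    """Clone, prune to the trait taxa, resolve polytomies, fix zero branches."""
    work = tree.clone(depth=1)
    labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    if set(taxa) != labels:
        work.retain_taxa_with_labels(taxa)
    # multifurcations are resolved arbitrarily with zero-length branches,
    # which the perturbation below then makes invertible
    work.resolve_polytomies()
    height = max(
        leaf.distance_from_root() for leaf in work.leaf_node_iter()
    )
    if height <= 0:
        raise ValueError("tree has zero height: all branch lengths are zero")
    eps = ZERO_BRANCH_EPS * height
    perturbed = 0
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps
            perturbed += 1
    if perturbed:
        warnings.warn(
            f"perturbed {perturbed} zero-length branch(es) by {eps:g}", stacklevel=3
        )
    return work


def tree_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length per tip pair."""
    work = _prepare_tree(tree, taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    v = np.zeros((n, n))
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in work.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        length = node.edge.length or 0.0
        depth[id(node)] = parent_depth + (length if node.parent_node is not None else 0.0)
    for node in work.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[id(node)] = [i]
            v[i, i] = depth[id(node)]
        else:
            children = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a, b in itertools.combinations(children, 2):
                for i in a:
                    for j in b:
                        v[i, j] = v[j, i] = d
            below[id(node)] = [i for sub in children for i in sub]
    return v


def pic_contrast_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Linear map from tip values to phylogenetically independent contrasts.

    Contrasts are linear in the tip values with tree-only weights, so the
    (n−1) × n matrix returned here lets contrast variances be recomputed for
    thousands of tip-label permutations at negligible cost.
    """
    work = _prepare_tree(tree, taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    rows: list[np.ndarray] = []
    coef: dict[int, np.ndarray] = {}
    length: dict[int, float] = {}
    for node in work.postorder_node_iter():
        edge = node.edge.length or 0.0
        if node.is_leaf():
            e = np.zeros(n)
            e[index[node.taxon.label]] = 1.0
            coef[id(node)] = e
            length[id(node)] = edge
        else:
            children = node.child_nodes()
            assert len(children) == 2  # guaranteed by resolve_polytomies
            a, b = children
            va, vb = length[id(a)], length[id(b)]
            ca, cb = coef[id(a)], coef[id(b)]
            rows.append((ca - cb) / math.sqrt(va + vb))
            coef[id(node)] = (vb * ca + va * cb) / (va + vb)
            length[id(node)] = edge + va * vb / (va + vb)
    return np.vstack(rows)


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PhyloSignalResult:
    """Blomberg's K with a permutation test on the variance of contrasts.

    The trait is matched to tree tips by label. Requires n >= 4 tips and a
    non-constant trait. The permutation p-value is
    ``(1 + #{var_perm <= var_obs}) / (1 + n_perm)``.
    """
    trait = trait.dropna()
    taxa = list(trait.index.astype(str))
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 tips with trait values")
    x = trait.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    v = tree_covariance(tree, taxa)
    ones = np.ones(n)
    try:
        vinv_x = np.linalg.solve(v, x)
        vinv_1 = np.linalg.solve(v, ones)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance (zero-length cherry?)") from exc
    sum_vinv = ones @ vinv_1
    a_hat = (ones @ vinv_x) / sum_vinv
    resid = x - a_hat
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ np.linalg.solve(v, resid)) / (n - 1)
    observed = mse0 / mse
    expected = (np.trace(v) - n / sum_vinv) / (n - 1)
    k = observed / expected

    contrasts = pic_contrast_matrix(tree, taxa)
    var_obs = float(np.mean((contrasts @ x) ** 2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        if float(np.mean((contrasts @ xp) ** 2)) <= var_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return PhyloSignalResult(
        k=float(k), p_perm=float(p), n_tips=n, n_permutations=n_perm, seed=seed
    )


def _patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in by_label]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                by_label[taxa[i]], by_label[taxa[j]]
            )
    return d


def distance_breadth_correlation(
    tree_or_matrix,
    breadth: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Matrix correlation of phylogenetic distance with |Δ niche breadth|.

    A Mantel-style test: Pearson correlation over the upper triangles, with
    significance from permuting taxa labels of the breadth-difference
    matrix, ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``. With
    ``exhaustive=True`` all n! label permutations are enumerated and the
    identity counts once in the numerator and denominator.
    """
    breadth = breadth.dropna()
    taxa = list(breadth.index.astype(str))
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if isinstance(tree_or_matrix, dendropy.Tree):
        d_phylo = _patristic_matrix(tree_or_matrix, taxa)
    else:
        d_phylo = (
            tree_or_matrix.loc[taxa, taxa].to_numpy(dtype=float)
            if isinstance(tree_or_matrix, pd.DataFrame)
            else np.asarray(tree_or_matrix, dtype=float)
        )
        if d_phylo.shape != (n, n) or not np.allclose(d_phylo, d_phylo.T):
            raise ValueError("distance matrix must be square and symmetric")
    b = breadth.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    xv = d_phylo[iu]
    if np.ptp(xv) == 0:
        raise ValueError("constant phylogenetic distances")
    xc = xv - xv.mean()
    xnorm = math.sqrt(xc @ xc)

    def _r(vals: np.ndarray) -> float:
        diff = np.abs(vals[:, None] - vals[None, :])[iu]
        yc = diff - diff.mean()
        ynorm = math.sqrt(yc @ yc)
        if ynorm == 0:
            return 0.0
        return float((xc @ yc) / (xnorm * ynorm))

    r_obs = _r(b)
    if exhaustive:
        rs = np.array([_r(b[list(perm)]) for perm in itertools.permutations(range(n))])
        p = float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if abs(_r(rng.permutation(b))) >= abs(r_obs) - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, p
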