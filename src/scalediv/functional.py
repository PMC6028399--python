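"""Functional trait space: Gower distances, UPGMA dendrogram, and
occupancy-weighted functional diversity (FD).

The trait space has three categories — body mass, diet (7 proportions) and
foraging niche (7 proportions) — combined with a weighted Gower distance in
which each category carries total weight 1 (mass weight 1; each of the seven
axes in a category weight 1/7).  A master ultrametric dendrogram is built
once with UPGMA (average linkage) over the full species pool and reused for
every assemblage.

FD of an assemblage with occupancy probabilities ``psi`` is the
probability-weighted total branch length: each branch contributes its length
times ``1 - prod_{i in I}(1 - psi_i)``, where I is the set of leaves below
the branch.  For a terminal branch this reduces to ``length * psi_i``; a
branch whose descendants all have psi = 0 contributes nothing, which is
exactly the prune-and-collapse rule (collapsing sums branch lengths, and the
surviving descendant's weight carries through unchanged).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthetic import DIET_AXES, FORAGING_AXES


def default_gower_weights(log_mass: bool = True) -> dict:
    """Category-balanced Gower weights: mass 1, each diet/foraging axis 1/7."""
    w = {("log_body_mass" if log_mass else "body_mass_g"): 1.0}
    for ax in DIET_AXES + FORAGING_AXES:
        w[ax] = 1.0 / 7.0
    return w


def gower_distance(traits: pd.DataFrame, weights=None, log_mass: bool = True) -> pd.DataFrame:
    """Weighted Gower dissimilarity over quantitative trait axes.

    d(x, y) = sum_k w_k |x_k - y_k| / range_k / sum_k w_k, with each axis
    range taken over the full species pool.  Body mass enters on the log
    scale by default (configurable off), preventing the heavy right tail of
    the mass distribution from dominating its axis.  Axes with zero range are
    dropped with a warning (they carry no information).
    """
    df = traits.set_index("species_id") if "species_id" in traits.columns else traits.copy()
    if log_mass:
        df = df.assign(log_body_mass=np.log(df["body_mass_g"]))
    if weights is None:
        weights = default_gower_weights(log_mass=log_mass)
    cols, w = [], []
    for axis, wt in weights.items():
        rng = df[axis].max() - df[axis].min()
        if rng <= 0 or not np.isfinite(rng):
            warnings.warn(f"trait axis {axis!r} has zero range; dropped from Gower distance")
            continue
        cols.append(df[axis].to_numpy(dtype=float) / rng)
        w.append(wt)
    if not cols:
        raise ValueError("no informative trait axes")
    X = np.column_stack(cols)
    w = np.asarray(w)
    diff = np.abs(X[:, None, :] - X[None, :, :])
    d = (diff * w).sum(axis=2) / w.sum()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass
class FunctionalDendrogram:
    """Rooted tree with branch lengths; leaves are species.

    Stored flat: ``parent[i]`` is the parent node of node i (root has -1),
    ``length[i]`` the branch length above node i, ``leafsets[i]`` the indices
    (into ``leaf_names``) of leaves descending from node i.
    """

    parent: np.ndarray
    length: np.ndarray
    leaf_names: list
    leafsets: list  # list of np.ndarray of leaf indices, per node
    heights: np.ndarray | None = None  # node height above leaves (ultrametric trees)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def total_branch_length(self) -> float:
        return float(self.length[self.length > 0].sum()) if len(self.length) else 0.0

    # -------------------------------------------------------------- builders
    @classmethod
    def from_linkage(cls, Z: np.ndarray, leaf_names) -> "FunctionalDendrogram":
        """From a scipy linkage matrix; merge height = half the linkage distance."""
        n = len(leaf_names)
        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=int)
        height = np.zeros(n_nodes)
        leafsets = [np.array([i]) for i in range(n)]
        for m, (a, b, dist, _) in enumerate(Z):
            node = n + m
            a, b = int(a), int(b)
            parent[a] = parent[b] = node
            height[node] = dist / 2.0  # ultrametric height
            leafsets.append(np.concatenate([leafsets[a], leafsets[b]]))
        length = np.zeros(n_nodes)
        for i in range(n_nodes - 1):
            length[i] = height[parent[i]] - height[i]
        return cls(
            parent=parent,
            length=length,
            leaf_names=list(leaf_names),
            leafsets=leafsets,
            heights=height,
        )

    @classmethod
    def from_newick(cls, newick: str) -> "FunctionalDendrogram":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        leaf_names, leaf_idx = [], {}
        for nd in nodes:
            if nd.is_leaf():
                leaf_idx[id(nd)] = len(leaf_names)
                leaf_names.append(nd.taxon.label if nd.taxon else "")
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        leafsets = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            length[i] = nd.edge.length or 0.0
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.is_leaf():
                leafsets[i] = np.array([leaf_idx[id(nd)]])
            else:
                leafsets[i] = np.concatenate([leafsets[index[id(c)]] for c in nd.child_nodes()])
        return cls(parent=parent, length=length, leaf_names=leaf_names, leafsets=leafsets)

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        root = None
        for i, p in enumerate(self.parent):
            if p == -1:
                root = i
            else:
                children.setdefault(p, []).append(i)

        def rec(i):
            if i not in children:
                return f"{self.leaf_names[self.leafsets[i][0]]}:{self.length[i]:.10g}"
            inner = ",".join(rec(c) for c in children[i])
            if self.parent[i] == -1:
                return f"({inner});"
            return f"({inner}):{self.length[i]:.10g}"

        return rec(root)

    # ------------------------------------------------------------ invariants
    def is_ultrametric(self, tol=1e-8) -> bool:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(p, []).append(i)
        depth = np.zeros(len(self.parent))
        order = [i for i in range(len(self.parent)) if self.parent[i] == -1]
        leaf_depths = []
        while order:
            i = order.pop()
            for c in children.get(i, []):
                depth[c] = depth[i] + self.length[c]
                order.append(c)
            if i not in children:
                leaf_depths.append(depth[i])
        return np.ptp(leaf_depths) <= tol if leaf_depths else True

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Tree-implied pairwise distances between leaves."""
        n = self.n_leaves
        depth_to_root = np.zeros(len(self.parent))
        for i in range(len(self.parent)):
            j, d = i, 0.0
            while self.parent[j] != -1:
                d += self.length[j]
                j = self.parent[j]
            depth_to_root[i] = d
        leaf_node = {self.leafsets[i][0]: i for i in range(len(self.parent)) if len(self.leafsets[i]) == 1}
        D = np.zeros((n, n))
        for i in range(len(self.parent)):
            ls = self.leafsets[i]
            if len(ls) < 2:
                continue
            # pairs first united at this node
            kids = [k for k in range(len(self.parent)) if self.parent[k] == i]
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    for la in self.leafsets[kids[a_i]]:
                        for lb in self.leafsets[kids[b_i]]:
                            d = (
                                depth_to_root[leaf_node[la]]
                                + depth_to_root[leaf_node[lb]]
                                - 2.0 * depth_to_root[i]
                            )
                            D[la, lb] = D[lb, la] = d
        return pd.DataFrame(D, index=self.leaf_names, columns=self.leaf_names)


def upgma_tree(dist: pd.DataFrame) -> FunctionalDendrogram:
    """Average-linkage (UPGMA) dendrogram from a pairwise distance matrix.

    Species are ordered lexicographically before clustering so tie-breaking
    is deterministic across platforms.  Merge heights are half the average
    inter-cluster distance, giving an ultrametric tree.
    """
    labels = sorted(dist.index)
    d = dist.loc[labels, labels].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if len(labels) < 2:
        raise ValueError("need at least 2 species")
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return FunctionalDendrogram.from_linkage(Z, labels)


def cophenetic_correlation(tree: FunctionalDendrogram, dist: pd.DataFrame) -> float:
    """Pearson correlation between original and tree-implied distances."""
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("cophenetic correlation undefined for n < 3")
    C = tree.cophenetic_matrix().loc[labels, labels].to_numpy()
    D = dist.to_numpy(dtype=float)
    iu = np.triu_indices(len(labels), 1)
    return float(np.corrcoef(D[iu], C[iu])[0, 1])


def functional_diversity(tree: FunctionalDendrogram, psi) -> float:
    """Occupancy-weighted FD: sum over branches of length * (1 - prod(1 - psi)).

    ``psi`` may be an array aligned to ``tree.leaf_names`` or a mapping/Series
    keyed by species.  Values outside [0, 1] raise; all-zero psi gives FD = 0
    with a warning.
    """
    if isinstance(psi, (pd.Series, dict)):
        psi = pd.Series(psi).reindex(tree.leaf_names).to_numpy(dtype=float)
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (tree.n_leaves,):
        raise ValueError("psi must align with tree leaves")
    if np.any((psi < 0) | (psi > 1) | ~np.isfinite(psi)):
        raise ValueError("psi must lie in [0, 1]")
    if np.all(psi == 0):
        warnings.warn("all occupancy probabilities are zero; FD = 0")
        return 0.0
    with np.errstate(divide="ignore"):
        log1m = np.log1p(-psi)  # -inf where psi == 1; guarded below
    fd = 0.0
    for i in range(len(tree.parent)):
        if tree.parent[i] == -1 or tree.length[i] == 0:
            continue
        ls = tree.leafsets[i]
        if np.any(psi[ls] >= 1.0):
            w = 1.0
        else:
            w = -np.expm1(log1m[ls].sum())
        fd += tree.length[i] * w
    return float(fd)


def functional_diversity_many(tree: FunctionalDendrogram, psi_matrix: pd.DataFrame) -> pd.Series:
    """FD for each column (assemblage) of a species x assemblage psi matrix."""
    vals = {}
    for col in psi_matrix.columns:
        vals[col] = functional_diversity(tree, psi_matrix[col])
    return pd.Series(vals, name="FD")
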