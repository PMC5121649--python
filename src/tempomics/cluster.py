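"""Agglomerative clustering with silhouette-based group-number selection.

Two-tier time-series clustering addresses a blind spot of spectral
distances: a periodogram is phaseless, so a series and its sign-flipped
copy have identical spectra.  Tier 1 therefore clusters components by the
euclidean distance between their (variance-normalized) periodograms, and
tier 2 re-clusters each tier-1 group on the original series with a
correlation distance computed over pairwise-complete time points, which
separates correlated from anti-correlated members.

The number of groups at every tier is chosen automatically: the tree is
cut at each candidate k and the k maximizing the mean silhouette width
(computed with the same metric the tree was built with) wins, ties going
to the smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .omics import OmicsInputError, TimeSeriesSet

__all__ = [
    "ClusterTree",
    "Grouping",
    "pairwise_distances",
    "linkage",
    "auto_groups",
    "two_tier_clusters",
    "single_tier_clusters",
    "matrix_biclusters",
]


@dataclass
class ClusterTree:
    """Agglomerative merge history plus the distance matrix it was built on."""

    Z: np.ndarray  # scipy linkage matrix
    labels: list
    metric: str
    method: str
    dmat: np.ndarray  # square pairwise distance matrix

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.Z)]

    def to_newick(self) -> str:
        """Serialize the tree in Newick format (branch lengths = merge
        height differences)."""
        tree = hierarchy.to_tree(self.Z)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _pairwise_correlation_distance(X: np.ndarray, labels) -> np.ndarray:
    """1 - Pearson correlation over pairwise-complete (non-NaN) entries.

    Pairs with undefined correlation (zero variance on the common support)
    get distance 0 if the common vectors are identical, else 1.
    """
    n = X.shape[0]
    for i in range(n):
        if np.sum(~np.isnan(X[i])) < 2:
            raise OmicsInputError(
                f"component {labels[i]!r} has < 2 observed features; "
                "correlation distance undefined"
            )
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if ok.sum() < 2:
                raise OmicsInputError(
                    f"components {labels[i]!r} and {labels[j]!r} share < 2 "
                    "observed features"
                )
            a, b = X[i, ok], X[j, ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                d = 0.0 if np.allclose(a, b) else 1.0
            else:
                d = 1.0 - float(np.corrcoef(a, b)[0, 1])
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def pairwise_distances(X: np.ndarray, metric: str, labels=None) -> np.ndarray:
    labels = labels if labels is not None else list(range(X.shape[0]))
    if metric == "euclidean":
        if np.isnan(X).any():
            raise OmicsInputError(
                "euclidean metric does not accept missing entries; use the "
                "correlation metric (pairwise-complete) or filter first"
            )
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff * diff).sum(axis=2))
    if metric == "correlation":
        return _pairwise_correlation_distance(X, labels)
    raise OmicsInputError(f"unknown metric {metric!r}")


def linkage(
    matrix: np.ndarray,
    metric: str = "euclidean",
    method: str = "average",
    labels=None,
) -> ClusterTree:
    """Hierarchical agglomerative clustering of matrix rows.

    Deterministic given the input order; scipy breaks height ties by the
    order pairs appear in the condensed distance matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise OmicsInputError("linkage needs a 2-D matrix with >= 2 rows")
    if method not in ("average", "complete", "ward"):
        raise OmicsInputError(f"unknown linkage method {method!r}")
    labels = list(labels) if labels is not None else [str(i) for i in range(X.shape[0])]
    D = pairwise_distances(X, metric, labels)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    return ClusterTree(Z, labels, metric, method, D)


@dataclass
class Grouping:
    """Partition of components into groups (and optional subgroups)."""

    groups: dict  # component -> group id (1-based)
    subgroups: dict = field(default_factory=dict)  # component -> subgroup id
    silhouettes: dict = field(default_factory=dict)  # k -> mean silhouette
    chosen_k: int = 1
    tree: ClusterTree | None = None
    subtrees: dict = field(default_factory=dict)  # group id -> ClusterTree
    subgroup_silhouettes: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def members(self, group: int) -> list:
        return [c for c, g in self.groups.items() if g == group]

    def to_frame(self):
        import pandas as pd

        comps = list(self.groups)
        return pd.DataFrame(
            {
                "component": comps,
                "group": [self.groups[c] for c in comps],
                "subgroup": [self.subgroups.get(c, 1) for c in comps],
            }
        )


def _renumber(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster ids to 1..k in order of first appearance."""
    seen: dict = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        seen.setdefault(v, len(seen) + 1)
        out[i] = seen[v]
    return out


def auto_groups(tree: ClusterTree, k_range=None) -> Grouping:
    """Cut the tree at each candidate k and keep the k with the best mean
    silhouette width (same metric as the tree; ties -> smaller k)."""
    n = len(tree.labels)
    if n < 3:
        warnings.warn("fewer than 3 components; returning a single group")
        return Grouping(
            {lab: 1 for lab in tree.labels}, chosen_k=1, tree=tree
        )
    if k_range is None:
        k_range = range(2, min(8, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise OmicsInputError("empty k_range after clipping to [2, n-1]")
    best_k, best_score, best_labels = None, -np.inf, None
    sils = {}
    if np.allclose(tree.dmat, 0.0):
        warnings.warn("all pairwise distances are zero; returning one group")
        return Grouping({lab: 1 for lab in tree.labels}, chosen_k=1, tree=tree)
    for k in sorted(k_range):
        flat = hierarchy.fcluster(tree.Z, t=k, criterion="maxclust")
        if len(set(flat)) < 2:
            continue
        score = float(silhouette_score(tree.dmat, flat, metric="precomputed"))
        sils[k] = score
        if score > best_score:
            best_k, best_score, best_labels = k, score, flat
    if best_labels is None:
        warnings.warn("no cut produced >= 2 clusters; returning one group")
        return Grouping({lab: 1 for lab in tree.labels}, chosen_k=1, tree=tree,
                        silhouettes=sils)
    if best_score < 0.25:
        warnings.warn(
            f"weak cluster structure (best mean silhouette {best_score:.2f})"
        )
    flat = _renumber(best_labels)
    return Grouping(
        {lab: int(g) for lab, g in zip(tree.labels, flat)},
        silhouettes=sils,
        chosen_k=int(best_k),
        tree=tree,
    )


def two_tier_clusters(
    tss: TimeSeriesSet, periodograms: dict, k_range=None
) -> Grouping:
    """Tier 1: euclidean clustering of periodogram vectors; tier 2:
    correlation-distance clustering of the original series within each
    tier-1 group (assessing directionality in real space).

    Tier-1 groups with fewer than 3 members are left as a single subgroup.
    """
    comps = [c for c in tss.series if c in periodograms]
    if len(comps) < 2:
        raise OmicsInputError("two-tier clustering needs >= 2 components")
    lengths = {len(periodograms[c].power) for c in comps}
    if len(lengths) != 1:
        raise OmicsInputError("periodograms must share one frequency grid")
    P = np.vstack([periodograms[c].power for c in comps])
    tier1 = auto_groups(linkage(P, "euclidean", "average", comps), k_range)
    grouping = Grouping(
        groups=dict(tier1.groups),
        silhouettes=tier1.silhouettes,
        chosen_k=tier1.chosen_k,
        tree=tier1.tree,
    )
    for g in sorted(set(tier1.groups.values())):
        members = tier1.members(g)
        if len(members) < 3:
            for c in members:
                grouping.subgroups[c] = 1
            continue
        X = np.vstack([tss.series[c] for c in members])
        subtree = linkage(X, "correlation", "average", members)
        sub = auto_groups(subtree, k_range)
        grouping.subtrees[g] = subtree
        grouping.subgroup_silhouettes[g] = sub.silhouettes
        for c in members:
            grouping.subgroups[c] = sub.groups[c]
    return grouping


def single_tier_clusters(tss: TimeSeriesSet, k_range=None) -> Grouping:
    """One clustering of the original series with correlation distance."""
    comps = list(tss.series)
    if len(comps) < 2:
        raise OmicsInputError("clustering needs >= 2 components")
    X = np.vstack([tss.series[c] for c in comps])
    return auto_groups(linkage(X, "correlation", "average", comps), k_range)


def matrix_biclusters(matrix: np.ndarray, k_range=None,
                      row_labels=None, col_labels=None) -> tuple:
    """Independent clustering of matrix rows and columns (euclidean,
    average linkage, silhouette-chosen k for each direction)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise OmicsInputError("matrix biclustering needs >= 2 rows and columns")
    rows = auto_groups(linkage(X, "euclidean", "average", row_labels), k_range)
    cols = auto_groups(linkage(X.T, "euclidean", "average", col_labels), k_range)
    return rows, cols
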