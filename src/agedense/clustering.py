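"""Ward-linkage hierarchical clustering of age-density vectors.

Ward's minimum-variance criterion merges, at each step, the pair of clusters
whose union least increases the total within-cluster sum of squared
Euclidean distances to centroids.  Merge heights here are that cost itself
(ΔSSE, squared-distance units), maintained with the Lance–Williams
recurrence; scipy's dendrogram convention stores sqrt(2·ΔSSE) instead, and
:meth:`LinkageTree.to_scipy` converts.  Ties are broken by the smallest
(left id, right id) pair so results are platform-stable.

Model selection uses the elbow of the within-cluster distance curve W(k):
k* maximizes the discrete second difference of log W(k) over interior k.
The log scale makes the curvature scale-invariant, so the elbow lands at
the true cluster count even when between-cluster separations are very
unequal — with the absolute second difference, the first splits of a few
far-flung clusters dominate the curvature and drag k* down.  The full curve
is returned so callers can override k*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import DataError

__all__ = [
    "LinkageTree",
    "ClusterAssignment",
    "ElbowCurve",
    "euclidean_distance",
    "ward_linkage",
    "cut_tree",
    "total_within_distance",
    "elbow_select",
    "summarize_dendrogram",
    "SummaryNode",
]


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Plain Euclidean distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


@dataclass(frozen=True)
class LinkageTree:
    """Ward merge history: rows (left id, right id, height, merged size).

    Leaves are 0..n−1 in input order; the merge created at step t gets id
    n+t.  Heights are the Ward merge cost ΔSSE and are non-decreasing.
    """

    merges: np.ndarray  # (n-1, 4) float; ids are integral

    def __post_init__(self) -> None:
        m = np.asarray(self.merges, dtype=float).reshape(-1, 4)
        object.__setattr__(self, "merges", m)

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy convention (heights sqrt(2·ΔSSE))."""
        z = self.merges.copy()
        z[:, 2] = np.sqrt(2.0 * np.maximum(z[:, 2], 0.0))
        return z

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkageTree":
        return cls(df[["left", "right", "height", "size"]].to_numpy(dtype=float))


@dataclass(frozen=True)
class ClusterAssignment:
    """A cut of the tree into k labeled clusters (labels 1..k)."""

    labels: dict[str, int]
    k: int

    def members(self, label: int) -> list[str]:
        return sorted(c for c, l in self.labels.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["code", "cluster"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterAssignment":
        labels = {str(r.code): int(r.cluster) for r in df.itertuples(index=False)}
        return cls(labels, k=len(set(labels.values())))


@dataclass(frozen=True)
class ElbowCurve:
    """Total within-cluster distance W(k) for k = 1..k_max."""

    points: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.points.items()), columns=["k", "W"])


def ward_linkage(vectors: Sequence[np.ndarray]) -> LinkageTree:
    """Agglomerate vectors under Ward's minimum-variance criterion.

    The pairwise merge cost starts at ‖x_i − x_j‖²/2 for singletons and is
    updated with the Lance–Williams recurrence
    D(k, i∪j) = [(n_i+n_k)·D(k,i) + (n_j+n_k)·D(k,j) − n_k·D(i,j)] / (n_i+n_j+n_k),
    which keeps D equal to the exact increase in within-cluster sum of
    squares.  Exact cost ties are broken by the smallest (left, right) id
    pair.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DataError("ward_linkage needs at least one vector")
    n = X.shape[0]
    if n == 1:
        return LinkageTree(np.empty((0, 4)))

    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    cost: dict[tuple[int, int], float] = {
        (i, j): 0.5 * sq[i, j] for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = np.empty((n - 1, 4))

    for t in range(n - 1):
        (bi, bj) = min(cost, key=lambda p: (cost[p], p))
        h = cost[(bi, bj)]
        new = n + t
        merges[t] = (bi, bj, h, size[bi] + size[bj])
        size[new] = size[bi] + size[bj]
        active.discard(bi)
        active.discard(bj)
        ni, nj = size[bi], size[bj]
        for k in active:
            nk = size[k]
            dki = cost.pop((min(k, bi), max(k, bi)))
            dkj = cost.pop((min(k, bj), max(k, bj)))
            cost[(k, new)] = ((ni + nk) * dki + (nj + nk) * dkj - nk * h) / (
                ni + nj + nk
            )
        del cost[(bi, bj)]
        active.add(new)
    return LinkageTree(merges)


def cut_tree(
    tree: LinkageTree, k: int, codes: Sequence[str] | None = None
) -> ClusterAssignment:
    """Undo the last k−1 merges; label clusters 1..k by smallest leaf id."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise DataError(f"k must be in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        li, ri = int(tree.merges[t, 0]), int(tree.merges[t, 1])
        parent[find(li)] = n + t
        parent[find(ri)] = n + t

    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=lambda leaves: leaves[0])
    keys = list(codes) if codes is not None else list(range(n))
    labels = {
        keys[leaf]: lab for lab, leaves in enumerate(clusters, 1) for leaf in leaves
    }
    return ClusterAssignment(labels, k=len(clusters))


def total_within_distance(
    vectors: Sequence[np.ndarray], assignment: ClusterAssignment,
    codes: Sequence[str] | None = None,
) -> float:
    """Σ over clusters of squared Euclidean distances to the cluster centroid."""
    X = np.asarray(vectors, dtype=float)
    keys = list(codes) if codes is not None else list(range(X.shape[0]))
    lab = np.asarray([assignment.labels[c] for c in keys])
    total = 0.0
    for l in np.unique(lab):
        block = X[lab == l]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def elbow_select(
    vectors: Sequence[np.ndarray], k_max: int = 20
) -> tuple[int, ElbowCurve]:
    """Elbow-based choice of the cluster count.

    W(k) is computed from tree cuts for k = 1..k_max; k* maximizes the
    second difference of log W over interior k (ties -> smallest k).  W
    values at or below machine zero are floored at 1e-12 of W(1) before
    taking logs.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DataError("elbow_select needs at least 3 vectors")
    k_max = min(k_max, n)
    tree = ward_linkage(X)
    W = {k: total_within_distance(X, cut_tree(tree, k)) for k in range(1, k_max + 1)}
    floor = max(W[1], 1.0) * 1e-12
    logw = {k: np.log(max(w, floor)) for k, w in W.items()}
    best_k, best_curv = 2, -np.inf
    for k in range(2, k_max):
        curv = logw[k - 1] - 2 * logw[k] + logw[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k, ElbowCurve(W)


# ---------------------------------------------------------------------------
# Depth-limited dendrogram summary


@dataclass
class SummaryNode:
    """Node of the truncated dendrogram.

    A truncated branch (or a leaf) is labeled by its most common member
    code — the member with the largest distinct-patient count, ties to the
    lexicographically smallest code — with that code's prevalence as a
    percentage of the cohort's N.
    """

    label: str
    prevalence_pct: float
    n_leaves: int
    height: float
    children: list["SummaryNode"]

    def to_text(self, indent: int = 0) -> str:
        head = (
            f"{'  ' * indent}{self.label} ({self.prevalence_pct:.1f}%)"
            f"{'' if not self.children else f' [{self.n_leaves} codes]'}"
        )
        return "\n".join([head] + [c.to_text(indent + 1) for c in self.children])

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        name = f"{self.label}_{self.prevalence_pct:.1f}pct"
        if not self.children:
            return name
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner}){name}"


def summarize_dendrogram(
    tree: LinkageTree,
    codes: Sequence[str],
    code_counts: dict[str, int],
    N: int,
    depth: int = 6,
) -> SummaryNode:
    """Truncate the dendrogram at ``depth`` levels below the root.

    Branches deeper than the cut are collapsed and labeled by their most
    common member code with its prevalence percentage of N.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    n = tree.n_leaves
    children: dict[int, tuple[int, int]] = {
        n + t: (int(tree.merges[t, 0]), int(tree.merges[t, 1]))
        for t in range(n - 1)
    }
    heights = {n + t: float(tree.merges[t, 2]) for t in range(n - 1)}

    def leaves_under(node: int) -> list[int]:
        if node < n:
            return [node]
        l, r = children[node]
        return leaves_under(l) + leaves_under(r)

    def best_code(node: int) -> str:
        members = [codes[i] for i in leaves_under(node)]
        return min(members, key=lambda c: (-code_counts.get(c, 0), c))

    def build(node: int, d: int) -> SummaryNode:
        label = best_code(node)
        pct = 100.0 * code_counts.get(label, 0) / max(N, 1)
        if node < n:
            return SummaryNode(label, pct, 1, 0.0, [])
        if d >= depth:
            return SummaryNode(label, pct, len(leaves_under(node)), heights[node], [])
        l, r = children[node]
        return SummaryNode(
            label, pct, len(leaves_under(node)), heights[node],
            [build(l, d + 1), build(r, d + 1)],
        )

    root = 2 * n - 2 if n > 1 else 0
    return build(root, 0)
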