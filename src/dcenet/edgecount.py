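"""Graph-based multi-sample edge-count tests on k-MST similarity graphs.

The test compares the joint distributions of two (or p) groups of points by
pooling all N samples, building a similarity graph G over them — here the
union of k successive edge-disjoint minimum spanning trees of the complete
Euclidean graph — and counting, for each group, the number of edges whose
endpoints both fall in that group.  If the groups differ in distribution,
points sit closer to their own group and the within-group counts
R_1, ..., R_p exceed their expectations under random labeling.

Under the permutation null (labels assigned uniformly at random at fixed
group sizes) the counts have closed-form moments

    mu_k = |G| n_k (n_k - 1) / (N (N - 1)),

with covariance built from |G|, the node degrees (through
C = 1/2 sum_i deg_i^2 - |G|) and falling factorials of the group sizes.
The quadratic form S = (R - mu)^T Sigma^{-1} (R - mu) is asymptotically
chi-square with p degrees of freedom (2 for the classical two-group test),
and a label-permutation test is provided as the exact-null oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "SimilarityGraph",
    "GroupLabeling",
    "EdgeCountResult",
    "KMSTError",
    "build_kmst",
    "count_edges",
    "edge_count_moments",
    "two_group_test",
    "multi_group_test",
    "permutation_test",
]

#: condition number above which Sigma is inverted by pseudo-inverse
_COND_LIMIT = 1e12


class KMSTError(RuntimeError):
    """Raised when a round of the k-MST construction cannot span the nodes."""


@dataclass(frozen=True)
class SimilarityGraph:
    """An undirected edge list over pooled sample indices."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, each row (i, j) with i < j

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if e.shape[0] > 1 and (np.diff(e, axis=0) == 0).all(axis=1).any():
            raise ValueError("duplicate edges are not allowed")
        if e.size and (e.min() < 0 or e.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        object.__setattr__(self, "edges", e)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)


@dataclass(frozen=True)
class GroupLabeling:
    """Per-node group indices 0..p-1 with the implied group sizes."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64).ravel()
        if lab.size == 0 or lab.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        sizes = np.bincount(lab)
        if (sizes == 0).any():
            raise ValueError("every group index 0..p-1 must be used")
        object.__setattr__(self, "labels", lab)

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


@dataclass(frozen=True)
class EdgeCountResult:
    """Edge counts, their permutation-null moments, and the chi-square test."""

    R: np.ndarray          # within-group counts (R_1, ..., R_p)
    R0: int                # between-group edge count (not part of S)
    mu: np.ndarray
    Sigma: np.ndarray
    C: float
    S: float
    df: int
    p_value: float
    method: str = "chi2"
    degrees_of_freedom_reduced: bool = field(default=False)


def _labels(labels) -> GroupLabeling:
    return labels if isinstance(labels, GroupLabeling) else GroupLabeling(np.asarray(labels))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]  # path halving
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def build_kmst(points: np.ndarray, k: int = 1) -> SimilarityGraph:
    """Union of k edge-disjoint successive MSTs of the complete Euclidean graph.

    Tree r is the Kruskal MST of the complete graph with the edges of trees
    1..r-1 removed.  Distance ties are broken by lexicographic (i, j) node
    order, so the result is deterministic; note that tie-rich integer data
    may admit other, equally minimal spanning trees.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 3:
        raise ValueError("build_kmst requires at least 3 points")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = pdist(pts)
    ii, jj = np.triu_indices(n, 1)
    order = np.lexsort((jj, ii, d))
    ii, jj = ii[order], jj[order]
    used = np.zeros(d.size, dtype=bool)
    all_edges = []
    for r in range(1, k + 1):
        uf = _UnionFind(n)
        got = 0
        for e in range(d.size):
            if used[e]:
                continue
            if uf.union(int(ii[e]), int(jj[e])):
                used[e] = True
                all_edges.append((ii[e], jj[e]))
                got += 1
                if got == n - 1:
                    break
        if got < n - 1:
            raise KMSTError(
                f"round {r} of the {k}-MST construction cannot span the graph "
                f"(only {got} of {n - 1} edges found)"
            )
    return SimilarityGraph(n, np.asarray(all_edges, dtype=np.int64))


def count_edges(graph: SimilarityGraph, labels) -> tuple[int, np.ndarray]:
    """Within-group counts R_k and between-group count R0 of a labeling."""
    gl = _labels(labels)
    if gl.labels.size != graph.n_nodes:
        raise ValueError(
            f"labeling covers {gl.labels.size} nodes but the graph has {graph.n_nodes}"
        )
    a = gl.labels[graph.edges[:, 0]]
    b = gl.labels[graph.edges[:, 1]]
    same = a == b
    R = np.bincount(a[same], minlength=gl.n_groups)
    return int((~same).sum()), R


def edge_count_moments(
    graph: SimilarityGraph, group_sizes
) -> tuple[np.ndarray, np.ndarray, float]:
    """Permutation-null mean vector, covariance matrix, and the constant C.

    C = 1/2 sum_i deg_i^2 - |G| counts the ordered pairs of distinct edges
    sharing a node.
    """
    nk = np.asarray(group_sizes, dtype=float)
    N = nk.sum()
    if N < 4:
        raise ValueError("edge-count moments require N >= 4")
    G = float(graph.n_edges)
    if G < 1:
        raise ValueError("the similarity graph has no edges")
    deg = graph.degrees.astype(float)
    C = 0.5 * float((deg**2).sum()) - G
    mu = G * nk * (nk - 1) / (N * (N - 1))
    f2 = nk * (nk - 1)
    f3 = f2 * (nk - 2)
    f4 = f3 * (nk - 3)
    D2 = N * (N - 1)
    D3 = D2 * (N - 2)
    D4 = D3 * (N - 3)
    GG = G * (G - 1) - 2 * C
    Sigma = GG * np.outer(f2, f2) / D4 - np.outer(mu, mu)
    diag = mu * (1 - mu) + 2 * C * f3 / D3 + GG * f4 / D4
    np.fill_diagonal(Sigma, diag)
    return mu, Sigma, C


def _quadratic(
    diff: np.ndarray, Sigma: np.ndarray
) -> tuple[float, int, bool]:
    p = diff.size
    cond = np.linalg.cond(Sigma)
    if np.isfinite(cond) and cond <= _COND_LIMIT:
        S = float(diff @ np.linalg.solve(Sigma, diff))
        return S, p, False
    warnings.warn(
        "edge-count covariance is numerically singular; using the pseudo-inverse "
        "with reduced degrees of freedom",
        RuntimeWarning,
        stacklevel=3,
    )
    S = float(diff @ np.linalg.pinv(Sigma) @ diff)
    df = int(np.linalg.matrix_rank(Sigma))
    return S, max(df, 1), True


def multi_group_test(graph: SimilarityGraph, labels) -> EdgeCountResult:
    """p-group edge-count test: S = (R - mu)^T Sigma^{-1} (R - mu) ~ chi^2_p."""
    gl = _labels(labels)
    sizes = gl.group_sizes
    if gl.n_groups < 2:
        raise ValueError("at least two groups are required")
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    R0, R = count_edges(graph, gl)
    mu, Sigma, C = edge_count_moments(graph, sizes)
    S, df, reduced = _quadratic(R - mu, Sigma)
    p_value = float(stats.chi2.sf(S, df))
    return EdgeCountResult(R, R0, mu, Sigma, C, S, df, p_value,
                           method="chi2", degrees_of_freedom_reduced=reduced)


def two_group_test(graph: SimilarityGraph, labels) -> EdgeCountResult:
    """Classical two-group edge-count test (chi-square with 2 df)."""
    gl = _labels(labels)
    if gl.n_groups != 2:
        raise ValueError(f"two_group_test requires exactly 2 groups, got {gl.n_groups}")
    return multi_group_test(graph, gl)


def permutation_test(
    graph: SimilarityGraph, labels, n_perm: int = 1000, seed: int | None = None
) -> float:
    """Label-permutation p-value for the edge-count statistic S.

    Permutes the group labels uniformly (group sizes fixed) and recomputes
    S each time; p = (1 + #{S_perm >= S_obs}) / (1 + n_perm).  mu and Sigma
    depend only on the graph and the group sizes, so they are computed once.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gl = _labels(labels)
    obs = multi_group_test(graph, gl)
    mu, Sigma = obs.mu, obs.Sigma
    cond = np.linalg.cond(Sigma)
    Minv = np.linalg.inv(Sigma) if np.isfinite(cond) and cond <= _COND_LIMIT else np.linalg.pinv(Sigma)
    rng = np.random.default_rng(seed)
    e0, e1 = graph.edges[:, 0], graph.edges[:, 1]
    p_groups = gl.n_groups
    count = 0
    for _ in range(n_perm):
        lab = rng.permutation(gl.labels)
        a, b = lab[e0], lab[e1]
        same = a == b
        R = np.bincount(a[same], minlength=p_groups).astype(float)
        d = R - mu
        if float(d @ Minv @ d) >= obs.S - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
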