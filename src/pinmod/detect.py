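"""Correlation-distance community detection.

The premise: nodes of the same community sit at similar distances to the rest
of the network, so the rows of the shortest-path matrix S (or of the weight
matrix M = A S, the matrix product of adjacency and shortest paths) of two
same-community nodes are positively correlated.  Each of the four methods
turns a row correlation (Pearson or Spearman) into a distance D = 1 - rho,
clusters D with Ward linkage, and cuts the dendrogram at the level that
maximizes Newman modularity.

M is a true matrix product, not an element-wise one: A and S are symmetric
but M is generally asymmetric, and its row i mixes the S-rows of i's
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .graph import Graph, GraphError, all_pairs_shortest_paths
from .metrics import Partition, modularity_from_labels

__all__ = [
    "MethodSpec",
    "Dendrogram",
    "CORRELATION_METHODS",
    "weight_matrix",
    "correlation_distance",
    "ward_cluster",
    "cut_dendrogram",
    "cut_by_modularity",
    "detect_communities",
]


@dataclass(frozen=True)
class MethodSpec:
    """One of the four correlation methods: base 'sp' or 'M' crossed with
    Pearson or Spearman row correlation."""

    base: str          # "sp" (shortest paths) or "M" (A x shortest paths)
    correlation: str   # "pearson" or "spearman"

    def __post_init__(self) -> None:
        if self.base not in ("sp", "M"):
            raise ValueError(f"unknown base {self.base!r}")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")

    @property
    def name(self) -> str:
        return f"d{self.base.lower()}-{self.correlation}"


#: canonical CLI names for the four methods
CORRELATION_METHODS: dict[str, MethodSpec] = {
    "dsp-pearson": MethodSpec("sp", "pearson"),
    "dsp-spearman": MethodSpec("sp", "spearman"),
    "dm-pearson": MethodSpec("M", "pearson"),
    "dm-spearman": MethodSpec("M", "spearman"),
}


@dataclass(frozen=True)
class Dendrogram:
    """A Ward merge tree over the graph's nodes.

    ``linkage`` is a scipy linkage matrix; ``leaves`` are node labels in the
    graph's stable (lexicographic) order, so leaf i of the tree is node
    ``leaves[i]``.
    """

    linkage: np.ndarray
    leaves: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def weight_matrix(g: Graph, s: np.ndarray) -> np.ndarray:
    """M = A @ S: row i is the sum of the shortest-path rows of i's
    neighbors.  Generally asymmetric."""
    n = g.n_nodes
    if s.shape != (n, n):
        raise GraphError(
            f"shortest-path matrix shape {s.shape} does not match graph size {n}"
        )
    a = g.adjacency()
    return np.asarray(a @ s, dtype=np.float64)


def correlation_distance(x: np.ndarray, correlation: str = "pearson") -> np.ndarray:
    """Pairwise row-correlation distance D = 1 - rho.

    Rows with zero variance have undefined correlation; any pair involving
    one gets the neutral distance 1.  The diagonal is forced to 0 and values
    are clipped to [0, 2].
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("correlation over rows needs at least 3 columns")
    if correlation == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)  # average ranks for ties
    elif correlation != "pearson":
        raise ValueError(f"unknown correlation {correlation!r}")
    sd = x.std(axis=1)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(x)
    d = 1.0 - rho
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def ward_cluster(d: np.ndarray, dialect: str = "ward.D2") -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    ``ward.D2`` (default) applies the Lance-Williams recurrence to squared
    distances — the textbook Ward objective and scipy's native behavior.
    ``ward.D`` applies the recurrence to the raw distances (the historical R
    dialect); it is realized by feeding sqrt-distances to the D2 machinery
    and squaring the merge heights back.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")
    if dialect == "ward.D2":
        z = sch.linkage(squareform(d, checks=False), method="ward")
    elif dialect == "ward.D":
        z = sch.linkage(squareform(np.sqrt(d), checks=False), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    else:
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    return Dendrogram(linkage=z, leaves=tuple(f"leaf{i}" for i in range(n)))


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Flat labels (length n) for the cut with exactly ``k`` clusters."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"cut level {k} outside 1..{n}")
    labels = sch.cut_tree(dend.linkage, n_clusters=k).ravel()
    return labels.astype(np.int64)


def cut_by_modularity(dend: Dendrogram, g: Graph) -> Partition:
    """Return the dendrogram cut with maximal modularity.

    Every level k = 1..n is evaluated; ties go to the smallest k (fewest
    communities).
    """
    if set(dend.leaves) != set(g.nodes):
        raise GraphError("dendrogram leaves do not match graph nodes")
    n = g.n_nodes
    leaf_pos = {v: i for i, v in enumerate(dend.leaves)}
    order = [leaf_pos[v] for v in g.nodes]
    all_cuts = sch.cut_tree(dend.linkage)  # n x n, column j has n-j clusters
    edge_idx = g.edge_indices()
    degrees = g.degrees()
    m = g.n_edges
    best_q, best_k, best_labels = -np.inf, None, None
    for k in range(1, n + 1):
        labels = all_cuts[:, n - k][order].astype(np.int64)
        # re-canonicalize label ids to be contiguous
        _, labels = np.unique(labels, return_inverse=True)
        q = modularity_from_labels(edge_idx, degrees, labels, m)
        if q > best_q + 1e-12:
            best_q, best_k, best_labels = q, k, labels
    return Partition.from_labels(list(g.nodes), best_labels)


def detect_communities(
    g: Graph,
    spec: MethodSpec,
    dialect: str = "ward.D2",
    s: np.ndarray | None = None,
) -> Partition:
    """Full pipeline: shortest paths -> (optional M = A S) -> D = 1 - rho ->
    Ward -> modularity-optimal cut.  Deterministic given ``g``.

    A precomputed shortest-path matrix ``s`` may be passed to amortize the
    BFS across the four method variants.
    """
    if g.n_nodes < 3:
        # too small for row correlations; a single community maximizes Q
        return Partition.from_communities([set(g.nodes)]) if g.n_nodes else \
            Partition.from_membership({})
    if s is None:
        s = all_pairs_shortest_paths(g)
    x = weight_matrix(g, s) if spec.base == "M" else np.asarray(s, dtype=np.float64)
    d = correlation_distance(x, spec.correlation)
    dend = Dendrogram(
        linkage=ward_cluster(d, dialect=dialect).linkage, leaves=g.nodes
    )
    return cut_by_modularity(dend, g)
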