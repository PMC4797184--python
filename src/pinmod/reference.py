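"""Reference community detection algorithms.

Native implementations of greedy modularity agglomeration (fast-greedy) and
asynchronous label propagation, plus a uniform adapter that exposes walktrap,
spinglass and multilevel through python-igraph when it is installed.  All
nine methods (these five plus the four correlation-distance methods) share
one dispatch surface, :func:`run_algorithm`.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .detect import CORRELATION_METHODS, detect_communities
from .graph import Graph, GraphError
from .metrics import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmSpec",
    "CapabilityError",
    "FastGreedyResult",
    "NATIVE_METHODS",
    "EXTERNAL_METHODS",
    "ALL_METHODS",
    "fast_greedy",
    "fast_greedy_full",
    "label_propagation",
    "run_algorithm",
]

NATIVE_METHODS = (
    "fastgreedy",
    "labelprop",
    "dsp-pearson",
    "dsp-spearman",
    "dm-pearson",
    "dm-spearman",
)
EXTERNAL_METHODS = ("walktrap", "spinglass", "multilevel")
ALL_METHODS = NATIVE_METHODS + EXTERNAL_METHODS


class CapabilityError(RuntimeError):
    """A requested external backend is not available."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """Uniform handle for the nine community detection methods."""

    name: str
    seed: int | None = None
    backend: str = "native"

    def __post_init__(self) -> None:
        if self.name not in ALL_METHODS:
            raise ValueError(f"unknown algorithm {self.name!r}")
        if self.name in EXTERNAL_METHODS and self.backend != "external":
            object.__setattr__(self, "backend", "external")


@dataclass
class FastGreedyResult:
    """Full agglomeration record of the greedy modularity algorithm."""

    partition: Partition                  # the max-Q cut of the merge sequence
    merges: list[tuple[int, int]]         # community pairs merged, in order
    q_trace: list[float]                  # Q after 0, 1, ..., n-1 merges
    best_step: int                        # index into q_trace of the maximum

    def partition_at(self, g: Graph, step: int) -> Partition:
        """Recover the partition after ``step`` merges (for cross-checks)."""
        comm = {i: {v} for i, v in enumerate(g.nodes)}
        for i, j in self.merges[:step]:
            comm[i] |= comm.pop(j)
        return Partition.from_communities(comm.values())


def fast_greedy_full(g: Graph) -> FastGreedyResult:
    """Greedy modularity agglomeration (Clauset-Newman-Moore scheme).

    Starts from singleton communities with the pair score
    dQ_ij = 1/(2m) - k_i k_j/(2m)^2 for adjacent pairs and repeatedly merges
    the pair with the largest score, maintaining scores with the standard
    sparse-row + lazy max-heap bookkeeping until one community remains.  The
    pair score is e_ij - a_i a_j, half the symmetric modularity gain
    e_ij + e_ji - 2 a_i a_j, so the recorded Q advances by twice the score
    of each merge (the ranking, and hence the merge order, is unaffected by
    the factor).  Q is recorded after every merge and the maximum-Q cut is
    reported; score ties break toward the smallest (i, j).
    """
    m = g.n_edges
    if m == 0:
        raise GraphError("fast-greedy requires at least one edge")
    nodes = g.nodes
    n = len(nodes)
    deg = g.degrees().astype(float)
    a = deg / (2.0 * m)
    # sparse dQ rows over community pairs, keyed (i, j) with i < j
    adj = g.adjacency_sets()
    idx = {v: i for i, v in enumerate(nodes)}
    dq: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    heap: list[tuple[float, int, int]] = []
    for u, nbrs in adj.items():
        i = idx[u]
        for v in nbrs:
            j = idx[v]
            if i < j:
                val = 1.0 / (2.0 * m) - deg[i] * deg[j] / (2.0 * m) ** 2
                dq[i][j] = val
                dq[j][i] = val
                heapq.heappush(heap, (-val, i, j))
    alive = set(range(n))
    q = -float(np.sum(a**2))  # singleton partition: all e_ii = 0
    q_trace = [q]
    merges: list[tuple[int, int]] = []
    comm_nodes: dict[int, list[str]] = {i: [nodes[i]] for i in range(n)}
    while len(alive) > 1:
        # pop until a live, current entry surfaces
        while heap:
            negval, i, j = heapq.heappop(heap)
            if i in alive and j in alive and dq[i].get(j) == -negval:
                break
        else:
            # graph disconnected between remaining communities: join two
            # arbitrary (smallest-id) communities; pair score -a_i a_j
            i, j = sorted(alive)[:2]
            negval = a[i] * a[j]
        # merge j into i; pair scores e_ij - a_i a_j are half the true
        # modularity gain e_ij + e_ji - 2 a_i a_j, so Q moves by twice
        merges.append((i, j))
        q += -2.0 * negval
        q_trace.append(q)
        nbrs_i = set(dq[i]) - {j}
        nbrs_j = set(dq[j]) - {i}
        for k in nbrs_i | nbrs_j:
            if k not in alive:
                continue
            if k in nbrs_i and k in nbrs_j:
                val = dq[i][k] + dq[j][k]
            elif k in nbrs_i:
                val = dq[i][k] - a[j] * a[k]
            else:
                val = dq[j][k] - a[i] * a[k]
            dq[i][k] = val
            dq[k][i] = val
            dq[k].pop(j, None)
            lo, hi = (i, k) if i < k else (k, i)
            heapq.heappush(heap, (-val, lo, hi))
        for k in dq.pop(j):
            dq[k].pop(j, None)
        dq[i].pop(j, None)
        a[i] += a[j]
        alive.discard(j)
        comm_nodes[i].extend(comm_nodes.pop(j))
    best_step = int(np.argmax(q_trace))
    # replay merges to the best step
    comm = {i: {v} for i, v in enumerate(nodes)}
    for i, j in merges[:best_step]:
        comm[i] |= comm.pop(j)
    partition = Partition.from_communities(comm.values())
    return FastGreedyResult(
        partition=partition, merges=merges, q_trace=q_trace, best_step=best_step
    )


def fast_greedy(g: Graph) -> Partition:
    """Max-modularity partition found by greedy agglomeration."""
    return fast_greedy_full(g).partition


def label_propagation(g: Graph, seed: int = 0) -> Partition:
    """Asynchronous label propagation.

    Every node starts with a unique label; in a seeded random order each node
    adopts the label held by the maximum number of its neighbors, breaking
    ties uniformly at random.  The algorithm stops once every node's label is
    already among the maximal labels of its neighborhood.
    """
    if g.n_nodes == 0:
        return Partition.from_membership({})
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    adj = g.adjacency_sets()
    label = {v: i for i, v in enumerate(nodes)}
    for _sweep in range(10 * g.n_nodes + 10):
        order = rng.permutation(len(nodes))
        changed = False
        for pos in order:
            v = nodes[pos]
            if not adj[v]:
                continue
            counts: dict[int, int] = {}
            for u in adj[v]:
                counts[label[u]] = counts.get(label[u], 0) + 1
            top = max(counts.values())
            winners = sorted(lab for lab, c in counts.items() if c == top)
            if label[v] in winners:
                continue
            label[v] = winners[int(rng.integers(len(winners)))]
            changed = True
        if not changed:
            break
    return Partition.from_membership(label)


# -- external backend adapter ---------------------------------------------


def _igraph_partition(g: Graph, name: str, seed: int | None) -> Partition:
    try:
        import igraph as ig
    except ImportError as exc:  # pragma: no cover - igraph present in CI env
        raise CapabilityError(
            f"method {name!r} requires the python-igraph backend, "
            "which is not installed"
        ) from exc
    import random as _random

    ig.set_random_number_generator(_random.Random(0 if seed is None else seed))
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    graph = ig.Graph(
        n=len(nodes), edges=[(idx[u], idx[v]) for u, v in sorted(g.edges)]
    )
    if name == "walktrap":
        clustering = graph.community_walktrap().as_clustering()
    elif name == "multilevel":
        clustering = graph.community_multilevel()
    elif name == "spinglass":
        clustering = graph.community_spinglass()
    else:  # pragma: no cover
        raise ValueError(name)
    return Partition.from_labels(nodes, clustering.membership)


def run_algorithm(g: Graph, spec: AlgorithmSpec) -> Partition:
    """Dispatch one of the nine methods; output is always canonicalized.

    Native methods never fall back to a library; external methods raise
    :class:`CapabilityError` when python-igraph is missing.
    """
    if spec.name == "fastgreedy":
        return fast_greedy(g)
    if spec.name == "labelprop":
        return label_propagation(g, seed=spec.seed if spec.seed is not None else 0)
    if spec.name in CORRELATION_METHODS:
        return detect_communities(g, CORRELATION_METHODS[spec.name])
    return _igraph_partition(g, spec.name, spec.seed)
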