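"""Planted-community benchmark networks and perturbation operators.

The generator plants a known non-overlapping community structure: node
degrees follow a truncated discrete power law d^(-gamma) tuned so its mean
hits the target average degree; community sizes follow a truncated power law
summing exactly to n; every node splits its degree into a (1-mu) internal
and a mu external part; stubs are matched by a configuration-model pairing,
then rewiring sweeps clean self-loops, duplicate edges and misclassified
(internal vs external) pairs.  The mixing parameter mu is the fraction of
each node's edges attached outside its own community — the single dial that
makes detection hard.

The two perturbation operators emulate noisy interaction data: uniform
random edge additions (false positives) and degree- and bridge-guarded
random deletions that keep the network connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Graph, GraphError
from .metrics import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkConfig",
    "PlantedNetwork",
    "GenerationError",
    "sample_degree_sequence",
    "sample_community_sizes",
    "generate",
    "add_random_edges",
    "delete_random_edges",
]


class GenerationError(RuntimeError):
    """Benchmark generation could not satisfy its constraints."""


@dataclass(frozen=True)
class BenchmarkConfig:
    """Parameters of the planted-community generator.

    Defaults are the reference study conditions: 1000 nodes, degree exponent
    gamma = 1, mean degree 10, maximum degree 20.  Community-size bounds must
    satisfy k_max > d_max so every node can fit its internal degree into a
    community; (20, 50) is the smallest grid pair compatible with d_max = 20.
    """

    n: int = 1000
    gamma: float = 1.0
    d_avg: float = 10.0
    d_max: int = 20
    mu: float = 0.05
    size_exponent: float = 1.0
    k_min: int = 20
    k_max: int = 50
    seed: int = 0
    max_rewire_sweeps: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise ValueError("mu must lie in [0, 1)")
        if self.d_avg > self.d_max:
            raise ValueError("d_avg cannot exceed d_max")
        if self.k_min > self.k_max:
            raise ValueError("k_min cannot exceed k_max")
        if self.k_max <= self.d_max:
            raise ValueError(
                "k_max must exceed d_max so every node can join a community"
            )
        if self.n < self.k_min:
            raise ValueError("n must be at least k_min")


@dataclass(frozen=True)
class PlantedNetwork:
    """A generated benchmark graph with its ground-truth partition."""

    graph: Graph
    truth: Partition
    realized_mu: float
    config: BenchmarkConfig


def _truncated_power_law(lo: int, hi: int, exponent: float) -> np.ndarray:
    support = np.arange(lo, hi + 1, dtype=float)
    w = support**-exponent
    return w / w.sum()


def sample_degree_sequence(cfg: BenchmarkConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw n degrees from p(d) ~ d^(-gamma) on [d_min, d_max].

    d_min is solved so the distribution mean is as close as possible to
    d_avg (the mean is increasing in d_min, so the best integer truncation
    point is unique up to a tie).  The degree sum is adjusted to be even.
    """
    if cfg.d_avg == cfg.d_max:
        deg = np.full(cfg.n, cfg.d_max, dtype=np.int64)
    else:
        means = []
        for d_min in range(1, cfg.d_max + 1):
            p = _truncated_power_law(d_min, cfg.d_max, cfg.gamma)
            means.append(float(np.dot(np.arange(d_min, cfg.d_max + 1), p)))
        means_arr = np.array(means)
        if cfg.d_avg < means_arr[0] - 0.5 or cfg.d_avg > cfg.d_max:
            raise GenerationError(
                f"d_avg={cfg.d_avg} unreachable for gamma={cfg.gamma}, "
                f"d_max={cfg.d_max} (reachable mean range "
                f"[{means_arr[0]:.2f}, {cfg.d_max}])"
            )
        d_min = int(np.argmin(np.abs(means_arr - cfg.d_avg))) + 1
        p = _truncated_power_law(d_min, cfg.d_max, cfg.gamma)
        deg = rng.choice(np.arange(d_min, cfg.d_max + 1), size=cfg.n, p=p)
        deg = deg.astype(np.int64)
    if deg.sum() % 2 == 1:
        below = np.flatnonzero(deg < cfg.d_max)
        if below.size:
            deg[below[0]] += 1
        else:
            deg[0] -= 1
    return deg


def sample_community_sizes(cfg: BenchmarkConfig, rng: np.random.Generator) -> list[int]:
    """Community sizes from a truncated power law, summing exactly to n.

    Sizes are drawn until the running sum reaches n; the final size is the
    remainder, and if it falls below k_min the deficit is borrowed one node
    at a time from communities still above k_min.
    """
    if cfg.n < cfg.k_min:
        raise GenerationError("n is smaller than the minimum community size")
    if cfg.k_min == cfg.k_max:
        if cfg.n % cfg.k_min:
            raise GenerationError(
                f"n={cfg.n} is not a multiple of the forced size {cfg.k_min}"
            )
        return [cfg.k_min] * (cfg.n // cfg.k_min)
    support = np.arange(cfg.k_min, cfg.k_max + 1)
    p = _truncated_power_law(cfg.k_min, cfg.k_max, cfg.size_exponent)
    sizes: list[int] = []
    total = 0
    while total < cfg.n:
        s = int(rng.choice(support, p=p))
        if total + s > cfg.n:
            s = cfg.n - total
        sizes.append(s)
        total += s
    if sizes[-1] < cfg.k_min:
        # try borrowing nodes from communities above k_min ...
        deficit = cfg.k_min - sizes[-1]
        donors = [i for i in range(len(sizes) - 1) if sizes[i] > cfg.k_min]
        gi = 0
        while deficit > 0 and donors:
            i = donors[gi % len(donors)]
            if sizes[i] > cfg.k_min:
                sizes[i] -= 1
                sizes[-1] += 1
                deficit -= 1
                gi += 1
            else:
                donors.remove(i)
        if deficit > 0:
            # ... otherwise dissolve the remainder into spare capacity
            rest = sizes.pop()
            takers = [i for i in range(len(sizes)) if sizes[i] < cfg.k_max]
            gi = 0
            while rest > 0 and takers:
                i = takers[gi % len(takers)]
                if sizes[i] < cfg.k_max:
                    sizes[i] += 1
                    rest -= 1
                    gi += 1
                else:
                    takers.remove(i)
            if rest > 0:
                raise GenerationError(
                    "community sizes cannot sum to n within [k_min, k_max]"
                )
    assert sum(sizes) == cfg.n
    return sizes


def _assign_communities(
    internal: np.ndarray, sizes: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Iterative random assignment with displacement when a community fills.

    A node may join community c only if the community size exceeds the
    node's internal degree (it needs that many distinct neighbors inside).
    """
    n = internal.shape[0]
    k = len(sizes)
    sizes_arr = np.array(sizes)
    comm = np.full(n, -1, dtype=np.int64)
    fill = np.zeros(k, dtype=np.int64)
    pool = list(rng.permutation(n))
    attempts = 0
    max_attempts = 200 * n
    while pool:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                "community assignment did not converge; "
                "increase k_min relative to d_max"
            )
        v = pool.pop()
        feasible = np.flatnonzero(sizes_arr > internal[v])
        if feasible.size == 0:
            raise GenerationError(
                f"node with internal degree {internal[v]} fits no community; "
                "increase k_min"
            )
        c = int(feasible[rng.integers(feasible.size)])
        if fill[c] < sizes_arr[c]:
            comm[v] = c
            fill[c] += 1
        else:
            # displace a random member and take its slot
            members = np.flatnonzero(comm == c)
            out = int(members[rng.integers(members.size)])
            comm[out] = -1
            pool.insert(0, out)
            comm[v] = c
    return comm


def _simple_graph_with_degrees(
    members: np.ndarray,
    degs: np.ndarray,
    rng: np.random.Generator,
    n_swaps_factor: int = 10,
) -> set[tuple[int, int]]:
    """A uniform-ish simple graph on ``members`` with the given degrees.

    Construction is Havel-Hakimi (always succeeds for a graphical sequence)
    followed by seeded double-edge swaps to randomize.  Community subgraphs
    can be dense (internal degree close to community size), where naive
    configuration-model repair stalls; this construction cannot.
    """
    order = np.argsort(-degs, kind="stable")
    remaining = [[int(degs[i]), int(members[i])] for i in order if degs[i] > 0]
    edges: set[tuple[int, int]] = set()
    while remaining:
        remaining.sort(key=lambda x: -x[0])
        d, v = remaining.pop(0)
        if d > len(remaining):
            raise GenerationError(
                "degree sequence not graphical within a community"
            )
        for item in remaining[:d]:
            item[0] -= 1
            edges.add((v, item[1]) if v < item[1] else (item[1], v))
        remaining = [x for x in remaining if x[0] > 0]
    # randomize with double-edge swaps that preserve simplicity
    edge_list = sorted(edges)
    n_swaps = n_swaps_factor * len(edge_list)
    for _ in range(n_swaps):
        i, j = rng.integers(len(edge_list)), rng.integers(len(edge_list))
        if i == j:
            continue
        a, b = edge_list[i]
        c, d2 = edge_list[j]
        if len({a, b, c, d2}) < 4:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d2) if b < d2 else (d2, b)
        if e1 in edges or e2 in edges:
            continue
        edges.discard(edge_list[i])
        edges.discard(edge_list[j])
        edges.add(e1)
        edges.add(e2)
        edge_list[i], edge_list[j] = e1, e2
    return edges


def _graphical_deficit(degs: np.ndarray) -> bool:
    """Erdos-Gallai check for an even-sum degree sequence."""
    d = np.sort(degs[degs > 0])[::-1].astype(np.int64)
    n = d.size
    if n == 0:
        return True
    if d[0] > n - 1 or d.sum() % 2:
        return False
    csum = np.cumsum(d)
    for k in range(1, n + 1):
        rhs = k * (k - 1) + np.sum(np.minimum(d[k:], k))
        if csum[k - 1] > rhs:
            return False
    return True


def _pair_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    bad_pair,
    existing: set[tuple[int, int]],
    sweeps: int,
) -> set[tuple[int, int]]:
    """Configuration-model pairing with rewiring until no pair is bad.

    ``bad_pair(u, v)`` flags forbidden pairs (self-loop, duplicate of an
    existing edge, or wrong internal/external class); bad pairs are rewired
    by swapping endpoints with randomly chosen good pairs.
    """
    stubs = stubs.copy()
    rng.shuffle(stubs)
    pairs = [tuple(sorted((int(stubs[2 * i]), int(stubs[2 * i + 1]))))
             for i in range(len(stubs) // 2)]
    for _ in range(sweeps):
        seen: set[tuple[int, int]] = set()
        bad_idx = []
        for i, (u, v) in enumerate(pairs):
            if u == v or (u, v) in existing or (u, v) in seen or bad_pair(u, v):
                bad_idx.append(i)
            else:
                seen.add((u, v))
        if not bad_idx:
            return set(pairs)
        for i in bad_idx:
            j = int(rng.integers(len(pairs)))
            u, v = pairs[i]
            x, y = pairs[j]
            # swap one endpoint of each pair
            if rng.random() < 0.5:
                pairs[i] = tuple(sorted((u, y)))
                pairs[j] = tuple(sorted((x, v)))
            else:
                pairs[i] = tuple(sorted((u, x)))
                pairs[j] = tuple(sorted((v, y)))
    raise GenerationError(
        "rewiring sweeps exhausted before the pairing became clean; "
        "increase max_rewire_sweeps"
    )


def generate(cfg: BenchmarkConfig) -> PlantedNetwork:
    """Generate a planted-community benchmark network.

    Deterministic given ``cfg`` (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    deg = sample_degree_sequence(cfg, rng)
    sizes = sample_community_sizes(cfg, rng)
    # split degrees into internal/external by banker's rounding of (1-mu) d
    internal = np.rint((1.0 - cfg.mu) * deg).astype(np.int64)
    internal = np.minimum(internal, deg)
    comm = _assign_communities(internal, sizes, rng)
    # per-community internal stub sums must be even: demote one stub where
    # not (at mu = 0 the stub is dropped outright so no external edge can
    # appear)
    for c in range(len(sizes)):
        members = np.flatnonzero(comm == c)
        if internal[members].sum() % 2 == 1:
            cand = members[internal[members] > 0]
            v = int(cand[rng.integers(cand.size)])
            internal[v] -= 1
            if cfg.mu == 0:
                deg[v] -= 1
    external = deg - internal
    if external.sum() % 2 == 1:
        cand = np.flatnonzero(external > 0)
        v = int(cand[rng.integers(cand.size)])
        external[v] -= 1
        internal[v] += 1  # keep total degree; may add one internal stub
        members = np.flatnonzero(comm == comm[v])
        if internal[members].sum() % 2 == 1:
            internal[v] -= 1  # give up the stub instead of breaking parity
    edges: set[tuple[int, int]] = set()
    for c in range(len(sizes)):
        members = np.flatnonzero(comm == c)
        degs = internal[members].copy()
        # demote stubs (pairs of them, keeping parity) until graphical
        guard = 0
        while not _graphical_deficit(degs):
            guard += 1
            if guard > 2 * degs.sum() + 10:
                raise GenerationError(
                    "internal degree sequence cannot be made graphical; "
                    "increase k_min"
                )
            worst = int(np.argmax(degs))
            degs[worst] -= 1
            nxt = int(np.argmax(np.where(np.arange(degs.size) == worst,
                                         -1, degs)))
            degs[nxt] -= 1
            internal[members[worst]] -= 1
            internal[members[nxt]] -= 1
            if cfg.mu == 0:
                deg[members[worst]] -= 1
                deg[members[nxt]] -= 1
        if degs.sum() == 0:
            continue
        edges |= _simple_graph_with_degrees(members, degs, rng)
    ext_stubs = np.repeat(np.arange(cfg.n), external)
    if ext_stubs.size:
        pairs = _pair_stubs(
            ext_stubs, rng,
            bad_pair=lambda u, v: comm[u] == comm[v],
            existing=edges, sweeps=cfg.max_rewire_sweeps,
        )
        edges |= pairs
    labels = [f"n{i:04d}" for i in range(cfg.n)]
    # isolated nodes (degree drawn but all stubs demoted) are still planted
    graph = Graph.from_edges(
        ((labels[u], labels[v]) for u, v in edges), nodes=labels
    )
    truth = Partition.from_membership(
        {labels[i]: int(comm[i]) for i in range(cfg.n)}
    )
    inter = sum(1 for u, v in edges if comm[u] != comm[v])
    realized_mu = inter / len(edges) if edges else 0.0
    return PlantedNetwork(graph=graph, truth=truth, realized_mu=realized_mu,
                          config=cfg)


def add_random_edges(
    g: Graph, fraction: float, rng: np.random.Generator
) -> Graph:
    """Add floor(fraction * m) uniformly sampled distinct non-edges."""
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    n, m = g.n_nodes, g.n_edges
    quota = int(np.floor(fraction * m))
    if quota == 0:
        return g
    max_edges = n * (n - 1) // 2
    if m + quota > max_edges:
        raise GraphError(
            f"cannot add {quota} edges: only {max_edges - m} non-edges exist"
        )
    nodes = g.nodes
    new_edges: set[tuple[str, str]] = set()
    existing = g.edges
    while len(new_edges) < quota:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        u, v = (nodes[i], nodes[j]) if nodes[i] < nodes[j] else (nodes[j], nodes[i])
        if (u, v) in existing or (u, v) in new_edges:
            continue
        new_edges.add((u, v))
    return Graph.from_edges(list(existing) + list(new_edges), nodes=nodes)


def delete_random_edges(
    g: Graph, fraction: float, rng: np.random.Generator
) -> Graph:
    """Delete floor(fraction * m) edges while preserving connectivity.

    Candidates are edges whose endpoints both keep degree >= 1 afterwards
    (i.e. both currently have degree >= 2) and that are not bridges; the
    candidate set is refreshed after every removal.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    comps = g.connected_components()
    if len(comps) > 1:
        raise GraphError("deletion requires a connected graph")
    quota = int(np.floor(fraction * g.n_edges))
    if quota == 0:
        return g
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges)
    removed = 0
    while removed < quota:
        bridges = set(tuple(sorted(e)) for e in nx.bridges(h))
        candidates = [
            (u, v) for u, v in h.edges()
            if h.degree(u) >= 2 and h.degree(v) >= 2
            and tuple(sorted((u, v))) not in bridges
        ]
        if not candidates:
            raise GraphError(
                f"deletion candidates exhausted after removing {removed} of "
                f"{quota} edges"
            )
        u, v = candidates[int(rng.integers(len(candidates)))]
        h.remove_edge(u, v)
        removed += 1
    return Graph.from_edges(h.edges(), nodes=g.nodes)
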