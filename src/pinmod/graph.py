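"""Undirected simple graphs with string node labels.

The universal input type of the toolkit: protein interaction networks and
benchmark networks are both plain undirected simple graphs.  Node order is
lexicographic by label everywhere a matrix is built, which makes shortest-path,
correlation and weight matrices bit-reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphError",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "giant_connected_component",
    "all_pairs_shortest_paths",
    "edge_density",
]


class GraphError(ValueError):
    """Structural error in a graph operation."""


class ParseError(GraphError):
    """Malformed input file."""


@dataclass(frozen=True)
class Graph:
    """An undirected simple graph.

    ``nodes`` is a lexicographically sorted tuple of string labels; ``edges``
    is a frozenset of ``(u, v)`` pairs with ``u < v``.  No self-loops, no
    duplicate edges, every endpoint registered.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "Graph":
        """Build a graph, dropping self-loops and collapsing duplicates.

        ``nodes`` may add isolated nodes beyond edge endpoints.
        """
        node_set = {str(x) for x in nodes}
        edge_set: set[tuple[str, str]] = set()
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            node_set.add(u)
            node_set.add(v)
            if u == v:
                n_loops += 1
                continue
            edge_set.add((u, v) if u < v else (v, u))
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        return cls._build(node_set, edge_set)

    @classmethod
    def _build(cls, nodes: set[str], edges: set[tuple[str, str]]) -> "Graph":
        order = tuple(sorted(nodes))
        g = cls(nodes=order, edges=frozenset(edges))
        object.__setattr__(g, "_index", {v: i for i, v in enumerate(order)})
        return g

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        return self._index[node]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def edge_indices(self) -> np.ndarray:
        """Edges as an (m, 2) int array in node order, sorted row-wise."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        idx = self._index
        arr = np.array(
            sorted((idx[u], idx[v]) for u, v in self.edges), dtype=np.int64
        )
        return arr

    def adjacency(self, dense: bool = False) -> sp.csr_matrix | np.ndarray:
        """Symmetric 0/1 adjacency matrix in lexicographic node order."""
        n = self.n_nodes
        e = self.edge_indices()
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        a = sp.csr_matrix(
            (np.ones(rows.shape[0], dtype=np.int8), (rows, cols)), shape=(n, n)
        )
        return a.toarray() if dense else a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for u, v in self.edges:
            deg[self._index[u]] += 1
            deg[self._index[v]] += 1
        return deg

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def adjacency_sets(self) -> dict[str, set[str]]:
        """node -> neighbor set, for algorithms that walk the graph."""
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def subgraph(self, keep: Iterable[str]) -> "Graph":
        keep_set = set(keep)
        missing = keep_set - set(self.nodes)
        if missing:
            raise GraphError(f"{len(missing)} node(s) not in graph")
        edges = {e for e in self.edges if e[0] in keep_set and e[1] in keep_set}
        return Graph._build(keep_set, edges)

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges

    # -- connectivity ------------------------------------------------------

    def connected_components(self) -> list[set[str]]:
        """Components as node sets, largest first (ties: smallest label)."""
        if self.n_nodes == 0:
            return []
        n_comp, labels = connected_components(self.adjacency(), directed=False)
        comps: dict[int, set[str]] = {}
        for node, lab in zip(self.nodes, labels):
            comps.setdefault(int(lab), set()).add(node)
        return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


# -- module-level operations ----------------------------------------------


def read_edge_list(path: str | Path, directed_hint: bool = False) -> Graph:
    """Read a 2-column whitespace/tab-separated edge list.

    Lines starting with ``#`` are ignored; self-loops are dropped with a
    warning; duplicate edges (including reversed duplicates) are collapsed.
    ``directed_hint`` is accepted for interface symmetry but edges are always
    stored undirected.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    return Graph.from_edges(edges)


def write_edge_list(g: Graph, path: str | Path) -> None:
    """Write lexicographically sorted ``u<TAB>v`` lines with ``u < v``."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated nodes would be lost by an edge list; record them as comments
        isolated = set(g.nodes) - {x for e in g.edges for x in e}
        for v in sorted(isolated):
            fh.write(f"# isolated\t{v}\n")


def giant_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest component.

    Size ties are broken toward the component containing the
    lexicographically smallest node label.  An empty graph is returned
    unchanged.
    """
    comps = g.connected_components()
    if not comps:
        return g
    return g.subgraph(comps[0])


def all_pairs_shortest_paths(g: Graph) -> np.ndarray:
    """Unweighted hop-count matrix indexed in the graph's stable node order.

    The input must be connected (callers pass the giant component first).
    """
    if g.n_nodes == 0:
        raise GraphError("empty graph")
    a = g.adjacency()
    n_comp, _ = connected_components(a, directed=False)
    if n_comp > 1:
        raise GraphError(f"graph is disconnected ({n_comp} components)")
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    return d.astype(np.int64)


def edge_density(g: Graph) -> float:
    """Edge density 2m / (n(n-1)) of a simple undirected graph."""
    n, m = g.n_nodes, g.n_edges
    if n < 2:
        raise GraphError("edge density requires at least 2 nodes")
    return 2.0 * m / (n * (n - 1))
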