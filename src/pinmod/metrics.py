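"""Partitions, Newman modularity, contingency tables and NMI.

Modularity of a partition is Q = sum_i (e_ii - a_i^2), where e_ij is the
fraction of edge ends running between communities i and j and a_i the
fraction of edge ends attached to community i.  Agreement between two
partitions is scored by normalized mutual information computed from their
contingency table; the default normalization divides the mutual information
by max(H(U), H(V)) so that identical partitions score 1.0, with the
sum-normalized variant I/(H(U)+H(V)) available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import Graph, GraphError

__all__ = [
    "Partition",
    "ModularityDecomposition",
    "ContingencyTable",
    "modularity",
    "modularity_decomposition",
    "contingency",
    "nmi",
    "read_partition",
    "write_partition",
]


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with contiguous integer ids 0..K-1."""

    membership: dict[str, int]

    @classmethod
    def from_membership(cls, membership: Mapping[str, int]) -> "Partition":
        """Canonicalize: community ids become 0..K-1 in order of first
        appearance over lexicographically sorted node labels."""
        remap: dict[int, int] = {}
        canon: dict[str, int] = {}
        for node in sorted(membership):
            old = int(membership[node])
            if old not in remap:
                remap[old] = len(remap)
            canon[str(node)] = remap[old]
        return cls(membership=canon)

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[str]]) -> "Partition":
        memb: dict[str, int] = {}
        for cid, comm in enumerate(communities):
            for node in comm:
                if node in memb:
                    raise ValueError(f"node {node!r} appears in two communities")
                memb[str(node)] = cid
        return cls.from_membership(memb)

    @classmethod
    def from_labels(cls, nodes: Sequence[str], labels: Sequence[int]) -> "Partition":
        if len(nodes) != len(labels):
            raise ValueError("nodes and labels differ in length")
        return cls.from_membership(dict(zip(nodes, (int(x) for x in labels))))

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    @property
    def nodes(self) -> set[str]:
        return set(self.membership)

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, cid in self.membership.items():
            out[cid].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]

    def labels_for(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.membership[v] for v in nodes], dtype=np.int64)

    def restrict(self, nodes: Iterable[str]) -> "Partition":
        keep = set(nodes)
        return Partition.from_membership(
            {v: c for v, c in self.membership.items() if v in keep}
        )


@dataclass(frozen=True)
class ModularityDecomposition:
    """The (e, a, m) decomposition behind Q = sum_i (e_ii - a_i^2)."""

    e: np.ndarray  # K x K symmetric matrix of edge-end fractions
    a: np.ndarray  # length-K community degree fractions
    m: int         # total edge count

    @property
    def q(self) -> float:
        return float(np.trace(self.e) - np.sum(self.a**2))


def modularity_decomposition(g: Graph, p: Partition) -> ModularityDecomposition:
    missing = set(g.nodes) - p.nodes
    if missing:
        raise GraphError(
            f"partition is missing node(s), e.g. {sorted(missing)[0]!r}"
        )
    m = g.n_edges
    if m == 0:
        raise GraphError("modularity of an edgeless graph is undefined")
    labels = p.labels_for(g.nodes)
    k = int(labels.max()) + 1 if labels.size else 0
    e = np.zeros((k, k))
    edge_idx = g.edge_indices()
    for i, j in edge_idx:
        ci, cj = labels[i], labels[j]
        e[ci, cj] += 1.0
        e[cj, ci] += 1.0
    e /= 2.0 * m
    a = e.sum(axis=1)
    return ModularityDecomposition(e=e, a=a, m=m)


def modularity(g: Graph, p: Partition) -> float:
    """Newman modularity Q of partition ``p`` on graph ``g``; Q in [-1, 1)."""
    return modularity_decomposition(g, p).q


def modularity_from_labels(
    edge_idx: np.ndarray, degrees: np.ndarray, labels: np.ndarray, m: int
) -> float:
    """Fast Q for array-encoded partitions (used by dendrogram scans).

    Q = sum_i (e_ii - a_i^2) with e_ii = (internal edges of i)/m and
    a_i = (degree sum of i)/(2m).
    """
    internal = labels[edge_idx[:, 0]] == labels[edge_idx[:, 1]]
    k = int(labels.max()) + 1
    e_ii = np.bincount(labels[edge_idx[:, 0]][internal], minlength=k) / m
    a = np.bincount(labels, weights=degrees, minlength=k) / (2.0 * m)
    return float(e_ii.sum() - (a**2).sum())


@dataclass(frozen=True)
class ContingencyTable:
    """Community-overlap counts between two partitions of the same nodes."""

    n: np.ndarray  # R x C shared-node counts
    a: np.ndarray  # row sums
    b: np.ndarray  # column sums
    total: int     # N, total node count


def contingency(u: Partition, v: Partition) -> ContingencyTable:
    if u.nodes != v.nodes:
        diff = len(u.nodes ^ v.nodes)
        raise GraphError(f"partitions cover different node sets ({diff} differ)")
    nodes = sorted(u.nodes)
    lu = u.labels_for(nodes)
    lv = v.labels_for(nodes)
    r = int(lu.max()) + 1 if lu.size else 0
    c = int(lv.max()) + 1 if lv.size else 0
    n = np.zeros((r, c), dtype=np.int64)
    np.add.at(n, (lu, lv), 1)
    return ContingencyTable(n=n, a=n.sum(axis=1), b=n.sum(axis=0), total=len(nodes))


def _entropy(counts: np.ndarray, total: int) -> float:
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def mutual_information(table: ContingencyTable) -> float:
    """I(U, V) in nats from a contingency table; 0 log 0 terms are 0."""
    n, a, b, total = table.n, table.a, table.b, table.total
    nz = n > 0
    nij = n[nz].astype(float)
    ai = np.broadcast_to(a[:, None], n.shape)[nz].astype(float)
    bj = np.broadcast_to(b[None, :], n.shape)[nz].astype(float)
    return float(np.sum(nij / total * np.log(nij * total / (ai * bj))))


def nmi(u: Partition, v: Partition, variant: str = "max") -> float:
    """Normalized mutual information between two partitions.

    variant "max": I / max(H(U), H(V)) (1.0 for identical partitions);
    variant "sum": I / (H(U) + H(V)) (0.5 for identical partitions).
    Both single-block: 1.0 for "max" by convention; exactly one entropy
    zero: 0.0.
    """
    if variant not in ("max", "sum"):
        raise ValueError(f"unknown NMI variant {variant!r}")
    table = contingency(u, v)
    hu = _entropy(table.a, table.total)
    hv = _entropy(table.b, table.total)
    if hu == 0.0 and hv == 0.0:
        return 1.0 if variant == "max" else 0.5
    if hu == 0.0 or hv == 0.0:
        return 0.0
    i = mutual_information(table)
    denom = max(hu, hv) if variant == "max" else hu + hv
    return i / denom


# -- partition I/O ---------------------------------------------------------


def read_partition(path: str | Path) -> Partition:
    """Read a ``node<TAB>community_id`` TSV (``#`` comments allowed)."""
    memb: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphError(f"{path}:{lineno}: expected node and community id")
            memb[tokens[0]] = int(tokens[1])
    return Partition.from_membership(memb)


def write_partition(p: Partition, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for node in sorted(p.membership):
            fh.write(f"{node}\t{p.membership[node]}\n")
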