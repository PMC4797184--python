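"""Shared fixtures: small hand-built graphs and planted benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from pinmod import BenchmarkConfig, Graph, generate


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangles() -> Graph:
    """Two disjoint triangles."""
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f")]
    )


@pytest.fixture
def bridge_graph() -> Graph:
    """Two triangles joined by a single bridge edge c-d."""
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )


@pytest.fixture
def path_p3() -> Graph:
    return Graph.from_edges([("a", "b"), ("b", "c")])


def random_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    """Erdos-Renyi helper for oracle comparisons."""
    nodes = [f"v{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph.from_edges(edges, nodes=nodes)


@pytest.fixture(scope="session")
def planted_small():
    """One small, well-separated planted benchmark reused across tests."""
    return generate(BenchmarkConfig(n=300, mu=0.05, k_min=30, k_max=60, seed=11))
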