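"""Experiment orchestration: detection sweeps, planted-partition recovery,
perturbation robustness, table summaries and the Q-vs-module-count regression.

All stochastic steps derive their randomness hierarchically from a single
top-level seed (numpy ``SeedSequence.spawn``), so a rerun of any experiment
with the same configuration is bit-identical.  Results are long-format
pandas tables that round-trip losslessly through CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .benchmark import (
    BenchmarkConfig,
    PlantedNetwork,
    add_random_edges,
    delete_random_edges,
    generate,
)
from .detect import CORRELATION_METHODS, detect_communities
from .graph import Graph, all_pairs_shortest_paths, giant_connected_component
from .metrics import Partition, modularity, nmi
from .reference import NATIVE_METHODS, AlgorithmSpec, run_algorithm

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MU_GRID",
    "DEFAULT_ADD_FRACTIONS",
    "truncate",
    "column_mean",
    "run_detection_suite",
    "planted_recovery",
    "run_perturbation_experiment",
    "modularity_vs_count_regression",
]

#: the study's mixing-parameter grid
DEFAULT_MU_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50)
#: the study's random-edge-addition fractions
DEFAULT_ADD_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


def truncate(x: float, decimals: int = 4) -> float:
    """Truncate toward zero at ``decimals`` places (table convention)."""
    factor = 10.0**decimals
    return math.trunc(x * factor) / factor


def column_mean(
    table: pd.DataFrame, method: str, metric: str, decimals: int | None = 4
) -> float:
    """Arithmetic mean of one metric for one method over all networks.

    With ``decimals`` set, the mean is truncated toward zero at that many
    places (the convention of printed summary rows); pass ``None`` for full
    precision.
    """
    sel = table[(table["method"] == method) & (table["metric"] == metric)]
    if sel.empty:
        raise ValueError(f"no records for method={method!r}, metric={metric!r}")
    mean = float(sel["value"].mean())
    return truncate(mean, decimals) if decimals is not None else mean


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n child seeds < 2**31 derived from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_detection_suite(
    networks: dict[str, Graph],
    methods: tuple[str, ...] = NATIVE_METHODS,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every method on every network; record Q and module counts.

    Failures (e.g. a missing external backend) are recorded per cell and do
    not abort the sweep.
    """
    if not methods:
        raise ValueError("no methods requested")
    rows = []
    seeds = _spawn_seeds(seed, len(networks) * len(methods))
    i = 0
    for net_name, g in networks.items():
        for method in methods:
            child = seeds[i]
            i += 1
            try:
                p = run_algorithm(g, AlgorithmSpec(name=method, seed=child))
                rows.append(
                    dict(network=net_name, method=method, replicate=0,
                         metric="Q", value=modularity(g, p))
                )
                rows.append(
                    dict(network=net_name, method=method, replicate=0,
                         metric="n_modules", value=float(p.n_communities))
                )
            except Exception as exc:  # noqa: BLE001 - isolation contract
                logger.warning("%s on %s failed: %s", method, net_name, exc)
                rows.append(
                    dict(network=net_name, method=method, replicate=0,
                         metric="failed", value=float("nan"))
                )
    return pd.DataFrame(rows)


def planted_recovery(
    mu_values: tuple[float, ...] = DEFAULT_MU_GRID,
    n_replicates: int = 20,
    methods: tuple[str, ...] = NATIVE_METHODS,
    base_config: BenchmarkConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """NMI between detected and planted partitions over a mu grid.

    For every mu, ``n_replicates`` benchmark networks are generated and each
    method's partition is scored against the planted truth with NMI (max
    variant).  Long-format records (network id = "mu<mu>/r<rep>").
    """
    if base_config is None:
        base_config = BenchmarkConfig()
    rows = []
    seeds = _spawn_seeds(seed, len(mu_values) * n_replicates)
    i = 0
    for mu in mu_values:
        for rep in range(n_replicates):
            child = seeds[i]
            i += 1
            cfg = replace(base_config, mu=mu, seed=child)
            pn = generate(cfg)
            # analyses run on the giant component, as with the real networks
            g = giant_connected_component(pn.graph)
            truth = pn.truth.restrict(set(g.nodes))
            s = None
            for method in methods:
                if method in CORRELATION_METHODS:
                    if s is None:
                        s = all_pairs_shortest_paths(g)
                    p = detect_communities(g, CORRELATION_METHODS[method], s=s)
                else:
                    p = run_algorithm(g, AlgorithmSpec(name=method, seed=child))
                rows.append(
                    dict(network=f"mu{mu:g}/r{rep}", method=method,
                         replicate=rep, metric="NMI_vs_truth",
                         value=nmi(truth, p), mu=mu)
                )
    return pd.DataFrame(rows)


def run_perturbation_experiment(
    mode: str,
    base: PlantedNetwork | None = None,
    fractions: tuple[float, ...] = DEFAULT_ADD_FRACTIONS,
    n_replicates: int = 20,
    methods: tuple[str, ...] = NATIVE_METHODS,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness experiment on a planted benchmark.

    mode "add": for each fraction and replicate, add that share of random
    edges and record the modularity of each method's partition on the
    perturbed graph (plus NMI vs the unperturbed run).
    mode "delete": delete each fraction of edges under the degree>=2 /
    non-bridge guards and record NMI between the perturbed and unperturbed
    detections (node set is unchanged by deletion).
    """
    if mode not in ("add", "delete"):
        raise ValueError("mode must be 'add' or 'delete'")
    if base is None:
        base = generate(BenchmarkConfig(seed=seed))
    g0 = giant_connected_component(base.graph)
    reference: dict[str, Partition] = {}
    for method in methods:
        reference[method] = run_algorithm(g0, AlgorithmSpec(name=method, seed=seed))
    rows = []
    seeds = _spawn_seeds(seed, len(fractions) * n_replicates)
    i = 0
    for frac in fractions:
        for rep in range(n_replicates):
            rng = np.random.default_rng(seeds[i])
            i += 1
            try:
                if mode == "add":
                    g = add_random_edges(g0, frac, rng)
                else:
                    g = delete_random_edges(g0, frac, rng)
            except Exception as exc:  # noqa: BLE001 - recorded failure
                logger.warning("perturbation %s %.2f failed: %s", mode, frac, exc)
                rows.append(
                    dict(network=f"{mode}{frac:g}/r{rep}", method="-",
                         replicate=rep, metric="perturbation_failed",
                         value=float("nan"), fraction=frac)
                )
                continue
            for method in methods:
                p = run_algorithm(g, AlgorithmSpec(name=method, seed=seeds[i - 1]))
                rows.append(
                    dict(network=f"{mode}{frac:g}/r{rep}", method=method,
                         replicate=rep, metric="Q", value=modularity(g, p),
                         fraction=frac)
                )
                rows.append(
                    dict(network=f"{mode}{frac:g}/r{rep}", method=method,
                         replicate=rep, metric="NMI_vs_unperturbed",
                         value=nmi(reference[method], p), fraction=frac)
                )
    return pd.DataFrame(rows)


def modularity_vs_count_regression(
    points: list[tuple[float, float]], order: int = 2
) -> dict:
    """Ordinary least squares of Q on the module count (and its square).

    Returns coefficient estimates and two-sided t-test significances per
    term (keys "const", "x", and "x2" for order 2).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if len(points) < order + 2:
        raise ValueError(f"need at least {order + 2} points for order {order}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("design is rank deficient: all module counts equal")
    cols = [x] if order == 1 else [x, x**2]
    design = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, design).fit()
    names = ["const", "x"] + (["x2"] if order == 2 else [])
    return {
        "params": dict(zip(names, map(float, fit.params))),
        "pvalues": dict(zip(names, map(float, fit.pvalues))),
        "rsquared": float(fit.rsquared),
        "rsquared_adj": float(fit.rsquared_adj),
    }
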