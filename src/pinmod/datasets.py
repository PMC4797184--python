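"""Bundled reference tables.

Small curated tables for ten BioGRID-derived protein interaction networks
(giant connected components) and four Homo sapiens experimental subnetworks:
node/edge counts with published edge densities, and per-method modularity
and module-count summaries for the nine detection methods.  They serve as
fixed inputs for summary statistics and regression analyses; nothing here is
recomputed from raw interaction data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["pin_networks", "pin_modularity", "pin_module_counts", "METHODS"]

#: column order of the nine methods in the bundled tables
METHODS = (
    "dm-pearson",
    "dm-spearman",
    "dsp-pearson",
    "dsp-spearman",
    "fastgreedy",
    "labelprop",
    "multilevel",
    "spinglass",
    "walktrap",
)


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("pinmod").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kwargs)


def pin_networks() -> pd.DataFrame:
    """Network sizes and published edge densities (14 rows).

    The ``density`` column keeps the published string representation so its
    printed precision is recoverable.
    """
    return _load("pin_networks.tsv", dtype={"density": str, "tax_id": str})


def pin_modularity() -> pd.DataFrame:
    """Per-network modularity Q of the nine methods, indexed by network."""
    return _load("pin_modularity.tsv", index_col="network")


def pin_module_counts() -> pd.DataFrame:
    """Per-network module counts of the nine methods, indexed by network."""
    return _load("pin_module_counts.tsv", index_col="network")
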