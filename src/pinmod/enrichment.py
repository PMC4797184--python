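"""Module-wise gene-set overrepresentation analysis.

Each (module, term) pair gets a one-sided Fisher's exact test on the 2x2
table [[k, K-k], [t-k, N-K-t+k]] — k annotated genes inside a module of
size K, against t annotated genes in a background of N — followed by a
Bonferroni correction over all tests performed.  Summaries count, per term,
in how many modules it is significant (the multi-module histogram) and how
many organisms share a significant term.

A synthetic-annotation generator aligned with a planted partition makes the
whole pipeline testable without any ontology download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .benchmark import PlantedNetwork
from .metrics import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "MultiModuleSummary",
    "read_annotations",
    "fisher_enrichment",
    "bonferroni_filter",
    "multi_module_summary",
    "cross_organism_overlap",
    "synthetic_annotations",
    "results_frame",
]


@dataclass
class AnnotationSet:
    """term id -> gene set, with an optional organism tag and term names."""

    terms: dict[str, set[str]]
    organism: str = ""
    names: dict[str, str] = field(default_factory=dict)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def restrict(self, background: set[str]) -> "AnnotationSet":
        """Intersect every term with a background; empty terms are dropped."""
        kept = {
            t: genes & background
            for t, genes in self.terms.items()
            if genes & background
        }
        return AnnotationSet(terms=kept, organism=self.organism,
                             names=dict(self.names))


@dataclass
class EnrichmentResult:
    """One (module, term) overrepresentation test."""

    module: int
    term: str
    k: int        # annotated genes inside the module
    K: int        # module size
    t: int        # annotated genes in the background
    N: int        # background size
    p_raw: float
    significant: bool = False


def read_annotations(path: str | Path, format: str = "gmt") -> AnnotationSet:
    """Read annotations from GMT (term, description, genes...) or a
    two-column ``gene<TAB>term`` TSV; duplicate pairs collapse."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if format == "gmt":
                if len(tokens) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs term, description "
                        "and at least one gene"
                    )
                term, desc, genes = tokens[0], tokens[1], tokens[2:]
                terms.setdefault(term, set()).update(g for g in genes if g)
                names[term] = desc
            elif format == "two-column":
                if len(tokens) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected gene and term columns"
                    )
                gene, term = tokens[0], tokens[1]
                terms.setdefault(term, set()).add(gene)
            else:
                raise ValueError(f"unknown annotation format {format!r}")
    if not terms:
        logger.warning("annotation file %s is empty", path)
    return AnnotationSet(terms=terms, names=names)


def fisher_enrichment(
    p: Partition, ann: AnnotationSet, background: set[str]
) -> list[EnrichmentResult]:
    """One-sided (greater) Fisher's exact test for every (module, term).

    Terms are restricted to the background before counting; pairs with an
    empty term-background intersection are not tested.  The tail probability
    is the hypergeometric survival P(X >= k).
    """
    if not background:
        raise ValueError("empty background")
    extra = background - p.nodes
    if extra:
        raise ValueError(
            f"background contains {len(extra)} node(s) outside the partition"
        )
    restricted = ann.restrict(background)
    n_bg = len(background)
    results: list[EnrichmentResult] = []
    communities = p.restrict(background).communities()
    for module_id, members in enumerate(communities):
        big_k = len(members)
        for term, genes in sorted(restricted.terms.items()):
            t = len(genes)
            k = len(genes & members)
            p_raw = float(hypergeom.sf(k - 1, n_bg, t, big_k))
            results.append(
                EnrichmentResult(
                    module=module_id, term=term, k=k, K=big_k, t=t, N=n_bg,
                    p_raw=min(p_raw, 1.0),
                )
            )
    return results


def bonferroni_filter(
    results: list[EnrichmentResult], alpha: float = 0.001
) -> list[EnrichmentResult]:
    """Mark results significant where p_raw <= alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_tests = len(results)
    if n_tests == 0:
        return results
    threshold = alpha / n_tests
    for r in results:
        r.significant = r.p_raw <= threshold
    return results


@dataclass(frozen=True)
class MultiModuleSummary:
    """How many modules each significant term is enriched in."""

    per_term: dict[str, int]
    histogram: dict[int, int]
    max_modules: int


def multi_module_summary(results: list[EnrichmentResult]) -> MultiModuleSummary:
    per_term: dict[str, int] = {}
    for r in results:
        if r.significant:
            per_term[r.term] = per_term.get(r.term, 0) + 1
    histogram: dict[int, int] = {}
    for count in per_term.values():
        histogram[count] = histogram.get(count, 0) + 1
    return MultiModuleSummary(
        per_term=per_term,
        histogram=histogram,
        max_modules=max(per_term.values(), default=0),
    )


def cross_organism_overlap(
    per_organism_terms: Sequence[set[str]],
) -> dict[int, set[str]]:
    """Group terms by the number of organisms in which they are significant."""
    if len(per_organism_terms) < 2:
        raise ValueError("need significant-term sets for at least 2 organisms")
    counts: dict[str, int] = {}
    for terms in per_organism_terms:
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    out: dict[int, set[str]] = {}
    for t, c in counts.items():
        out.setdefault(c, set()).add(t)
    return out


def synthetic_annotations(
    pn: PlantedNetwork,
    terms_per_community: int = 1,
    coverage: float = 0.8,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    n_random_terms: int = 5,
) -> AnnotationSet:
    """Annotation fixture aligned with a planted partition.

    Each planted community contributes ``terms_per_community`` terms holding
    a ``coverage`` fraction of its nodes plus a ``noise`` fraction of random
    outside nodes; ``n_random_terms`` unaligned terms act as negatives.
    Deterministic given the generator state.
    """
    if not 0 <= coverage <= 1 or not 0 <= noise <= 1:
        raise ValueError("coverage and noise must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    all_nodes = np.array(sorted(pn.truth.nodes))
    terms: dict[str, set[str]] = {}
    for cid, members in enumerate(pn.truth.communities()):
        members_arr = np.array(sorted(members))
        outside = np.array(sorted(set(all_nodes) - members))
        for j in range(terms_per_community):
            n_in = max(1, int(round(coverage * members_arr.size)))
            picked = set(
                rng.choice(members_arr, size=n_in, replace=False).tolist()
            )
            n_out = int(round(noise * n_in))
            if n_out and outside.size:
                picked |= set(
                    rng.choice(
                        outside, size=min(n_out, outside.size), replace=False
                    ).tolist()
                )
            terms[f"COMM{cid:03d}_T{j}"] = picked
    avg_size = max(2, int(np.mean([len(v) for v in terms.values()]))) if terms else 5
    for j in range(n_random_terms):
        terms[f"RAND_T{j}"] = set(
            rng.choice(all_nodes, size=min(avg_size, all_nodes.size),
                       replace=False).tolist()
        )
    return AnnotationSet(terms=terms, organism="synthetic")


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Long-format table (module, term, k, K, t, N, p_raw, significant)."""
    return pd.DataFrame(
        [
            {
                "module": r.module, "term": r.term, "k": r.k, "K": r.K,
                "t": r.t, "N": r.N, "p_raw": r.p_raw,
                "significant": r.significant,
            }
            for r in results
        ]
    )
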