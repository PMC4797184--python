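"""Gene-set overrepresentation: Fisher tail, Bonferroni, summaries,
synthetic annotations."""

import math

import numpy as np
import pytest

from pinmod import (
    AnnotationSet,
    BenchmarkConfig,
    Partition,
    bonferroni_filter,
    cross_organism_overlap,
    fisher_enrichment,
    generate,
    multi_module_summary,
    read_annotations,
    synthetic_annotations,
)


def hypergeom_tail_oracle(k: int, n_bg: int, t: int, big_k: int) -> float:
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(t, big_k) + 1):
        total += (
            math.comb(t, x)
            * math.comb(n_bg - t, big_k - x)
            / math.comb(n_bg, big_k)
        )
    return total


class TestReadAnnotations:
    def test_gmt_line(self, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("T1\tdesc\tg1\tg2\n")
        ann = read_annotations(f, format="gmt")
        assert ann.terms == {"T1": {"g1", "g2"}}
        assert ann.names["T1"] == "desc"

    def test_two_column_dedupe(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("g1\tT1\ng2\tT1\ng1\tT1\n")
        ann = read_annotations(f, format="two-column")
        assert ann.terms == {"T1": {"g1", "g2"}}

    def test_empty_file_warns(self, tmp_path, caplog):
        f = tmp_path / "a.gmt"
        f.write_text("")
        with caplog.at_level("WARNING"):
            ann = read_annotations(f)
        assert ann.n_terms == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_malformed_gmt_names_line(self, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("T1\tdesc\tg1\nT2\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_annotations(f)


class TestFisherEnrichment:
    def test_hand_computed_table(self):
        # N=20, module of 5, term of 5, overlap 4:
        # p = [C(5,4)C(15,1)+C(5,5)C(15,0)] / C(20,5) = 76/15504
        nodes = [f"g{i:02d}" for i in range(20)]
        module = set(nodes[:5])
        p = Partition.from_communities([module, set(nodes[5:])])
        ann = AnnotationSet(terms={"T": set(nodes[:4]) | {nodes[10]}})
        res = fisher_enrichment(p, ann, background=set(nodes))
        r = next(x for x in res if x.module == p.membership[nodes[0]])
        assert r.k == 4 and r.K == 5 and r.t == 5 and r.N == 20
        assert r.p_raw == pytest.approx(76 / 15504)

    def test_zero_overlap_full_tail(self):
        nodes = [f"g{i}" for i in range(10)]
        p = Partition.from_communities([set(nodes[:5]), set(nodes[5:])])
        ann = AnnotationSet(terms={"T": set(nodes[5:8])})
        res = fisher_enrichment(p, ann, background=set(nodes))
        r0 = next(x for x in res if x.k == 0)
        assert r0.p_raw == pytest.approx(1.0)

    def test_module_equals_background_degenerate(self):
        nodes = [f"g{i}" for i in range(8)]
        p = Partition.from_communities([set(nodes)])
        ann = AnnotationSet(terms={"T": set(nodes[:3])})
        res = fisher_enrichment(p, ann, background=set(nodes))
        assert res[0].p_raw == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        p = Partition.from_communities([{"a"}])
        with pytest.raises(ValueError):
            fisher_enrichment(p, AnnotationSet(terms={"T": {"a"}}), set())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_bg = int(rng.integers(8, 26))
        nodes = [f"g{i:02d}" for i in range(n_bg)]
        split = int(rng.integers(2, n_bg - 1))
        p = Partition.from_communities([set(nodes[:split]), set(nodes[split:])])
        t_size = int(rng.integers(1, n_bg))
        term = set(rng.choice(nodes, size=t_size, replace=False).tolist())
        res = fisher_enrichment(p, AnnotationSet(terms={"T": term}), set(nodes))
        for r in res:
            assert r.p_raw == pytest.approx(
                hypergeom_tail_oracle(r.k, r.N, r.t, r.K), abs=1e-12
            )
            assert r.k <= min(r.K, r.t)

    def test_matches_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        nodes = [f"g{i:02d}" for i in range(24)]
        p = Partition.from_communities([set(nodes[:9]), set(nodes[9:])])
        term = set(nodes[4:12])
        res = fisher_enrichment(p, AnnotationSet(terms={"T": term}), set(nodes))
        for r in res:
            table = [[r.k, r.K - r.k], [r.t - r.k, r.N - r.K - r.t + r.k]]
            _, expected = fisher_exact(table, alternative="greater")
            assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_background_restriction_never_increases_counts(self):
        nodes = [f"g{i:02d}" for i in range(30)]
        p = Partition.from_communities([set(nodes[:15]), set(nodes[15:])])
        ann = AnnotationSet(terms={"T": set(nodes[:10]) | {"outside1"}})
        res = fisher_enrichment(p, ann, background=set(nodes))
        assert all(r.t <= 10 for r in res)


class TestBonferroni:
    def test_threshold_division(self):
        from pinmod.enrichment import EnrichmentResult

        results = [
            EnrichmentResult(module=0, term=f"T{i}", k=1, K=1, t=1, N=2,
                             p_raw=1e-7)
            for i in range(1000)
        ]
        out = bonferroni_filter(results, alpha=0.001)
        assert all(r.significant for r in out)  # 1e-7 <= 1e-6

    def test_single_test(self):
        from pinmod.enrichment import EnrichmentResult

        r = EnrichmentResult(module=0, term="T", k=1, K=1, t=1, N=2,
                             p_raw=0.0005)
        assert bonferroni_filter([r], alpha=0.001)[0].significant

    def test_boundary_is_inclusive(self):
        from pinmod.enrichment import EnrichmentResult

        r1 = EnrichmentResult(module=0, term="A", k=1, K=1, t=1, N=2,
                              p_raw=0.0005)
        r2 = EnrichmentResult(module=0, term="B", k=1, K=1, t=1, N=2,
                              p_raw=0.9)
        out = bonferroni_filter([r1, r2], alpha=0.001)
        assert out[0].significant  # exactly at 0.001/2
        assert not out[1].significant

    def test_empty_list(self):
        assert bonferroni_filter([]) == []


class TestSummaries:
    def _results(self, spec):
        from pinmod.enrichment import EnrichmentResult

        return [
            EnrichmentResult(module=m, term=t, k=1, K=1, t=1, N=2,
                             p_raw=0.5, significant=sig)
            for t, m, sig in spec
        ]

    def test_multi_module_counts(self):
        res = self._results(
            [("T1", 1, True), ("T1", 3, True), ("T2", 0, True),
             ("T3", 2, False)]
        )
        s = multi_module_summary(res)
        assert s.per_term == {"T1": 2, "T2": 1}
        assert s.histogram == {1: 1, 2: 1}
        assert s.max_modules == 2
        assert sum(s.histogram.values()) == len(s.per_term)

    def test_no_significant(self):
        s = multi_module_summary(self._results([("T1", 0, False)]))
        assert s.histogram == {} and s.max_modules == 0

    def test_cross_organism_overlap(self):
        out = cross_organism_overlap([{"A", "B"}, {"B", "C"}])
        assert out == {2: {"B"}, 1: {"A", "C"}}

    def test_cross_organism_all_shared(self):
        out = cross_organism_overlap([{"X"}] * 6)
        assert out == {6: {"X"}}

    def test_cross_organism_needs_two(self):
        with pytest.raises(ValueError):
            cross_organism_overlap([{"A"}])


class TestSyntheticAnnotations:
    def test_full_coverage_no_noise_equals_communities(self, planted_small):
        rng = np.random.default_rng(0)
        ann = synthetic_annotations(planted_small, coverage=1.0, noise=0.0,
                                    rng=rng)
        comms = {frozenset(c) for c in planted_small.truth.communities()}
        aligned = {t: g for t, g in ann.terms.items() if t.startswith("COMM")}
        assert {frozenset(g) for g in aligned.values()} == comms

    def test_determinism(self, planted_small):
        a1 = synthetic_annotations(planted_small,
                                   rng=np.random.default_rng(4))
        a2 = synthetic_annotations(planted_small,
                                   rng=np.random.default_rng(4))
        assert a1.terms == a2.terms

    def test_aligned_terms_enrich_exactly_one_module(self, planted_small):
        """The pipeline property: clean aligned terms light up exactly one
        module of the planted partition after Bonferroni."""
        rng = np.random.default_rng(1)
        ann = synthetic_annotations(planted_small, coverage=0.8, noise=0.0,
                                    rng=rng)
        truth = planted_small.truth
        res = fisher_enrichment(truth, ann, background=truth.nodes)
        res = bonferroni_filter(res, alpha=0.001)
        summary = multi_module_summary(res)
        for term in ann.terms:
            if term.startswith("COMM"):
                assert summary.per_term.get(term, 0) == 1
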