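"""Hypergeometric testing, Bonferroni adjustment and the pathway network."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from diseasome import enrichment
from diseasome.enrichment import Direction, PathwayCollection
from diseasome.integrate import Category

from oracles import exact_tails, exact_two_sided


def collection(**sets):
    pathways = {pid: (pid, frozenset(genes)) for pid, genes in sets.items()}
    universe = frozenset(g for _, gs in pathways.values() for g in gs)
    return PathwayCollection(pathways, universe)


class TestReadGmt:
    def test_universe_is_union(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\tdesc\tA\tB\tC\np2\tdesc\tC\tD\n")
        coll = enrichment.read_gmt(path)
        assert coll.universe == frozenset("ABCD")
        assert len(coll) == 2

    def test_duplicate_genes_collapse(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\tdesc\tA\tA\tB\n")
        coll = enrichment.read_gmt(path)
        assert coll.pathways["p1"][1] == frozenset("AB")

    def test_short_line_skipped_and_counted(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\tonlydesc\np2\tdesc\tA\n")
        coll = enrichment.read_gmt(path)
        assert len(coll) == 1 and coll.skipped_lines == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("")
        coll = enrichment.read_gmt(path)
        assert len(coll) == 0 and coll.universe == frozenset()


class TestTwoSided:
    def test_worked_enrichment_tail(self):
        p, direction = enrichment.hypergeom_two_sided(4, 5, 4, 10)
        assert direction is Direction.ENRICHED
        assert p == pytest.approx(float(2 * Fraction(5, 210)), rel=1e-12)
        p_e, _ = exact_tails(4, 5, 4, 10)
        assert p_e == Fraction(5, 210)

    def test_worked_depletion_tail(self):
        p, direction = enrichment.hypergeom_two_sided(0, 5, 4, 10)
        assert direction is Direction.DEPLETED
        assert p == pytest.approx(float(2 * Fraction(5, 210)), rel=1e-12)

    def test_pathway_equals_universe_degenerate(self):
        p, direction = enrichment.hypergeom_two_sided(4, 10, 4, 10)
        assert p == 1.0 and direction is Direction.ENRICHED

    @pytest.mark.parametrize("k,K,n,N", [(-1, 5, 4, 10), (5, 5, 4, 10),
                                         (0, 11, 4, 10), (0, 5, 11, 10),
                                         (0, 8, 8, 10)])
    def test_out_of_support_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            enrichment.hypergeom_two_sided(k, K, n, N)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=60, deadline=None)
    def test_tail_monotonicity_in_k(self, N, K, n):
        """p_e non-increasing and p_d non-decreasing along the support."""
        K, n = min(K, N), min(n, N)
        lo, hi = max(0, n + K - N), min(K, n)
        from scipy.stats import hypergeom
        prev_e, prev_d = 1.1, -0.1
        for k in range(lo, hi + 1):
            p_e = float(hypergeom.sf(k - 1, N, K, n))
            p_d = float(hypergeom.cdf(k, N, K, n))
            assert p_e <= prev_e + 1e-12
            assert p_d >= prev_d - 1e-12
            prev_e, prev_d = p_e, p_d

    @given(st.integers(2, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(0, 30))
    @settings(max_examples=80, deadline=None)
    def test_doubled_p_matches_exact_enumeration(self, N, K, n, k):
        K, n = min(K, N), min(n, N)
        lo, hi = max(0, n + K - N), min(K, n)
        k = lo + k % (hi - lo + 1)
        p, _ = enrichment.hypergeom_two_sided(k, K, n, N)
        assert p == pytest.approx(float(exact_two_sided(k, K, n, N)), rel=1e-9)

    def test_minlike_variant_sums_unlikelier_outcomes(self):
        from math import comb
        # X ~ HG(10, 5, 4): pmf over k=0..4 is (5,50,100,50,5)/210
        p, direction = enrichment.hypergeom_two_sided(4, 5, 4, 10, method="minlike")
        assert direction is Direction.ENRICHED
        assert p == pytest.approx(float(Fraction(10, 210)), rel=1e-9)
        p, _ = enrichment.hypergeom_two_sided(3, 5, 4, 10, method="minlike")
        assert p == pytest.approx(float(Fraction(110, 210)), rel=1e-9)


class TestEnrichDisease:
    UNIVERSE_COLL = None

    def setup_method(self):
        self.coll = collection(
            P1=frozenset("ABCDE"), P2=frozenset("FGHIJ"),
        )  # universe A..J, N = 10

    def test_disease_outside_universe_untestable(self):
        assert enrichment.enrich_disease({"Z1", "Z2"}, self.coll) == []

    def test_worked_record_composition(self):
        records = enrichment.enrich_disease(
            set("ABCD"), self.coll, disease_id="OMIM:1"
        )
        by_id = {r.pathway_id: r for r in records}
        rec = by_id["P1"]
        assert (rec.k, rec.K, rec.n, rec.N, rec.m_tests) == (4, 5, 4, 10, 2)
        assert rec.p_value == pytest.approx(float(Fraction(10, 210)), rel=1e-12)
        assert rec.adj_p == pytest.approx(2 * rec.p_value, rel=1e-12)
        assert rec.direction is Direction.ENRICHED

    def test_single_pathway_family_adj_equals_raw(self):
        coll = collection(P1=frozenset("ABCDE"))
        (rec,) = enrichment.enrich_disease(set("ABC"), coll)
        assert rec.adj_p == pytest.approx(rec.p_value)

    def test_adj_p_monotone_and_capped(self, default_table, default_bundle):
        bundle, _ = default_bundle
        coll = enrichment.read_gmt(bundle.gmt)
        genes = default_table.disease_genes()
        did = sorted(genes)[0]
        records = enrichment.enrich_disease(genes[did], coll, disease_id=did)
        records.sort(key=lambda r: r.p_value)
        adj = [r.adj_p for r in records]
        assert adj == sorted(adj)
        assert all(r.p_value <= r.adj_p <= 1.0 for r in records)

    def test_restricted_universe_changes_background(self):
        records = enrichment.enrich_disease(
            set("ABZ"), self.coll, universe=frozenset("ABCDEFGHIJKLMNOPQRST")
        )
        assert all(r.N == 20 for r in records)
        assert all(r.n == 2 for r in records)  # Z outside the universe


class TestDiseasePathwayNetwork:
    def _record(self, did, pid, adj_p, direction=Direction.ENRICHED):
        return enrichment.EnrichmentRecord(
            did, pid, 3, 5, 4, 20, adj_p / 2, adj_p, direction, 2
        )

    def test_enriched_significant_record_becomes_edge(self):
        g = enrichment.build_disease_pathway_network(
            [self._record("OMIM:1", "p1", 0.04)], alpha=0.05
        )
        assert g.has_edge("OMIM:1", "p1")

    def test_depleted_record_never_an_edge(self):
        g = enrichment.build_disease_pathway_network(
            [self._record("OMIM:1", "p1", 0.04, Direction.DEPLETED)], alpha=0.05
        )
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 0

    def test_nonsignificant_record_excluded(self):
        g = enrichment.build_disease_pathway_network(
            [self._record("OMIM:1", "p1", 0.2)], alpha=0.05
        )
        assert g.number_of_nodes() == 0

    def test_alpha_one_keeps_every_enriched_record(self):
        records = [self._record(f"OMIM:{i}", "p1", 0.5 + i / 10) for i in range(4)]
        g = enrichment.build_disease_pathway_network(records, alpha=1.0)
        assert g.number_of_edges() == 4

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment.build_disease_pathway_network([], alpha=0.0)


class TestSharedPathwayPairs:
    def _network(self, od_ids, cd_ids, pathway="hsaX"):
        cats = {d: Category.OD for d in od_ids} | {d: Category.CD for d in cd_ids}
        records = [
            enrichment.EnrichmentRecord(d, pathway, 3, 5, 4, 20, 0.01, 0.02,
                                        Direction.ENRICHED, 1)
            for d in (*od_ids, *cd_ids)
        ]
        return enrichment.build_disease_pathway_network(
            records, alpha=0.05, categories=cats
        )

    def test_single_pair(self):
        g = self._network(["ORPHA:1"], ["OMIM:2"])
        assert enrichment.shared_pathway_pairs(g) == [("ORPHA:1", "OMIM:2", "hsaX")]

    def test_pathway_touched_only_by_ods_yields_nothing(self):
        g = self._network(["ORPHA:1", "ORPHA:2"], [])
        assert enrichment.shared_pathway_pairs(g) == []

    def test_product_count(self):
        g = self._network(["ORPHA:1", "ORPHA:2"], ["OMIM:1", "OMIM:2", "OMIM:3"])
        assert len(enrichment.shared_pathway_pairs(g)) == 6

    def test_both_disease_pairs_with_others_not_itself(self):
        cats = {"OMIM:9": Category.BOTH, "OMIM:2": Category.CD}
        records = [
            enrichment.EnrichmentRecord(d, "hsaX", 3, 5, 4, 20, 0.01, 0.02,
                                        Direction.ENRICHED, 1)
            for d in ("OMIM:9", "OMIM:2")
        ]
        g = enrichment.build_disease_pathway_network(records, categories=cats)
        assert enrichment.shared_pathway_pairs(g) == [("OMIM:9", "OMIM:2", "hsaX")]
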