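"""Drug-target overrepresentation, bridge expansion, consensus ranking."""

import logging

import pytest

from repurpose.drug_mining import (BridgeMap, DrugEnrichmentResult, Interaction,
                                   InteractionTable, bridge_expand,
                                   consensus_rank, enrich_drugs, read_results,
                                   write_results)
from repurpose.gene_catalog import GeneSet
from repurpose.synthetic_data import EnrichmentSimConfig, simulate_interactions


def _result(drug_id, p, q):
    return DrugEnrichmentResult(drug_id=drug_id, k=1, K=1, n=1, N=10,
                                statistic=None, p_value=p, q_value=q,
                                rank=1, candidate=q <= 0.05)


class TestInteractionTable:
    def test_normalizes_and_rejects_duplicates(self):
        table = InteractionTable([Interaction("d1", "x", " myoc ", "S")])
        assert table.genes() == {"MYOC"}
        with pytest.raises(ValueError, match="duplicate"):
            InteractionTable([
                Interaction("d1", "x", "MYOC", "S"),
                Interaction("d1", "x", "myoc", "S"),
            ])

    def test_tsv_roundtrip(self, tmp_path, small_universe_table):
        path = tmp_path / "interactions.tsv"
        small_universe_table.to_tsv(path)
        again = InteractionTable.from_tsv(path)
        assert again.drug_targets() == small_universe_table.drug_targets()


class TestEnrichDrugs:
    def test_hypergeometric_example(self, small_universe_table, query_half):
        """Drug X: 3 of 3 targets in a 5-gene query over a 10-gene universe."""
        results = enrich_drugs(small_universe_table, query_half, method="fisher")
        by_id = {r.drug_id: r for r in results}
        x = by_id["X"]
        assert (x.k, x.K, x.n, x.N) == (3, 3, 5, 10)
        assert x.p_value == pytest.approx(1.0 / 12.0)

    def test_maximal_association_is_smallest_p(self):
        """A drug targeting exactly the query half of the universe wins."""
        edges = [Interaction("HIT", "hit", f"g{i}", "S") for i in range(5)]
        edges += [Interaction("BG", "bg", f"g{i}", "S") for i in range(3, 8)]
        edges += [Interaction("WIDE", "wide", f"g{i}", "S") for i in range(10)]
        table = InteractionTable(edges)
        query = GeneSet.from_symbols([f"g{i}" for i in range(5)])
        results = enrich_drugs(table, query, method="fisher")
        assert results[0].drug_id == "HIT"
        assert results[0].p_value == min(r.p_value for r in results)

    def test_zero_overlap_never_beats_positive_overlap(self, query_half):
        edges = [Interaction("IN", "a", f"g{i}", "S") for i in (1, 2, 3)]
        edges += [Interaction("OUT", "b", f"g{i}", "S") for i in (7, 8, 9)]
        edges += [Interaction("U", "u", f"g{i}", "S") for i in range(1, 11)]
        table = InteractionTable(edges)
        by_id = {r.drug_id: r for r in enrich_drugs(table, query_half, method="fisher")}
        assert by_id["OUT"].k == 0
        assert by_id["OUT"].p_value >= by_id["IN"].p_value

    def test_conservation_of_counts(self):
        table, query, _ = simulate_interactions(
            EnrichmentSimConfig(n_genes=300, n_drugs=30, targets_per_drug=8,
                                query_size=40, planted_drugs=3, seed=5))
        for r in enrich_drugs(table, query):
            assert r.k + (r.n - r.k) + (r.K - r.k) + (r.N - r.n - r.K + r.k) == r.N

    def test_adding_a_drug_leaves_other_p_unchanged(self, small_universe_table,
                                                    query_half):
        before = {r.drug_id: r.p_value
                  for r in enrich_drugs(small_universe_table, query_half)}
        edges = list(small_universe_table.edges)
        edges += [Interaction("NEW", "new", f"g{i}", "T") for i in (4, 9)]
        after = {r.drug_id: r.p_value
                 for r in enrich_drugs(InteractionTable(edges), query_half)}
        for drug, p in before.items():
            assert after[drug] == pytest.approx(p, rel=1e-12)

    def test_query_disjoint_from_universe(self, small_universe_table):
        far = GeneSet.from_symbols(["zzz1", "zzz2"])
        with pytest.raises(ValueError, match="disjoint"):
            enrich_drugs(small_universe_table, far)

    def test_results_tsv_roundtrip(self, tmp_path, small_universe_table, query_half):
        results = enrich_drugs(small_universe_table, query_half)
        path = tmp_path / "results.tsv"
        write_results(results, path)
        assert read_results(path) == results


class TestBridgeExpand:
    def test_union_of_target_genes(self):
        bmap = BridgeMap(
            disease_to_drugs={"dz": {"d1", "d2"}},
            drug_to_genes={"d1": {"GA", "GB"}, "d2": {"GB", "GC"}},
        )
        drugs, genes = bridge_expand(bmap, "dz")
        assert drugs == {"d1", "d2"}
        assert genes.symbols == ("GA", "GB", "GC")
        assert genes.record("GB").sources == {"d1", "d2"}

    def test_singleton_and_partial_map(self, caplog):
        bmap = BridgeMap(disease_to_drugs={"dz": {"d1", "d2"}},
                         drug_to_genes={"d1": {"GX"}})
        with caplog.at_level(logging.WARNING):
            drugs, genes = bridge_expand(bmap, "dz")
        assert genes.symbols == ("GX",)
        assert "d2" in caplog.text

    def test_unknown_disease_lists_known(self):
        bmap = BridgeMap(disease_to_drugs={"dz": {"d1"}}, drug_to_genes={"d1": {"G"}})
        with pytest.raises(KeyError, match="dz"):
            bridge_expand(bmap, "nope")


class TestConsensusRank:
    def test_source_count_dominates_p(self):
        lists = [
            ("S1", [_result("X", 1e-6, 1e-5), _result("Y", 1e-8, 1e-7)]),
            ("S2", [_result("X", 1e-4, 1e-3)]),
        ]
        entries = consensus_rank(lists, alpha=0.05, k=40)
        assert [e.drug_id for e in entries] == ["X", "Y"]
        assert entries[0].sources == ("S1", "S2")
        assert entries[0].best_p == pytest.approx(1e-6)

    def test_k_cap_and_alpha_filter(self):
        lists = [("S1", [_result("A", 1e-4, 1e-3), _result("B", 2e-4, 2e-3),
                         _result("C", 0.9, 0.9)])]
        assert len(consensus_rank(lists, alpha=0.05, k=10)) == 2
        assert [e.drug_id for e in consensus_rank(lists, alpha=0.05, k=1)] == ["A"]

    def test_lexicographic_tie_break(self):
        lists = [("S1", [_result("B", 1e-4, 1e-3), _result("A", 1e-4, 1e-3)])]
        assert [e.drug_id for e in consensus_rank(lists)] == ["A", "B"]
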