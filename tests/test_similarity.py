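"""Gene-pair similarity S = C·D·Sp against brute-force set arithmetic."""

import numpy as np
import pytest

from kgtool import (
    Entity,
    KnowledgeGraph,
    ScoringConfig,
    TableProvider,
    Triple,
    UnscorablePairError,
    coincident_set,
    gene_similarity,
    scoring_neighborhood,
    similarity_to_known,
)
from kgtool.errors import NotAGeneError, SelfPairError
from kgtool.kg import GeneTraitAssociation

from oracles import brute_coincident


def _mini_graph():
    """gene g with GO neighbors {bp1, mf1}; protein p with pathway {s1}."""
    kg = KnowledgeGraph()
    g = Entity("g", "gene")
    p = Entity("p", "protein")
    kg.add_triple(Triple(p, "corresponding_to", g))
    kg.add_triple(Triple(g, "involves_in_biological_process", Entity("bp1", "biological_process")))
    kg.add_triple(Triple(g, "performs", Entity("mf1", "molecular_function")))
    kg.add_triple(Triple(p, "involves_in_signal_pathway", Entity("s1", "signal_pathway")))
    return kg


class TestScoringNeighborhood:
    def test_default_includes_protein_hop(self):
        kg = _mini_graph()
        assert {e.id for e in scoring_neighborhood(kg, "g")} == {"p", "bp1", "mf1", "s1"}

    def test_strict_one_hop(self):
        kg = _mini_graph()
        config = ScoringConfig(include_protein_hop=False)
        assert {e.id for e in scoring_neighborhood(kg, "g", config)} == {"p", "bp1", "mf1"}

    def test_trait_excluded_by_default(self):
        kg = _mini_graph()
        kg.add_triple(
            Triple(Entity("p", "protein"), "associates_with", Entity("t", "trait"))
        )
        hood = {e.id for e in scoring_neighborhood(kg, "g")}
        assert "t" not in hood
        permissive = ScoringConfig(excluded_categories=frozenset())
        assert "t" in {e.id for e in scoring_neighborhood(kg, "g", permissive)}

    def test_rejects_non_gene(self):
        kg = _mini_graph()
        with pytest.raises(NotAGeneError):
            scoring_neighborhood(kg, "p")


class TestGeneSimilarity:
    def test_worked_example(self, worked_example):
        kg, provider, _ = worked_example
        r = gene_similarity(kg, "LOC_Os05g12260", "LOC_Os02g15640", provider)
        assert (r.C, r.D, r.Sp) == (12, 4, 79.191)
        assert round(r.S, 2) == 3801.17

    def test_annihilation_when_no_overlap(self):
        kg = _mini_graph()
        g2 = Entity("g2", "gene")
        p2 = Entity("p2", "protein")
        kg.add_triple(Triple(p2, "corresponding_to", g2))
        kg.add_triple(Triple(g2, "performs", Entity("mf_other", "molecular_function")))
        provider = TableProvider({("p", "p2"): 99.0})
        r = gene_similarity(kg, "g", "g2", provider)
        assert r.C == 0 and r.S == 0.0

    def test_hand_built_three_category_overlap(self):
        kg = KnowledgeGraph()
        shared = [
            ("mf1", "molecular_function", "performs"),
            ("bp2", "biological_process", "involves_in_biological_process"),
        ]
        for gene, prot in (("g1", "p1"), ("g2", "p2")):
            kg.add_triple(
                Triple(Entity(prot, "protein"), "corresponding_to", Entity(gene, "gene"))
            )
            for ann, cat, rel in shared:
                kg.add_triple(Triple(Entity(gene, "gene"), rel, Entity(ann, cat)))
            kg.add_triple(
                Triple(
                    Entity(prot, "protein"),
                    "involves_in_signal_pathway",
                    Entity("s1", "signal_pathway"),
                )
            )
        provider = TableProvider({("p1", "p2"): 50.0})
        r = gene_similarity(kg, "g1", "g2", provider)
        assert {e for e in r.coincident} == {"mf1", "bp2", "s1"}
        assert (r.C, r.D, r.S) == (3, 3, 450.0)

    def test_symmetry(self, worked_example):
        kg, provider, _ = worked_example
        a = gene_similarity(kg, "LOC_Os05g12260", "LOC_Os02g15640", provider)
        b = gene_similarity(kg, "LOC_Os02g15640", "LOC_Os05g12260", provider)
        assert (a.C, a.D, a.Sp, a.S) == (b.C, b.D, b.Sp, b.S)

    def test_self_pair_rejected(self, worked_example):
        kg, provider, _ = worked_example
        with pytest.raises(SelfPairError):
            gene_similarity(kg, "LOC_Os05g12260", "LOC_Os05g12260", provider)

    def test_unscorable_is_an_error_not_zero(self):
        kg = _mini_graph()
        g2 = Entity("g2", "gene")
        kg.add_triple(Triple(Entity("p2", "protein"), "corresponding_to", g2))
        with pytest.raises(UnscorablePairError):
            gene_similarity(kg, "g", "g2", TableProvider())

    def test_monotone_under_added_shared_neighbor(self):
        kg = _mini_graph()
        g2 = Entity("g2", "gene")
        p2 = Entity("p2", "protein")
        kg.add_triple(Triple(p2, "corresponding_to", g2))
        kg.add_triple(Triple(g2, "performs", Entity("mf1", "molecular_function")))
        provider = TableProvider({("p", "p2"): 10.0})
        before = gene_similarity(kg, "g", "g2", provider)
        kg.add_triple(
            Triple(g2, "involves_in_biological_process", Entity("bp1", "biological_process"))
        )
        after = gene_similarity(kg, "g", "g2", provider)
        assert after.C >= before.C and after.D >= before.D and after.S >= before.S


class TestBruteForceOracle:
    """C and D on random schema-legal graphs vs raw set arithmetic."""

    CATEGORIES = [
        ("molecular_function", "performs", "gene"),
        ("biological_process", "involves_in_biological_process", "gene"),
        ("cellular_component", "located_in_cellular_component", "gene"),
        ("metabolic_pathway", "involves_in_metabolic_pathway", "gene"),
        ("signal_pathway", "involves_in_signal_pathway", "protein"),
        ("protein_family", "belongs_to_protein_family", "protein"),
    ]

    def _random_graph(self, rng):
        triples = []
        genes = ["gA", "gB"]
        for gene in genes:
            prot = f"P{gene}"
            triples.append((prot, "protein", "corresponding_to", gene, "gene"))
            n_ann = int(rng.integers(0, 10))
            for _ in range(n_ann):
                cat, rel, anchor = self.CATEGORIES[int(rng.integers(len(self.CATEGORIES)))]
                ann = f"{cat}_{int(rng.integers(6))}"  # small pool forces overlap
                if anchor == "gene":
                    triples.append((gene, "gene", rel, ann, cat))
                else:
                    triples.append((prot, "protein", rel, ann, cat))
        if rng.random() < 0.5:
            triples.append(("PgA", "protein", "homologous_to", "PgB", "protein"))
        if rng.random() < 0.3:
            triples.append(("PgA", "protein", "associates_with", "t1", "trait"))
        return triples

    @pytest.mark.parametrize("include_protein_hop", [True, False])
    def test_fifty_random_graphs(self, include_protein_hop):
        rng = np.random.default_rng(42)
        config = ScoringConfig(include_protein_hop=include_protein_hop)
        for _ in range(50):
            triples = self._random_graph(rng)
            kg = KnowledgeGraph()
            for h, hc, r, t, tc in triples:
                kg.add_triple(Triple(Entity(h, hc), r, Entity(t, tc)))
            assert len(kg) <= 30
            expected_C, expected_D, expected_k = brute_coincident(
                triples, "gA", "gB", include_protein_hop=include_protein_hop
            )
            k = coincident_set(kg, "gA", "gB", config)
            assert {e.id for e in k} == expected_k
            provider = TableProvider({("PgA", "PgB"): 50.0})
            r = gene_similarity(kg, "gA", "gB", provider, config)
            assert (r.C, r.D) == (expected_C, expected_D)
            assert r.D <= min(r.C, 13)
            assert r.S == r.C * r.D * 50.0


class TestSimilarityToKnown:
    def test_worked_example_single_tagged_result(self, worked_example):
        kg, provider, associations = worked_example
        results = similarity_to_known(kg, "LOC_Os02g15640", associations, provider)
        assert len(results) == 1
        assert results[0].traits == ("drought_resistance",)
        assert round(results[0].S, 2) == 3801.17

    def test_empty_known_set(self, worked_example):
        kg, provider, _ = worked_example
        assert similarity_to_known(kg, "LOC_Os02g15640", [], provider) == []

    def test_self_among_known_is_skipped(self, worked_example):
        kg, provider, associations = worked_example
        extra = associations + [
            GeneTraitAssociation("LOC_Os02g15640", "drought_resistance", 2020, "x")
        ]
        results = similarity_to_known(kg, "LOC_Os02g15640", extra, provider)
        assert len(results) == 1  # the query itself contributes nothing
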