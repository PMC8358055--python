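"""Pathway semantics: filtering, Wang similarity, BMA, PageRank."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coevopath.semantics import (
    PPITable,
    PathwayCatalog,
    bma_similarity,
    build_semantic_graph,
    filter_partners,
    filter_pathways,
    load_go_graph,
    pagerank,
    s_values,
    semantic_value,
    term_similarity,
)
from oracles import pagerank_oracle


def _ppi(scores: dict, query="SNCA") -> PPITable:
    return PPITable(
        query=query,
        table=pd.DataFrame(
            {"partner": list(scores), "score": list(scores.values())}
        ),
    )


class TestFilterPartners:
    def test_all_below_cutoff_leaves_only_query(self):
        kept = filter_partners(_ppi({"A": 0.2, "B": 0.4}))
        assert kept.partners == ["SNCA"]

    def test_truncation_to_top_n_including_query(self):
        scores = {f"P{i:02d}": 0.99 - i * 0.01 for i in range(15)}
        kept = filter_partners(_ppi(scores), cutoff=0.5, top_n=11)
        assert len(kept.table) == 11
        assert "SNCA" in kept.partners
        assert kept.partners[1:] == [f"P{i:02d}" for i in range(10)]

    def test_tie_at_cut_kept(self):
        scores = {"A": 0.9, "B": 0.8, "C": 0.8, "D": 0.8}
        kept = filter_partners(_ppi(scores), cutoff=0.5, top_n=3)
        # budget is 2 partners but B/C/D tie with A..: cut falls inside the tie
        assert set(kept.partners) == {"SNCA", "A", "B", "C", "D"}

    def test_idempotent(self):
        scores = {f"P{i}": 0.6 + 0.02 * i for i in range(8)}
        once = filter_partners(_ppi(scores))
        twice = filter_partners(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            filter_partners(_ppi({"A": 0.7}), cutoff=1.2)


class TestFilterPathways:
    CAT = PathwayCatalog(
        members={
            "with_query": frozenset({"SNCA", "LRRK2"}),
            "no_query": frozenset({"LRRK2", "PARK2"}),
            "query_alone": frozenset({"SNCA"}),
        }
    )

    def test_rules(self):
        kept = filter_pathways(self.CAT, "SNCA", min_members=2)
        assert set(kept.members) == {"with_query"}

    def test_idempotent(self):
        once = filter_pathways(self.CAT, "SNCA")
        assert filter_pathways(once, "SNCA").members == once.members


class TestWangSimilarity:
    def test_self_s_value_is_one(self, chain_ontology):
        assert s_values(chain_ontology, "T").s["T"] == 1.0

    def test_single_is_a_edge(self, chain_ontology):
        sv = s_values(chain_ontology, "T")
        assert sv.s["P"] == pytest.approx(0.8)
        assert sv.s["R"] == pytest.approx(0.64)

    def test_max_rule_over_two_routes(self):
        g = nx.DiGraph()
        g.add_edge("T", "P", relation="is_a", c_e=0.8)
        g.add_edge("P", "G", relation="is_a", c_e=0.8)
        g.add_edge("T", "G", relation="part_of", c_e=0.6)
        sv = s_values(g, "T")
        assert sv.s["G"] == pytest.approx(0.64)  # 0.8*0.8 beats 0.6

    def test_semantic_value_chain(self, chain_ontology):
        assert semantic_value(s_values(chain_ontology, "T")) == pytest.approx(2.44)
        g1 = nx.DiGraph()
        g1.add_edge("T", "P", relation="is_a", c_e=0.8)
        assert semantic_value(s_values(g1, "T")) == pytest.approx(1.8)

    def test_isolated_root_sv_is_one(self):
        g = nx.DiGraph()
        g.add_node("R")
        assert semantic_value(s_values(g, "R")) == 1.0

    def test_sibling_similarity_closed_form(self):
        g = nx.DiGraph()
        g.add_edge("T", "R", relation="is_a", c_e=0.8)
        g.add_edge("Q", "R", relation="is_a", c_e=0.8)
        assert term_similarity(g, "T", "Q") == pytest.approx((0.8 + 0.8) / 3.6)

    def test_self_similarity_is_one(self, chain_ontology):
        assert term_similarity(chain_ontology, "T", "T") == pytest.approx(1.0)

    def test_unrelated_roots_give_zero(self):
        g = nx.DiGraph()
        g.add_edge("T", "R1", relation="is_a", c_e=0.8)
        g.add_edge("Q", "R2", relation="is_a", c_e=0.8)
        assert term_similarity(g, "T", "Q") == 0.0

    def test_symmetry_and_range_on_random_dags(self, rng):
        for trial in range(10):
            g = nx.DiGraph()
            n = 12
            for child in range(1, n):
                for parent in rng.choice(child, size=min(child, 2), replace=False):
                    rel = "part_of" if rng.random() < 0.3 else "is_a"
                    g.add_edge(
                        f"t{child}", f"t{parent}",
                        relation=rel, c_e=0.6 if rel == "part_of" else 0.8,
                    )
            terms = [f"t{i}" for i in range(n) if f"t{i}" in g]
            a, b = rng.choice(terms, size=2, replace=False)
            sab = term_similarity(g, a, b)
            assert sab == pytest.approx(term_similarity(g, b, a), abs=1e-12)
            assert 0.0 <= sab <= 1.0
            assert term_similarity(g, a, a) == pytest.approx(1.0)


class TestBMA:
    def test_identical_singletons(self, chain_ontology):
        assert bma_similarity({"T"}, {"T"}, chain_ontology) == pytest.approx(1.0)

    def test_hand_evaluated_mixed_sets(self):
        # SS_w(T, Q) for siblings under one root = 4/9
        g = nx.DiGraph()
        g.add_edge("T", "R", relation="is_a", c_e=0.8)
        g.add_edge("Q", "R", relation="is_a", c_e=0.8)
        s = bma_similarity({"T"}, {"T", "Q"}, g)
        ss = (0.8 + 0.8) / 3.6
        # forward best match 1 (T->T); backward 1 (T) and ss (Q); i + j = 3
        assert s == pytest.approx((1.0 + 1.0 + ss) / 3)

    def test_unrelated_sets_give_zero(self):
        g = nx.DiGraph()
        g.add_edge("T", "R1", relation="is_a", c_e=0.8)
        g.add_edge("Q", "R2", relation="is_a", c_e=0.8)
        assert bma_similarity({"T"}, {"Q"}, g) == 0.0

    def test_symmetric(self, go_world):
        go, ann, *_ = go_world
        terms = sorted(go.nodes)
        s1, s2 = set(terms[2:5]), set(terms[6:8])
        assert bma_similarity(s1, s2, go) == pytest.approx(
            bma_similarity(s2, s1, go), abs=1e-12
        )

    def test_empty_set_rejected(self, chain_ontology):
        with pytest.raises(ValueError):
            bma_similarity(set(), {"T"}, chain_ontology)


class TestSemanticGraph:
    def test_identical_term_sets_give_strong_unit_edge(self, chain_ontology):
        cat = PathwayCatalog(
            members={"pw1": frozenset({"p1"}), "pw2": frozenset({"p2"})}
        )
        ann = pd.DataFrame(
            [
                {"protein": "p1", "term": "T", "ontology": "BP"},
                {"protein": "p2", "term": "T", "ontology": "BP"},
            ]
        )
        g = build_semantic_graph(cat, ann, chain_ontology, "BP")
        assert g.number_of_edges() == 1
        (u, v, d), = g.edges(data=True)
        assert d["weight"] == pytest.approx(1.0)
        assert d["strong"]

    def test_unannotated_pathway_is_isolated(self, chain_ontology):
        cat = PathwayCatalog(
            members={"pw1": frozenset({"p1"}), "pw2": frozenset({"lonely"})}
        )
        ann = pd.DataFrame([{"protein": "p1", "term": "T", "ontology": "BP"}])
        g = build_semantic_graph(cat, ann, chain_ontology, "BP")
        assert g.degree("pw2") == 0

    def test_weights_match_pairwise_bma(self, go_world):
        go, ann, cat, _, _ = go_world
        kept = filter_pathways(cat, "SNCA")
        g = build_semantic_graph(kept, ann, go, "BP")
        by_protein = {
            p: set(t["term"] for _, t in grp.iterrows())
            for p, grp in ann[ann["ontology"] == "BP"].groupby("protein")
        }
        for u, v, d in g.edges(data=True):
            tu = set().union(*(by_protein.get(m, set()) for m in kept.members[u]))
            tv = set().union(*(by_protein.get(m, set()) for m in kept.members[v]))
            assert d["weight"] == pytest.approx(bma_similarity(tu, tv, go), abs=1e-12)

    def test_fewer_than_two_pathways_rejected(self, chain_ontology):
        cat = PathwayCatalog(members={"pw1": frozenset({"p1"})})
        with pytest.raises(ValueError):
            build_semantic_graph(cat, pd.DataFrame(columns=["protein", "term", "ontology"]),
                                 chain_ontology, "BP")


class TestPageRank:
    def test_symmetric_ring_uniform(self):
        pr = pagerank(nx.cycle_graph(4))
        assert np.allclose(pr.values, 0.25)

    def test_path_graph_stationary(self):
        pr = pagerank(nx.path_graph(3))
        assert pr.to_dict() == pytest.approx({0: 0.25, 1: 0.5, 2: 0.25})

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("only")
        assert pagerank(g)["only"] == pytest.approx(1.0)

    def test_sums_to_one_with_isolated_nodes(self):
        g = nx.Graph([(0, 1), (1, 2)])
        g.add_node(99)
        pr = pagerank(g)
        assert pr.sum() == pytest.approx(1.0)
        assert pr[99] == pytest.approx(0.0, abs=1e-9)

    def test_matches_eigenvector_oracle_on_weighted_graphs(self, rng):
        for trial in range(8):
            g = nx.gnp_random_graph(6, 0.5, seed=100 + trial)
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
            pr = pagerank(g)
            oracle = pagerank_oracle(g)
            for node in g:
                assert pr[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_damped_variant_agrees_with_networkx(self):
        g = nx.karate_club_graph()
        pr = pagerank(g, damping=0.85)
        ref = nx.pagerank(g, alpha=0.85, tol=1e-12)
        for node in g:
            assert pr[node] == pytest.approx(ref[node], abs=1e-6)


class TestOntologyIO:
    def test_edge_tsv_roundtrip(self, tmp_path, chain_ontology):
        path = tmp_path / "go.tsv"
        rows = [
            {"child": u, "parent": v, "relation": d["relation"], "c_e": d["c_e"]}
            for u, v, d in chain_ontology.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        g = load_go_graph(path)
        assert set(g.edges) == set(chain_ontology.edges)
        assert semantic_value(s_values(g, "T")) == pytest.approx(2.44)

    def test_default_contribution_factors(self, tmp_path):
        path = tmp_path / "go.tsv"
        pd.DataFrame(
            [
                {"child": "a", "parent": "r", "relation": "is_a"},
                {"child": "b", "parent": "r", "relation": "part_of"},
            ]
        ).to_csv(path, sep="\t", index=False)
        g = load_go_graph(path)
        assert g["a"]["r"]["c_e"] == 0.8
        assert g["b"]["r"]["c_e"] == 0.6

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "cyc.tsv"
        pd.DataFrame(
            [
                {"child": "a", "parent": "b", "relation": "is_a"},
                {"child": "b", "parent": "a", "relation": "is_a"},
            ]
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="cycle"):
            load_go_graph(path)
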