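"""Knowledge-graph construction and attention-based pocket refinement."""

import numpy as np
import pandas as pd
import pytest

from pocketrank.data_model import ingest_assays, label_activity
from pocketrank.hgnn import (
    AttentionParams,
    DomainError,
    N_RELATION_BINS,
    add_query_pocket,
    attention_aggregate,
    attention_weights,
    build_graph,
    init_attention_params,
    load_graph,
    pocket_alignment_score,
    refine_pocket,
    save_graph,
    two_hop_ligand_neighbors,
)


class TestAlignment:
    def test_identical_triple_alanine_scores_fifteen(self):
        assert pocket_alignment_score("AAA", "AAA") == 15.0

    def test_symmetry_on_random_pairs(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aa), size=10))
            b = "".join(rng.choice(list(aa), size=10))
            assert pocket_alignment_score(a, b) == pocket_alignment_score(b, a)

    def test_self_alignment_dominates_equal_length(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aa), size=12))
        for _ in range(10):
            b = "".join(rng.choice(list(aa), size=12))
            assert pocket_alignment_score(a, a) >= pocket_alignment_score(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DomainError):
            pocket_alignment_score("", "AAA")

    def test_unknown_letters_mapped_to_x(self):
        # 'J' is not an amino-acid code; must score like X, not crash
        s = pocket_alignment_score("AJA", "AXA")
        assert s == pocket_alignment_score("AXA", "AXA")


def _toy_collection():
    df = pd.DataFrame(
        {
            "assay_id": ["a1"] * 4 + ["a2"] * 4,
            "target_group_id": ["T1"] * 4 + ["T2"] * 4,
            "ligand_id": [f"l{i}" for i in range(8)],
            "value": [1.0, 2.0, 50.0, 60.0, 3.0, 40.0, 70.0, 80.0],
            "unit": ["uM"] * 8,
        }
    )
    coll = ingest_assays(df)
    coll.pockets["pocket:a1"]["sequence"] = "AAAA"
    coll.pockets["pocket:a2"]["sequence"] = "AACA"
    return coll


class TestBuildGraph:
    def test_edge_rule_arithmetic(self):
        coll = _toy_collection()
        labels = label_activity(coll)
        scores = {("A", "A"): 15.0, ("A", "B"): 8.0, ("B", "B"): 15.0,
                  ("B", "A"): 8.0}
        seq_name = {"AAAA": "A", "AACA": "B"}

        def fake_score(s1, s2):
            return scores[(seq_name[s1], seq_name[s2])]

        g = build_graph(coll, labels, score_fn=fake_score)
        pp = [(u, v) for u, v, d in g.edges(data=True) if d["kind"] == "pp"]
        # 8 > 0.5*15 both ways
        assert ("pocket:a1", "pocket:a2") in pp and ("pocket:a2", "pocket:a1") in pp

        scores[("A", "B")] = scores[("B", "A")] = 7.0  # 7 < 7.5: no edges
        g2 = build_graph(coll, labels, score_fn=fake_score)
        assert not [e for e in g2.edges(data=True) if e[2]["kind"] == "pp"]

    def test_ligand_edges_count_equals_actives(self):
        coll = _toy_collection()
        labels = label_activity(coll)
        g = build_graph(coll, labels)
        lp = [e for e in g.edges(data=True) if e[2]["kind"] == "lp"]
        # values <= 10 uM: l0, l1, l4 are active
        assert len(lp) == 3

    def test_serialization_roundtrip(self, tmp_path):
        coll = _toy_collection()
        g = build_graph(coll, label_activity(coll))
        save_graph(g, tmp_path / "graph")
        g2 = load_graph(tmp_path / "graph")
        assert set(g.edges) == set(g2.edges)
        for u, v, d in g.edges(data=True):
            if d["kind"] == "pp":
                assert g2.edges[u, v]["score"] == d["score"]


class TestTwoHop:
    def _chain_graph(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("p1", kind="pocket")
        g.add_node("p2", kind="pocket")
        g.add_node("l1", kind="ligand")
        g.add_edge("l1", "p1", kind="lp")
        g.add_edge("p1", "p2", kind="pp", score=10.0, norm_score=0.8)
        return g

    def test_chain_reaches_ligand(self):
        assert two_hop_ligand_neighbors(self._chain_graph(), "p2") == {"l1": 0.8}

    def test_no_incoming_pocket_edges_gives_empty_set(self):
        assert two_hop_ligand_neighbors(self._chain_graph(), "p1") == {}

    def test_multi_path_deduplicated_keeping_best_relation(self):
        g = self._chain_graph()
        g.add_node("p3", kind="pocket")
        g.add_edge("l1", "p3", kind="lp")
        g.add_edge("p3", "p2", kind="pp", score=12.0, norm_score=0.95)
        assert two_hop_ligand_neighbors(g, "p2") == {"l1": 0.95}


class TestAttention:
    def test_single_neighbor_returns_its_value(self, rng):
        params = init_attention_params(d=4, seed=0)
        q = rng.normal(size=4)
        v = rng.normal(size=4)
        out = attention_aggregate(q, [(v, None)], params, head="pp")
        assert np.allclose(out, v)

    def test_identical_neighbors_get_half_weight_each(self, rng):
        params = init_attention_params(d=4, seed=0)
        q, v = rng.normal(size=4), rng.normal(size=4)
        w = attention_weights(q, np.stack([v, v]), params, head="pp")
        assert np.allclose(w, [0.5, 0.5])

    @pytest.mark.parametrize("n", [1, 2, 5, 9])
    def test_weights_nonnegative_sum_to_one(self, n, rng):
        params = init_attention_params(d=4, seed=1)
        w = attention_weights(
            rng.normal(size=4), rng.normal(size=(n, 4)), params, head="pp"
        )
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_output_in_convex_hull_of_values(self, rng):
        params = init_attention_params(d=3, seed=2)
        q = rng.normal(size=3)
        vals = rng.normal(size=(3, 3))
        out = attention_aggregate(q, [(v, None) for v in vals], params, head="pp")
        w = attention_weights(q, vals, params, head="pp")
        assert np.allclose(out, w @ vals)

    def test_empty_neighbors_fall_back_to_query(self, rng):
        params = init_attention_params(d=4, seed=0)
        q = rng.normal(size=4)
        assert np.array_equal(attention_aggregate(q, [], params), q)


class TestRefine:
    def _exact_params(self, d):
        params = init_attention_params(d=d, seed=0)
        # exact pass-through Phi and zeroed relation table
        W0 = np.zeros((2 * d, 2 * d))
        W0[:d, :d] = np.eye(d)
        W0[:d, d:] = -np.eye(d)
        params.params["phi.W0"].value = W0
        params.params["phi.W1"].value = np.vstack([np.eye(d), -np.eye(d)])
        params.params["relation.table"].value = np.zeros((N_RELATION_BINS, d))
        return params

    def _graph_one_neighbor(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("q", kind="pocket")
        g.add_node("nbr", kind="pocket")
        g.add_node("lig", kind="ligand")
        g.add_edge("nbr", "q", kind="pp", score=10.0, norm_score=0.9)
        g.add_edge("lig", "nbr", kind="lp")
        return g

    def test_gamma_zero_is_identity(self, rng):
        params = self._exact_params(3)
        params.params["gamma.logits"].value = np.array([-60.0, -60.0, 60.0])
        g = self._graph_one_neighbor()
        p = rng.normal(size=3)
        out = refine_pocket(
            "q", p, g, {"nbr": rng.normal(size=3)}, {"lig": rng.normal(size=3)}, params
        )
        assert np.allclose(out, p)

    def test_gamma_one_returns_ligand_aggregate(self, rng):
        params = self._exact_params(3)
        params.params["gamma.logits"].value = np.array([60.0, -60.0, -60.0])
        g = self._graph_one_neighbor()
        lig = rng.normal(size=3)
        out = refine_pocket(
            "q", rng.normal(size=3), g, {"nbr": rng.normal(size=3)}, {"lig": lig}, params
        )
        assert np.allclose(out, lig, atol=1e-10)

    def test_quarter_quarter_half_combination(self, rng):
        params = self._exact_params(3)
        params.params["gamma.logits"].value = np.log(np.array([0.25, 0.25, 0.5]))
        g = self._graph_one_neighbor()
        p, nbr, lig = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        out = refine_pocket("q", p, g, {"nbr": nbr}, {"lig": lig}, params)
        assert np.allclose(out, 0.25 * lig + 0.25 * nbr + 0.5 * p, atol=1e-10)

    def test_empty_graph_identity_for_any_gamma(self, rng):
        import networkx as nx

        params = init_attention_params(d=4, seed=3)
        params.params["gamma.logits"].value = rng.normal(size=3)
        p = rng.normal(size=4)
        assert np.array_equal(refine_pocket("q", p, None, {}, {}, params), p)
        assert np.array_equal(refine_pocket("q", p, nx.DiGraph(), {}, {}, params), p)

    def test_isolated_pocket_refinement_is_identity(self, rng):
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("q", kind="pocket")
        params = init_attention_params(d=4, seed=3)
        params.params["gamma.logits"].value = rng.normal(size=3)
        p = rng.normal(size=4)
        assert np.allclose(refine_pocket("q", p, g, {}, {}, params), p)


class TestQueryInsertion:
    def test_query_gets_incoming_edges_from_similar_pockets(self):
        coll = _toy_collection()
        g = build_graph(coll, label_activity(coll))
        n = add_query_pocket(g, "query", "AAAA")
        assert n >= 1
        assert any(
            d.get("kind") == "pp" for _, _, d in g.in_edges("query", data=True)
        )
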