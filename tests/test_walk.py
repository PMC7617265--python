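import networkx as nx
import numpy as np
import pandas as pd
import pytest

import transwalker as tw
from transwalker.walk import (
    filter_expressed,
    sample_matched_cpg_sets,
    transition_matrix,
)
from conftest import closed_form_aggregated, random_connected_graph


def k3():
    g = nx.Graph()
    g.add_edges_from([("v1", "v2"), ("v1", "v3"), ("v2", "v3")])
    return g


def binding_for(cpg_to_proteins: dict[str, list[str]], proteins: list[str]):
    cpgs = sorted(cpg_to_proteins)
    mat = pd.DataFrame(False, index=cpgs, columns=proteins)
    for c, ps in cpg_to_proteins.items():
        mat.loc[c, ps] = True
    return mat


class TestTransitionMatrix:
    def test_path_graph_entries(self):
        g = nx.path_graph(["A", "B", "C"])
        t, d = transition_matrix(g, ["A", "B", "C"])
        t = t.toarray()
        assert t[0, 1] == pytest.approx(1 / np.sqrt(2))
        assert t[0, 2] == 0.0
        assert list(d) == [1, 2, 1]

    def test_triangle_spectrum(self):
        spec = tw.transition_spectrum(k3(), n_eig=3)
        assert np.allclose(sorted(spec.eigvals), [-0.5, -0.5, 1.0], atol=1e-12)
        t, _ = transition_matrix(k3(), spec.nodes)
        assert np.allclose(t.toarray()[0, 1], 0.5)

    def test_stationary_eigenvector_proportional_to_sqrt_degree(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(20, 200)))
            spec = tw.transition_spectrum(g, n_eig=5)
            d = spec.degrees
            ref = np.sqrt(d) / np.linalg.norm(np.sqrt(d))
            assert np.max(np.abs(spec.eigvecs[:, 0] - ref)) < 1e-6

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="disconnected"):
            tw.transition_spectrum(g, n_eig=2)


class TestAggregatedMatrix:
    def test_k3_worked_value(self):
        spec = tw.transition_spectrum(k3(), n_eig=3)
        m = tw.aggregated_matrix(spec, ["v1"], ["v2", "v3"])
        assert m.loc["v1", "v2"] == pytest.approx(1 / 9, abs=1e-12)
        assert m.loc["v1", "v3"] == pytest.approx(1 / 9, abs=1e-12)
        diag = tw.aggregated_matrix(spec, ["v1"], ["v1"])
        assert diag.loc["v1", "v1"] == pytest.approx(-2 / 9, abs=1e-12)

    def test_full_spectrum_equals_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(10, 120)))
            nodes, m_ref = closed_form_aggregated(g)
            spec = tw.transition_spectrum(g, n_eig=len(nodes))
            m = tw.aggregated_matrix(spec, nodes, nodes)
            assert np.max(np.abs(m.to_numpy() - m_ref)) < 1e-8

    def test_truncated_spectrum_error_bounded(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(rng, 80, p=0.15)
        nodes, m_ref = closed_form_aggregated(g)
        spec_full = tw.transition_spectrum(g, n_eig=80)
        spec_small = tw.transition_spectrum(g, n_eig=40)
        m_small = tw.aggregated_matrix(spec_small, nodes, nodes)
        lam = spec_full.eigvals
        tail_bound = np.sum(np.abs(lam[40:] / (1 - lam[40:])))
        err = np.max(np.abs(m_small.to_numpy() - m_ref))
        assert err <= tail_bound + 1e-10

    def test_eigenvector_sign_invariance(self):
        g = random_connected_graph(np.random.default_rng(3), 30)
        spec = tw.transition_spectrum(g, n_eig=30)
        m1 = tw.aggregated_matrix(spec, spec.nodes[:5], spec.nodes[5:10])
        spec.eigvecs[:, 1:] *= -1
        m2 = tw.aggregated_matrix(spec, spec.nodes[:5], spec.nodes[5:10])
        assert np.allclose(m1, m2, atol=1e-12)

    def test_power_sum_oracle_with_spectral_gap(self):
        rng = np.random.default_rng(4)
        tried = 0
        for _ in range(10):
            g = random_connected_graph(rng, 40, p=0.3)
            nodes = sorted(g.nodes)
            t, d = transition_matrix(g, nodes)
            t = t.toarray()
            psi0 = np.sqrt(d) / np.linalg.norm(np.sqrt(d))
            spec = tw.transition_spectrum(g, n_eig=len(nodes))
            if np.max(np.abs(spec.eigvals[1:])) > 0.9:
                continue
            tried += 1
            base = t - np.outer(psi0, psi0)
            acc = np.zeros_like(t)
            term = np.eye(len(nodes))
            for _t in range(1, 201):
                term = term @ base
                acc += term
            m = tw.aggregated_matrix(spec, nodes, nodes)
            assert np.max(np.abs(acc - m.to_numpy())) < 1e-6
        assert tried >= 3


class TestScores:
    def test_k3_scores_one_ninth(self):
        spec = tw.transition_spectrum(k3(), n_eig=3)
        m = tw.aggregated_matrix(spec, ["v1"], ["v2", "v3"])
        s = tw.score_candidates(m)
        assert s["v2"] == pytest.approx(1 / 9, abs=1e-12)
        assert s["v3"] == pytest.approx(1 / 9, abs=1e-12)

    def test_automorphic_candidates_equal_scores(self):
        # star of 4 leaves: leaves are interchangeable
        g = nx.star_graph(["hub", "l1", "l2", "l3", "l4"])
        spec = tw.transition_spectrum(g, n_eig=5)
        m = tw.aggregated_matrix(spec, ["l1"], ["l2", "l3", "l4"])
        s = tw.score_candidates(m)
        assert s["l2"] == pytest.approx(s["l3"], abs=1e-10)
        assert s["l3"] == pytest.approx(s["l4"], abs=1e-10)

    def test_adjacent_candidate_outranks_pendant(self):
        # CpG bound by p1; candidate c_near adjacent to p1, c_far pendant
        # hanging three hops away
        g = nx.Graph()
        g.add_edges_from([("cg", "p1"), ("p1", "c_near"), ("p1", "p2"),
                          ("p2", "p3"), ("p3", "p4"), ("p4", "c_far"),
                          ("p2", "c_near")])
        spec = tw.transition_spectrum(g, n_eig=len(g))
        m = tw.aggregated_matrix(spec, ["cg"], ["c_near", "c_far"])
        s = tw.score_candidates(m)
        assert s["c_near"] > s["c_far"]


class TestLocusGraph:
    def _toy(self):
        ppi = nx.Graph()
        ppi.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                            ("E", "F"), ("A", "C")])
        binding = binding_for({"cg1": ["A"], "cg2": ["C"], "cg3": ["F"]},
                              ["A", "C", "F"])
        return ppi, binding

    def test_construction_counts(self):
        ppi, binding = self._toy()
        g, cands, dropped = tw.build_locus_graph(
            ppi, binding, ["cg1", "cg2", "cg3"], ["A", "D"])
        assert g.number_of_nodes() == 9
        assert cands == ["A", "D"]
        assert not dropped
        assert set(g.neighbors("cg1")) == {"A"}

    def test_expression_filter_removes_silent_protein(self):
        ppi, binding = self._toy()
        med = pd.Series({"A": 5.0, "B": 5.0, "C": 5.0, "D": 5.0, "E": 5.0,
                         "F": 0.05})
        g, _, dropped = tw.build_locus_graph(
            ppi, binding, ["cg1", "cg3"], ["A"], expression_medians=med)
        assert "F" not in g
        assert dropped == ["cg3"]

    def test_largest_component_kept(self):
        ppi = nx.Graph()
        ppi.add_edges_from([("A", "B"), ("B", "C"), ("X", "Y")])
        binding = binding_for({"cg1": ["A"]}, ["A"])
        g, _, _ = tw.build_locus_graph(ppi, binding, ["cg1"], ["A"])
        assert "X" not in g and "Y" not in g

    def test_no_candidate_in_network_raises(self):
        ppi, binding = self._toy()
        with pytest.raises(ValueError, match="no candidate"):
            tw.build_locus_graph(ppi, binding, ["cg1"], ["ZZZ"])

    def test_all_cpgs_unbound_raises(self):
        ppi, binding = self._toy()
        with pytest.raises(ValueError, match="lacks a binding protein"):
            tw.build_locus_graph(ppi, binding, ["cg_unknown"], ["A"])


class TestBackgrounds:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"cg{i:03d}" for i in range(80)]
        stats = pd.DataFrame({"mean": rng.uniform(0.2, 0.8, 80),
                              "sd": rng.uniform(0.02, 0.08, 80)}, index=names)
        return names, stats, rng

    def test_matched_sets_have_equal_size(self):
        names, stats, rng = self._setup()
        S = names[:7]
        sets = sample_matched_cpg_sets(S, stats, 20, rng)
        assert all(len(s) == len(S) for s in sets)
        assert all(not set(s) & set(S) for s in sets)

    def test_matched_sets_track_mean_within_bin_width(self):
        names, stats, rng = self._setup(seed=2)
        S = names[:10]
        sets = sample_matched_cpg_sets(S, stats, 50, rng)
        target = stats.loc[S, "mean"].mean()
        for s in sets:
            assert abs(stats.loc[s, "mean"].mean() - target) <= 0.05

    def test_background_scores_deterministic_under_seed(self):
        ppi = nx.erdos_renyi_graph(40, 0.15, seed=5)
        ppi = nx.relabel_nodes(ppi, {i: f"P{i:02d}" for i in range(40)})
        ppi = ppi.subgraph(max(nx.connected_components(ppi), key=len)).copy()
        proteins = sorted(ppi.nodes)
        rng = np.random.default_rng(7)
        names = [f"cg{i:03d}" for i in range(60)]
        binding = pd.DataFrame(rng.random((60, len(proteins))) < 0.1,
                               index=names, columns=proteins)
        stats = pd.DataFrame({"mean": rng.uniform(0.2, 0.8, 60),
                              "sd": rng.uniform(0.02, 0.08, 60)}, index=names)
        S = [c for c in names if binding.loc[c].any()][:6]
        args = (ppi, binding, S, proteins[:4], stats)
        a = tw.randomized_background(*args, B=10, n_eig=50, rng=123)
        b = tw.randomized_background(*args, B=10, n_eig=50, rng=123)
        pd.testing.assert_frame_equal(a, b)


class TestEmpiricalPvalues:
    def test_dominant_score_gets_minimum_p(self):
        scores = pd.Series({"tf": 10.0, "decoy": 0.1})
        bg = pd.DataFrame({"tf": np.zeros(100), "decoy": np.ones(100) * 0.5})
        out = tw.empirical_candidate_pvalues(scores, bg)
        assert out.loc["tf", "empirical_p"] == pytest.approx(1 / 101)
        assert out.loc["tf", "selected"]
        assert out.loc["decoy", "empirical_p"] == 1.0

    def test_p_monotone_in_score(self):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.random((50, 3)), columns=list("abc"))
        scores = pd.Series({"a": 0.2, "b": 0.5, "c": 0.9})
        out = tw.empirical_candidate_pvalues(scores, bg)
        assert out.loc["a", "empirical_p"] >= out.loc["b", "empirical_p"] \
            >= out.loc["c", "empirical_p"]
        assert ((out["empirical_p"] >= 1 / 51)
                & (out["empirical_p"] <= 1.0)).all()


class TestPlantedRecovery:
    def test_planted_tf_ranked_first(self, scenario):
        truth = scenario["truth"]
        binding = tw.overlap_cpg_tfbs(scenario["cpg_anno"], scenario["tracks"])
        g = tw.run_locus_walk.__globals__["ppi_graph"](scenario["ppi"])
        meth = scenario["methylation"]
        stats = pd.DataFrame({"mean": meth.mean(), "sd": meth.std()})
        res = tw.run_locus_walk(g, binding, sorted(truth.bound_cpgs),
                                truth.locus_genes, stats, B=100, rng=42)
        ranked = res["scores"].sort_values(ascending=False)
        assert ranked.index[0] == truth.planted_tf
        assert truth.planted_tf in res["selected"]
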