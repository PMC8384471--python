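"""Semantic models, GIP kernel, and similarity integration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirwalker as mw
from mirwalker.datatypes import DiseaseDAG


def _chain_dag(*terms):
    """DAG whose root is terms[0] with a single upward chain."""
    edges = frozenset(zip(terms, terms[1:]))
    return DiseaseDAG(root=terms[0], terms=frozenset(terms), edges=edges)


def brute_force_contribution(dag, delta):
    """Oracle: max over all downward paths of delta**path_length,
    found by exhaustive path enumeration from the root."""
    out = {dag.root: 1.0}

    def walk(term, value):
        for child, parent in dag.edges:
            if child == term:
                out[parent] = max(out.get(parent, 0.0), value * delta)
                walk(parent, value * delta)

    walk(dag.root, 1.0)
    return out


class TestSemanticModel1:
    def test_single_node(self):
        dag = DiseaseDAG("D", frozenset({"D"}), frozenset())
        assert mw.semantic_contributions_model1(dag, 0.5) == {"D": 1.0}

    def test_chain_decays_per_level(self):
        dag = _chain_dag("D", "p", "r")
        assert mw.semantic_contributions_model1(dag, 0.5) == {
            "D": 1.0,
            "p": 0.5,
            "r": 0.25,
        }

    def test_diamond_takes_path_max_not_sum(self):
        dag = DiseaseDAG(
            "D",
            frozenset({"D", "x", "y", "r"}),
            frozenset({("D", "x"), ("D", "y"), ("x", "r"), ("y", "r")}),
        )
        contrib = mw.semantic_contributions_model1(dag, 0.5)
        assert contrib["r"] == pytest.approx(0.25)
        assert contrib == brute_force_contribution(dag, 0.5)

    @given(seed=st.integers(0, 200), delta=st.floats(0.1, 0.9))
    def test_contributions_match_path_max_oracle(self, seed, delta):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        terms = [f"t{i}" for i in range(n)]
        # random DAG with edges only from lower to higher index, every
        # non-root term reachable from t0
        edges = set()
        for i in range(1, n):
            parents_of = rng.integers(0, i, size=rng.integers(1, i + 1))
            for p in set(parents_of.tolist()):
                edges.add((terms[p], terms[i]))
        dag = DiseaseDAG(terms[0], frozenset(terms), frozenset(edges))
        got = mw.semantic_contributions_model1(dag, delta)
        expected = brute_force_contribution(dag, delta)
        assert got.keys() == expected.keys()
        for t in got:
            assert got[t] == pytest.approx(expected[t], abs=1e-12)

    def test_unreachable_term_rejected(self):
        dag = DiseaseDAG(
            "D", frozenset({"D", "island"}), frozenset()
        )
        with pytest.raises(ValueError, match="unreachable"):
            mw.semantic_contributions_model1(dag, 0.5)

    def test_similarity_identical_dags_is_one(self):
        dag = _chain_dag("D", "p", "r")
        assert mw.semantic_similarity_model1(dag, dag, 0.5) == pytest.approx(
            1.0
        )

    def test_similarity_shared_root_chain_case(self):
        d1 = _chain_dag("d1", "r")
        d2 = _chain_dag("d2", "r")
        # (0.5 + 0.5) / (1.5 + 1.5)
        assert mw.semantic_similarity_model1(d1, d2, 0.5) == pytest.approx(
            1 / 3
        )

    def test_similarity_disjoint_dags_is_zero(self):
        assert (
            mw.semantic_similarity_model1(
                _chain_dag("a", "r"), _chain_dag("b", "s"), 0.5
            )
            == 0.0
        )


class TestSemanticModel2:
    @pytest.fixture
    def corpus(self):
        return {
            "d1": _chain_dag("d1", "r"),
            "d2": _chain_dag("d2", "r"),
            "d3": _chain_dag("d3", "s"),
        }

    def test_contributions_are_corpus_specificity(self, corpus):
        contrib = mw.semantic_contributions_model2(corpus)
        assert contrib["r"] == pytest.approx(-math.log(2 / 3))
        assert contrib["d1"] == pytest.approx(-math.log(1 / 3))

    def test_ubiquitous_term_contributes_zero(self):
        dags = {d: _chain_dag(d, "root") for d in ("a", "b", "c")}
        assert mw.semantic_contributions_model2(dags)["root"] == 0.0

    def test_similarity_three_disease_corpus(self, corpus):
        contrib = mw.semantic_contributions_model2(corpus)
        s = mw.semantic_similarity_model2(corpus["d1"], corpus["d2"], contrib)
        # hand evaluation: (0.4055 * 2) / (1.5041 * 2)
        assert s == pytest.approx(0.2696, abs=5e-5)

    def test_identical_dags_score_one(self, corpus):
        contrib = mw.semantic_contributions_model2(corpus)
        s = mw.semantic_similarity_model2(corpus["d1"], corpus["d1"], contrib)
        assert s == pytest.approx(1.0)

    def test_disjoint_dags_score_zero(self, corpus):
        contrib = mw.semantic_contributions_model2(corpus)
        assert (
            mw.semantic_similarity_model2(corpus["d1"], corpus["d3"], contrib)
            == 0.0
        )

    def test_all_ubiquitous_warns_and_returns_zero(self):
        dag = DiseaseDAG("root", frozenset({"root"}), frozenset())
        contrib = mw.semantic_contributions_model2({"a": dag, "b": dag})
        with pytest.warns(UserWarning, match="ubiquitous"):
            assert mw.semantic_similarity_model2(dag, dag, contrib) == 0.0


class TestGip:
    def test_identical_profiles_similarity_one(self):
        K = mw.gip_similarity(np.array([[1.0, 0.0], [1.0, 0.0]]), 1.0)
        assert K[0, 1] == pytest.approx(1.0)

    def test_identity_profiles_give_exp_minus_two(self):
        K = mw.gip_similarity(np.eye(2), 1.0)
        assert K[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_doubling_bandwidth_squares_entries(self):
        rng = np.random.default_rng(3)
        profiles = (rng.random((5, 7)) < 0.4).astype(float)
        profiles[0, 0] = 1.0
        K1 = mw.gip_similarity(profiles, 1.0)
        K2 = mw.gip_similarity(profiles, 2.0)
        np.testing.assert_allclose(K2, K1**2, atol=1e-12)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="bandwidth undefined"):
            mw.gip_similarity(np.zeros((3, 4)), 1.0)

    @given(seed=st.integers(0, 100))
    def test_hamming_monotonicity(self, seed):
        """At fixed bandwidth, a larger profile Hamming distance can
        never yield a larger kernel value."""
        rng = np.random.default_rng(seed)
        profiles = (rng.random((6, 9)) < 0.5).astype(float)
        if profiles.sum() == 0:
            profiles[0, 0] = 1.0
        K = mw.gip_similarity(profiles, 1.0)
        d = np.array(
            [
                [np.sum(np.abs(p - q)) for q in profiles]
                for p in profiles
            ]
        )
        # sorted by increasing distance the kernel must not increase
        order = np.argsort(d, axis=None, kind="stable")
        assert (np.diff(K.flatten()[order]) <= 1e-12).all()


class TestIntegration:
    def test_semantic_pair_uses_mean_of_models(self):
        SS1 = np.array([[1.0, 1 / 3], [1 / 3, 1.0]])
        SS2 = np.array([[1.0, 0.2696], [0.2696, 1.0]])
        KD = np.full((2, 2), 0.9)
        SD = mw.integrate_disease_similarity(
            SS1, SS2, KD, np.ones((2, 2), dtype=bool)
        )
        assert SD[0, 1] == pytest.approx(0.3015, abs=5e-5)
        assert SD[0, 0] == pytest.approx(1.0)

    def test_non_semantic_pair_falls_back_to_gip(self):
        SD = mw.integrate_disease_similarity(
            np.zeros((2, 2)),
            np.zeros((2, 2)),
            np.full((2, 2), 0.1353),
            np.zeros((2, 2), dtype=bool),
        )
        assert SD[0, 1] == pytest.approx(0.1353)

    def test_mirna_integration_branches(self):
        FS = np.array([[1.0, 0.7], [0.7, 1.0]])
        KM = np.array([[1.0, 0.4], [0.4, 1.0]])
        present = np.array([[True, True], [True, True]])
        np.testing.assert_allclose(
            mw.integrate_mirna_similarity(FS, KM, present), FS
        )
        absent = np.zeros((2, 2), dtype=bool)
        np.testing.assert_allclose(
            mw.integrate_mirna_similarity(FS, KM, absent), KM
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            mw.integrate_mirna_similarity(
                np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((3, 3), bool)
            )


class TestBundleInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_layers_symmetric_bounded_unit_diagonal(self, seed):
        data = mw.generate(
            mw.SyntheticConfig(n_d=8, n_m=12, k=2, p_in=0.6, p_out=0.1,
                               seed=seed)
        )
        bundle = mw.compute_bundle(data.dataset, data.forest, data.fs)
        for name in ("SS1", "SS2", "KD", "KM", "SD", "SM"):
            m = getattr(bundle, name)
            np.testing.assert_allclose(m, m.T, atol=1e-12, err_msg=name)
            assert (m >= -1e-12).all() and (m <= 1 + 1e-12).all(), name
        np.testing.assert_allclose(np.diag(bundle.SS1), 1.0)
        np.testing.assert_allclose(np.diag(bundle.KD), 1.0)
        np.testing.assert_allclose(np.diag(bundle.KM), 1.0)

    def test_mirnas_missing_from_fs_fall_back_to_gip(self, small_planted):
        ds = small_planted.dataset
        partial = mw.LabeledMatrix(
            ds.mirna_ids[:4],
            ds.mirna_ids[:4],
            small_planted.fs.values[:4, :4],
        )
        bundle = mw.compute_bundle(ds, small_planted.forest, partial)
        assert bundle.has_functional[:4, :4].all()
        assert not bundle.has_functional[4:, :].any()
        np.testing.assert_allclose(
            bundle.SM[4:, 4:], bundle.KM[4:, 4:], atol=1e-15
        )
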