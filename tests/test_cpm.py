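"""Connectome-based predictive modeling protocol and ridge baseline."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentsna import (cpm_predict, cpm_train, matrix_from_edge_vector,
                       ridge_baseline, vectorize_edges)
from latentsna.cpm import CpmModel


def _sym(rng, v):
    m = rng.standard_normal((v, v))
    return 0.5 * (m + m.T)


class TestVectorizeEdges:
    @pytest.mark.parametrize("v,expected", [(3, 6), (10, 55), (268, 36046)])
    def test_length_is_upper_triangle_with_diagonal(self, v, expected):
        vec = vectorize_edges(np.eye(v))
        assert vec.values.size == expected == (v * v + v) // 2

    def test_roundtrip_identity(self, rng):
        m = _sym(rng, 7)
        np.testing.assert_allclose(
            matrix_from_edge_vector(vectorize_edges(m)), m)

    def test_rowwise_order_and_index_map(self, rng):
        m = _sym(rng, 4)
        vec = vectorize_edges(m)
        # row-wise: (0,0),(0,1),(0,2),(0,3),(1,1),...
        assert vec.values[0] == m[0, 0]
        assert vec.values[4] == m[1, 1]
        for x in range(4):
            for y in range(x, 4):
                assert vec.values[vec.index_of(x, y)] == m[x, y]
        # unordered access
        assert vec.index_of(3, 1) == vec.index_of(1, 3)

    def test_asymmetric_rejected(self, rng):
        m = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_edges(m)

    @given(st.integers(3, 12))
    @settings(max_examples=10, deadline=None)
    def test_roundtrip_property(self, v):
        rng = np.random.default_rng(v)
        m = _sym(rng, v)
        np.testing.assert_allclose(
            matrix_from_edge_vector(vectorize_edges(m)), m, atol=1e-12)


class TestCpmTrain:
    def test_planted_edge_selected(self):
        """One feature correlated ~0.9 with y among noise features is found
        at the 0.001 threshold in virtually every replicate."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, e = 200, 80
            y = rng.standard_normal(n)
            x = rng.standard_normal((n, e))
            x[:, 17] = 0.9 * y + np.sqrt(1 - 0.81) * rng.standard_normal(n)
            model = cpm_train(x, y, 0.001)
            hits += 17 in set(model.positive_edges)
        assert hits == 10

    def test_null_features_type_one_rate(self):
        """y independent of 1000 features at alpha=0.001: about one false
        edge per fit on average."""
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.standard_normal(150)
            x = rng.standard_normal((150, 1000))
            model = cpm_train(x, y, 0.001)
            counts.append(len(model.positive_edges)
                          + len(model.negative_edges))
        assert np.mean(counts) == pytest.approx(1.0, abs=1.0)

    def test_threshold_one_selects_everything(self, rng):
        y = rng.standard_normal(30)
        x = rng.standard_normal((30, 12))
        model = cpm_train(x, y, p_threshold=1.0)
        assert len(model.positive_edges) + len(model.negative_edges) == 12

    def test_no_survivor_flags_empty_and_predicts_mean(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 5))
        model = cpm_train(x, y, p_threshold=1e-12)
        assert model.empty
        pred = cpm_predict(model, rng.standard_normal((7, 5)))
        np.testing.assert_allclose(pred, y.mean())

    def test_constant_columns_dropped_with_warning(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 6))
        x[:, 2] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            model = cpm_train(x, y, p_threshold=1.0)
        assert 2 not in set(model.positive_edges) | set(model.negative_edges)

    def test_edge_sets_disjoint_invariant(self, rng):
        y = rng.standard_normal(60)
        x = rng.standard_normal((60, 40))
        model = cpm_train(x, y, p_threshold=0.2)
        assert not set(model.positive_edges) & set(model.negative_edges)


class TestCpmPredict:
    def test_two_subject_hand_example(self):
        """Strength sums and the linear fit applied by hand."""
        model = CpmModel(positive_edges=np.array([0, 2]),
                         negative_edges=np.array([1]),
                         coef=np.array([2.0, -1.0]), intercept=0.5,
                         terms=("pos", "neg"))
        feats = np.array([[1.0, 4.0, 2.0], [0.0, 1.0, -1.0]])
        # pos strengths: 1+2=3, 0-1=-1 ; neg strengths: 4, 1
        expected = np.array([0.5 + 2 * 3 - 4, 0.5 + 2 * (-1) - 1])
        np.testing.assert_allclose(cpm_predict(model, feats), expected)

    def test_training_fit_is_nonnegative_by_construction(self, rng):
        y = rng.standard_normal(80)
        x = rng.standard_normal((80, 50))
        x[:, 3] += 0.8 * y
        model = cpm_train(x, y, p_threshold=0.05)
        pred = cpm_predict(model, x)
        assert np.corrcoef(pred, y)[0, 1] >= 0.0

    def test_short_feature_vector_rejected(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 30))
        x[:, 25] += 2.0 * y
        model = cpm_train(x, y, p_threshold=0.05)
        with pytest.raises(ValueError):
            cpm_predict(model, rng.standard_normal((3, 10)))


class TestRidgeBaseline:
    def test_huge_penalty_shrinks_to_training_mean(self, rng):
        y = rng.standard_normal(50) + 3.0
        x = rng.standard_normal((50, 10))
        pred = ridge_baseline(x, y, rng.standard_normal((5, 10)),
                              alphas=[1e12])
        np.testing.assert_allclose(pred, y.mean(), atol=0.01)

    def test_zero_penalty_equals_ols(self, rng):
        n, e = 60, 5
        y = rng.standard_normal(n)
        x = rng.standard_normal((n, e))
        xt = rng.standard_normal((4, e))
        pred = ridge_baseline(x, y, xt, alphas=[0.0])
        xd = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
        expected = beta[0] + xt @ beta[1:]
        np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_planted_signal_transfers_to_heldout(self, rng):
        n, e = 150, 20
        beta = rng.standard_normal(e)
        x = rng.standard_normal((n, e))
        y = x @ beta + 0.5 * rng.standard_normal(n)
        xt = rng.standard_normal((50, e))
        yt = xt @ beta + 0.5 * rng.standard_normal(50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = ridge_baseline(x, y, xt)
        assert np.corrcoef(pred, yt)[0, 1] > 0.5

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            ridge_baseline(rng.standard_normal((20, 3)),
                           rng.standard_normal(20),
                           rng.standard_normal((2, 3)), alphas=[])
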