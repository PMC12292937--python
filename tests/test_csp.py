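"""CSP core: covariances, eigendecomposition, features, row selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mi3d import (CSPModel, TrialSet, WeightGene, apply_weight,
                  class_covariance, csp_features, csp_from_covariances,
                  fit_csp, load_csp_hdf5, reduce_rows, save_csp_hdf5)


def _white_ts(n_per_class=200, n_ch=2, n_samp=250, scales=None, seed=0):
    """White-noise trials; optional per-class per-channel std scaling."""
    rng = np.random.default_rng(seed)
    scales = scales or [np.ones(n_ch), np.ones(n_ch)]
    trials, labels = [], []
    for k, sc in enumerate(scales):
        for _ in range(n_per_class):
            trials.append(rng.standard_normal((n_ch, n_samp)) * np.asarray(sc)[:, None])
            labels.append(k + 1)
    return TrialSet(np.array(trials), np.array(labels), 250.0,
                    [f"CH{i}" for i in range(n_ch)])


def _random_spd(rng, dim):
    A = rng.normal(size=(dim, dim))
    return A @ A.T + 0.1 * np.eye(dim)


@pytest.fixture(scope="module")
def model22():
    rng = np.random.default_rng(11)
    evals, P = csp_from_covariances(_random_spd(rng, 22), _random_spd(rng, 22))
    return CSPModel(P=P, eigenvalues=evals, class_a=1, class_b=2)


class TestClassCovariance:
    def test_white_noise_approaches_scaled_identity(self):
        ts = _white_ts(n_per_class=200)
        cov = class_covariance(ts, 1)
        np.testing.assert_allclose(cov, 0.5 * np.eye(2), atol=0.05)

    def test_single_trial_is_its_normalised_covariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3, 100))
        ts = TrialSet(np.stack([X, X]), [1, 1], 250.0, ["A", "B", "C"])
        S = X @ X.T
        np.testing.assert_allclose(class_covariance(ts, 1), S / np.trace(S),
                                   atol=1e-12)

    def test_exactly_symmetric(self):
        ts = _white_ts(n_per_class=5)
        cov = class_covariance(ts, 2)
        assert np.abs(cov - cov.T).max() < 1e-12

    def test_missing_class_errors(self):
        ts = _white_ts(n_per_class=3)
        with pytest.raises(ValueError, match="no trials"):
            class_covariance(ts, 9)


class TestFitCSP:
    def test_identical_generators_give_half_eigenvalues(self):
        ts = _white_ts(n_per_class=200)
        m = fit_csp(ts, 1, 2)
        np.testing.assert_allclose(m.eigenvalues, 0.5, atol=0.05)

    def test_planted_variance_ratio_recovered(self):
        # population covariances diag(4,1) vs diag(1,4): top eigenvalue 4/5
        ts = _white_ts(n_per_class=200, scales=[(2.0, 1.0), (1.0, 2.0)], seed=1)
        m = fit_csp(ts, 1, 2)
        assert abs(m.eigenvalues[0] - 0.8) < 0.05
        assert abs(m.eigenvalues[-1] - 0.2) < 0.05
        v = m.P[0] / np.linalg.norm(m.P[0])
        assert abs(v[0]) > 0.99  # first filter aligned with channel 1

    def test_filter_matrix_is_square_in_channels(self):
        ts = _white_ts(n_per_class=4, n_ch=22, n_samp=100)
        assert fit_csp(ts, 1, 2).P.shape == (22, 22)

    def test_matches_whitening_oracle(self):
        # independent route: explicit whitening + symmetric eigendecomposition
        rng = np.random.default_rng(7)
        for _ in range(20):
            A, B = _random_spd(rng, 4), _random_spd(rng, 4)
            evals, P = csp_from_covariances(A, B)
            lam, U = np.linalg.eigh(A + B)
            Wh = U @ np.diag(lam ** -0.5) @ U.T
            lam2, V = np.linalg.eigh(Wh @ A @ Wh)
            order = np.argsort(lam2)[::-1]
            np.testing.assert_allclose(evals, lam2[order], atol=1e-8)
            oracle_P = (Wh @ V[:, order]).T
            for row, orow in zip(P, oracle_P):
                cos = abs(row @ orow) / (np.linalg.norm(row) * np.linalg.norm(orow))
                assert cos > 1 - 1e-8

    def test_eigenvalues_of_swapped_classes_pair_to_one(self):
        ts = _white_ts(n_per_class=20, n_ch=4, scales=[np.ones(4), np.ones(4)])
        ab = fit_csp(ts, 1, 2).eigenvalues
        ba = fit_csp(ts, 2, 1).eigenvalues
        np.testing.assert_allclose(np.sort(ab) + np.sort(ba)[::-1], 1.0,
                                   atol=1e-8)

    def test_singular_composite_is_ridge_regularised(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((1, 50))
        X = np.vstack([base, base])  # rank-1 trials
        ts = TrialSet(np.stack([X, X, X, X]), [1, 1, 2, 2], 250.0, ["A", "B"])
        with pytest.warns(RuntimeWarning, match="ridge"):
            m = fit_csp(ts, 1, 2)
        assert np.isfinite(m.P).all()


class TestFeatures:
    def test_four_pairs_give_eight_features(self, model22):
        trial = np.random.default_rng(0).standard_normal((22, 250))
        assert csp_features(model22, trial, n_pairs=4).shape == (8,)

    def test_normalised_variance_convention(self, model22):
        trial = np.random.default_rng(1).standard_normal((22, 250))
        f = csp_features(model22, trial, n_pairs=4)
        assert abs(np.exp(f).sum() - 1.0) < 1e-9

    @given(gain=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_global_gain(self, model22, gain):
        trial = np.random.default_rng(2).standard_normal((22, 250))
        f1 = csp_features(model22, trial, n_pairs=3)
        f2 = csp_features(model22, gain * trial, n_pairs=3)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_too_many_pairs_rejected(self, model22):
        trial = np.zeros((22, 100))
        with pytest.raises(ValueError):
            csp_features(model22, trial, n_pairs=12)


class TestReduceRows:
    def test_n4_reduces_22_to_8(self, model22):
        assert reduce_rows(model22, 4).P.shape == (8, 22)

    def test_half_keeps_all_rows_in_order(self, model22):
        r = reduce_rows(model22, 11)
        np.testing.assert_array_equal(r.P, model22.P)

    def test_composition_equals_single_reduction(self, model22):
        a = reduce_rows(reduce_rows(model22, 6), 2)
        b = reduce_rows(model22, 2)
        np.testing.assert_array_equal(a.P, b.P)

    def test_oversized_reduction_rejected(self, model22):
        with pytest.raises(ValueError):
            reduce_rows(model22, 12)


class TestApplyWeight:
    def test_all_ones_is_identity(self):
        P = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(apply_weight(P, WeightGene(np.ones(4))), P)

    def test_single_selection(self):
        P = np.arange(16.0).reshape(4, 4)
        out = apply_weight(P, WeightGene([1, 0, 0, 0]))
        np.testing.assert_array_equal(out, P[:1])

    def test_k_ones_give_k_rows(self):
        P = np.random.default_rng(0).normal(size=(6, 6))
        out = apply_weight(P, WeightGene([1, 0, 1, 1, 0, 0]))
        assert out.shape == (3, 6)

    def test_zero_convention(self):
        P = np.ones((3, 3))
        out = apply_weight(P, WeightGene([0, 1, 0]), drop=False)
        np.testing.assert_array_equal(out, [[0, 0, 0], [1, 1, 1], [0, 0, 0]])

    def test_all_zero_gene_flagged(self):
        with pytest.raises(ValueError, match="all-zero"):
            apply_weight(np.eye(3), WeightGene([0, 0, 0]))

    def test_non_binary_gene_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            WeightGene([0, 2, 1])


def test_csp_model_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    evals, P = csp_from_covariances(_random_spd(rng, 5), _random_spd(rng, 5))
    m = CSPModel(P=P, eigenvalues=evals, class_a=1, class_b=3, n_pairs=2)
    path = tmp_path / "csp.h5"
    save_csp_hdf5(m, path)
    back = load_csp_hdf5(path)
    np.testing.assert_array_equal(back.P, m.P)
    np.testing.assert_array_equal(back.eigenvalues, m.eigenvalues)
    assert (back.class_a, back.class_b, back.n_pairs) == (1, 3, 2)
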