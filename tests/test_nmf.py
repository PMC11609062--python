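"""Factorization primitives: extraction, NNLS refitting, VAF, rescaling."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsynergy import nmf
from emgsynergy.exceptions import ParameterError


def _match_cosines(W_true, W_est):
    from emgsynergy.features import match_and_similarity

    _, r = match_and_similarity(W_true, W_est)
    return r


class TestVaf:
    def test_perfect_reconstruction_is_100(self):
        M = np.random.default_rng(0).random((4, 9))
        assert nmf.vaf(M, M) == pytest.approx(100.0)

    def test_zero_reconstruction_is_0(self):
        M = np.ones((2, 3))
        assert nmf.vaf(M, np.zeros_like(M)) == pytest.approx(0.0)

    def test_hand_example(self):
        # SSE = 1, sum M^2 = 5 -> 100 * (1 - 1/5) = 80
        assert nmf.vaf([[1.0, 2.0]], [[1.0, 1.0]]) == pytest.approx(80.0)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ParameterError):
            nmf.vaf(np.zeros((2, 2)), np.ones((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            nmf.vaf(np.ones((2, 2)), np.ones((2, 3)))

    def test_uncentered_correlation_variant(self):
        M = np.array([[1.0, 2.0]])
        assert nmf.vaf(M, M, method="corr") == pytest.approx(100.0)
        # scaling M_hat leaves the correlation untouched but not the SSE form
        assert nmf.vaf(M, 2 * M, method="corr") == pytest.approx(100.0)
        assert nmf.vaf(M, 2 * M, method="sse") < 100.0


class TestExtract:
    def test_rank1_outer_product_fully_explained(self):
        rng = np.random.default_rng(3)
        M = np.outer(rng.random(6), rng.random(40))
        S = nmf.extract(M, 1, seed=0)
        assert S.vaf_pct > 99.99

    def test_noiseless_low_rank_recovery(self):
        rng = np.random.default_rng(5)
        W_true = rng.random((4, 2))
        C_true = rng.random((2, 30))
        S = nmf.extract(W_true @ C_true, 2, seed=1)
        r = _match_cosines(W_true, S.W)
        assert np.all(r > 0.999)

    def test_reproducible_for_same_seed(self):
        M = np.random.default_rng(11).random((5, 20))
        S1 = nmf.extract(M, 3, seed=42)
        S2 = nmf.extract(M, 3, seed=42)
        np.testing.assert_array_equal(S1.W, S2.W)
        np.testing.assert_array_equal(S1.C, S2.C)

    def test_unit_norm_columns_and_nonnegativity(self):
        M = np.random.default_rng(2).random((6, 25))
        S = nmf.extract(M, 4, seed=0)
        np.testing.assert_allclose(np.linalg.norm(S.W, axis=0), 1.0, atol=1e-9)
        assert np.all(S.W >= 0) and np.all(S.C >= 0)

    def test_training_vaf_nondecreasing_in_n(self):
        M = np.random.default_rng(8).random((6, 60))
        vafs = [nmf.extract(M, n, seed=0).vaf_pct for n in range(1, 5)]
        assert np.all(np.diff(vafs) > -0.1)  # 0.1 pp optimizer tolerance

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            nmf.extract(-np.ones((3, 3)), 1)
        with pytest.raises(ParameterError):
            nmf.extract(np.ones((3, 3)), 0)
        with pytest.raises(ParameterError):
            nmf.extract(np.ones((3, 3)), 4)

    def test_structural_zeros_preserved(self):
        rng = np.random.default_rng(9)
        M = rng.random((4, 30))
        support = np.ones((2, 30), dtype=bool)
        support[0, :15] = False
        S = nmf.extract(M, 2, seed=0, c_support=support)
        assert np.all(S.C[0, :15] == 0.0)
        assert np.any(S.C[0, 15:] > 0)

    def test_matches_reference_mu_implementation(self):
        # independent cross-check against scikit-learn's multiplicative-update
        # solver on the same objective
        from sklearn.decomposition import NMF as SkNMF

        M = np.random.default_rng(4).random((8, 50))
        ours = nmf.extract(M, 3, seed=0, n_restarts=5)
        sk = SkNMF(
            n_components=3, solver="mu", init="random", max_iter=2000,
            random_state=0, tol=1e-7,
        )
        W_sk = sk.fit_transform(M)
        vaf_sk = nmf.vaf(M, W_sk @ sk.components_)
        assert ours.vaf_pct == pytest.approx(vaf_sk, abs=0.5)


class TestFitCoefficients:
    def test_exact_recovery_of_true_coefficients(self):
        rng = np.random.default_rng(6)
        W = rng.random((5, 3))
        C_true = rng.random((3, 12))
        C = nmf.fit_coefficients(W @ C_true, W)
        np.testing.assert_allclose(C, C_true, atol=1e-8)

    def test_zero_matrix_gives_zero_coefficients(self):
        W = np.random.default_rng(0).random((4, 2))
        C = nmf.fit_coefficients(np.zeros((4, 6)), W)
        np.testing.assert_array_equal(C, 0.0)

    def test_matches_bruteforce_active_set_oracle(self):
        # exhaustive NNLS: try every support set, keep the best feasible LS fit
        def brute_nnls(W, m):
            from itertools import combinations

            best, best_err = np.zeros(W.shape[1]), float(np.sum(m**2))
            cols = range(W.shape[1])
            for k in range(1, W.shape[1] + 1):
                for sub in combinations(cols, k):
                    x, *_ = np.linalg.lstsq(W[:, sub], m, rcond=None)
                    if np.any(x < -1e-12):
                        continue
                    full = np.zeros(W.shape[1])
                    full[list(sub)] = x
                    err = float(np.sum((m - W @ full) ** 2))
                    if err < best_err - 1e-15:
                        best, best_err = full, err
            return best

        rng = np.random.default_rng(13)
        W = rng.random((6, 4))
        M = rng.random((6, 8))
        C = nmf.fit_coefficients(M, W)
        for j in range(M.shape[1]):
            np.testing.assert_allclose(C[:, j], brute_nnls(W, M[:, j]), atol=1e-8)

    def test_zero_column_in_w_rejected(self):
        W = np.ones((3, 2))
        W[:, 1] = 0.0
        with pytest.raises(ParameterError):
            nmf.fit_coefficients(np.ones((3, 4)), W)


class TestRescaleWeights:
    def test_unit_sigma_is_identity(self):
        S = nmf.extract(np.random.default_rng(1).random((4, 20)), 2, seed=0)
        S2 = nmf.rescale_weights(S, np.ones(4))
        np.testing.assert_allclose(S2.W, S.W, atol=1e-12)
        np.testing.assert_allclose(S2.C, S.C, atol=1e-12)

    def test_columns_stay_unit_norm(self):
        S = nmf.extract(np.random.default_rng(1).random((4, 20)), 2, seed=0)
        S2 = nmf.rescale_weights(S, np.array([2.0, 0.5, 1.5, 3.0]))
        np.testing.assert_allclose(np.linalg.norm(S2.W, axis=0), 1.0, atol=1e-9)

    def test_single_muscle_toy_moves_scale_into_c(self):
        S = nmf.SynergySet(np.array([[1.0], [0.0]]), np.ones((1, 5)))
        S2 = nmf.rescale_weights(S, np.array([2.0, 1.0]))
        np.testing.assert_allclose(S2.W, [[1.0], [0.0]])
        np.testing.assert_allclose(S2.C, 2 * S.C)

    def test_nonpositive_sigma_rejected(self):
        S = nmf.SynergySet(np.eye(2), np.ones((2, 3)))
        with pytest.raises(ParameterError):
            nmf.rescale_weights(S, np.array([1.0, 0.0]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_mu_updates_never_go_negative(seed):
    rng = np.random.default_rng(seed)
    M = rng.random((4, 15))
    S = nmf.extract(M, 2, seed=seed, n_restarts=1, max_iter=50)
    assert np.all(S.W >= 0) and np.all(S.C >= 0)
    assert S.vaf_pct <= 100.0
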