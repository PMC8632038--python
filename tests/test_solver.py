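import numpy as np
import pytest

from helpers import dtrace_lasso_oracle, kkt_max_violation, random_difference_instance
from wjsdm import (
    CovarianceSet,
    DEWeights,
    PriorKnowledge,
    SolverConfig,
    apg_minimize,
    dtrace_gradient,
    dtrace_loss,
    fit,
    joint_loss,
    lambda_max,
    lla_weights,
    prox_weighted_l1,
)


def _diag_covset(s1, s2):
    p = len(s1)
    mats = np.stack([np.stack([np.diag(s1), np.diag(s2)])])
    return CovarianceSet(mats, [f"g{i}" for i in range(p)])


class TestLoss:
    def test_zero_delta(self, rng):
        S = rng.normal(size=(4, 4))
        S = S @ S.T
        assert dtrace_loss(np.zeros((4, 4)), S, S + np.eye(4)) == 0.0

    def test_scalar_expansion(self):
        # p=1, sigma1=1, sigma2=2, delta=1: 1/2*2*1 - 1*(1-2) = 2
        assert dtrace_loss(np.array([[1.0]]), np.array([[1.0]]), np.array([[2.0]])) == 2.0

    def test_identity_case(self):
        assert dtrace_loss(np.eye(2), np.eye(2), np.eye(2)) == pytest.approx(1.0)

    def test_joint_loss_additivity(self, rng):
        cov, _ = random_difference_instance(rng, p=5, K=3)
        deltas = rng.normal(size=(3, 5, 5))
        deltas = 0.5 * (deltas + np.transpose(deltas, (0, 2, 1)))
        total = joint_loss(deltas, cov)
        parts = sum(
            dtrace_loss(deltas[k], cov.matrices[k, 0], cov.matrices[k, 1]) for k in range(3)
        )
        assert total == pytest.approx(parts, rel=1e-12)
        single = joint_loss(deltas[:1], CovarianceSet(cov.matrices[:1], cov.gene_ids))
        assert single == pytest.approx(
            dtrace_loss(deltas[0], cov.matrices[0, 0], cov.matrices[0, 1]), rel=1e-12
        )


class TestGradient:
    def test_at_zero(self, rng):
        S1 = rng.normal(size=(3, 3))
        S1 = S1 @ S1.T
        S2 = np.eye(3)
        assert np.allclose(dtrace_gradient(np.zeros((3, 3)), S1, S2), -(S1 - S2))

    def test_equal_covariances_vanish_at_zero(self):
        S = np.eye(4) * 2.0
        g = dtrace_gradient(np.zeros((4, 4)), S, S)
        assert np.allclose(g, 0.0)

    def test_matches_finite_differences(self, rng):
        p = 6
        S1 = rng.normal(size=(p, p))
        S1 = S1 @ S1.T / p
        S2 = rng.normal(size=(p, p))
        S2 = S2 @ S2.T / p
        delta = rng.normal(size=(p, p))
        delta = 0.5 * (delta + delta.T)
        g = dtrace_gradient(delta, S1, S2)
        h = 1e-5
        fd = np.zeros_like(g)
        for i in range(p):
            for j in range(p):
                e = np.zeros((p, p))
                e[i, j] = h
                fd[i, j] = (
                    dtrace_loss(delta + e, S1, S2) - dtrace_loss(delta - e, S1, S2)
                ) / (2 * h)
        assert np.linalg.norm(g - fd) / np.linalg.norm(g) < 1e-6


class TestProx:
    def test_zero_thresholds_symmetrize(self, rng):
        M = rng.normal(size=(4, 4))
        assert np.allclose(prox_weighted_l1(M, np.zeros((4, 4))), 0.5 * (M + M.T))

    def test_soft_threshold_values(self):
        M = np.array([[2.0, -0.3], [-0.3, 0.1]])
        T = np.full((2, 2), 0.5)
        out = prox_weighted_l1(M, T)
        assert out[0, 0] == pytest.approx(1.5)
        assert out[0, 1] == 0.0 and out[1, 1] == 0.0

    def test_rejects_negative_thresholds(self):
        with pytest.raises(ValueError):
            prox_weighted_l1(np.eye(2), -np.ones((2, 2)))


class TestLLAWeights:
    def test_zero_pair_weight_gives_zero(self):
        deltas = np.ones((2, 3, 3))
        taus = np.zeros((2, 3, 3))
        assert np.all(lla_weights(deltas, taus, 1e-8) == 0.0)

    def test_single_platform_value(self):
        deltas = np.full((1, 2, 2), 0.25)
        taus = np.ones((1, 2, 2))
        phi = lla_weights(deltas, taus, 1e-8)
        assert np.allclose(phi, 1.0)  # 1 / (2 sqrt(0.25))

    def test_floor_keeps_weights_finite(self):
        phi = lla_weights(np.zeros((1, 2, 2)), np.ones((1, 2, 2)), 1e-8)
        assert np.allclose(phi, 1.0 / (2.0 * np.sqrt(1e-8)))

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            lla_weights(np.zeros((1, 2, 2)), -np.ones((1, 2, 2)), 1e-8)
        with pytest.raises(ValueError):
            lla_weights(np.zeros((1, 2, 2)), np.ones((1, 2, 2)), 0.0)


class TestAPG:
    def test_unpenalized_diagonal_closed_form(self):
        s1 = np.array([1.0, 2.0, 0.5])
        s2 = np.array([2.0, 1.0, 4.0])
        out = apg_minimize(
            np.diag(s1), np.diag(s2), np.zeros((3, 3)), tol=1e-12, max_iter=5000
        )
        expected = np.diag((s1 - s2) / (s1 * s2))
        assert np.allclose(out, expected, atol=1e-8)

    @pytest.mark.parametrize("w", [0.2, 0.9, 1.5])
    def test_scalar_soft_threshold_closed_form(self, w):
        out = apg_minimize(
            np.array([[1.0]]),
            np.array([[2.0]]),
            np.array([[w]]),
            tol=1e-14,
            max_iter=5000,
        )
        expected = np.sign(-1.0) * max(1.0 - w, 0.0) / 2.0
        assert out[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_huge_thresholds_return_zero(self, rng):
        cov, _ = random_difference_instance(rng, p=5, K=1)
        S1, S2 = cov.matrices[0]
        out = apg_minimize(S1, S2, np.full((5, 5), 100.0))
        assert np.all(out == 0.0)

    def test_objective_never_increases_from_init(self, rng):
        cov, _ = random_difference_instance(rng, p=6, K=1)
        S1, S2 = cov.matrices[0]
        T = np.full((6, 6), 0.05)
        init = rng.normal(size=(6, 6))
        init = 0.5 * (init + init.T)
        out = apg_minimize(S1, S2, T, init=init, tol=1e-10, max_iter=2000)
        obj = lambda M: dtrace_loss(M, S1, S2) + np.sum(T * np.abs(M))
        assert obj(out) <= obj(0.5 * (init + init.T)) + 1e-10
        assert np.array_equal(out, out.T)


class TestFit:
    def test_identical_covariances_give_zero(self, rng):
        cov, de = random_difference_instance(rng, p=6, K=2)
        mats = cov.matrices.copy()
        mats[:, 1] = mats[:, 0]
        same = CovarianceSet(mats, cov.gene_ids)
        net = fit(same, de, None, SolverConfig(lambda_value=0.1))
        assert net.support().sum() == 0

    def test_large_lambda_gives_zero(self, rng):
        cov, de = random_difference_instance(rng, p=8, K=2)
        lam = 1.01 * lambda_max(cov, de, None)
        net = fit(cov, de, None, SolverConfig(lambda_value=lam))
        assert net.support().sum() == 0

    def test_symmetry_and_monotone_trace(self, rng):
        cov, de = random_difference_instance(rng, p=8, K=2)
        lam = 0.3 * lambda_max(cov, de, None)
        net = fit(cov, de, None, SolverConfig(lambda_value=lam))
        for k in range(2):
            assert np.array_equal(net.deltas[k], net.deltas[k].T)
        diffs = np.diff(net.objective_trace)
        assert np.all(diffs <= 1e-7 * (1.0 + np.abs(net.objective_trace[:-1])))

    def test_rejects_non_psd_covariances(self, rng):
        cov, de = random_difference_instance(rng, p=4, K=1)
        mats = cov.matrices.copy()
        mats[0, 0, 0, 1] = mats[0, 0, 1, 0] = 5.0  # forces a negative eigenvalue
        bad = CovarianceSet(mats, cov.gene_ids)
        with pytest.raises(ValueError):
            fit(bad, de, None, SolverConfig(lambda_value=0.1))

    def test_unpenalized_diagonal_closed_form(self):
        s1 = np.array([1.0, 2.0, 4.0])
        s2 = np.array([2.0, 1.0, 0.5])
        cov = _diag_covset(s1, s2)
        de = DEWeights(np.full((1, 3), 0.5))
        net = fit(
            cov,
            de,
            None,
            SolverConfig(lambda_value=0.0, inner_tol=1e-12, inner_max_iter=5000, outer_max_iter=1),
        )
        assert np.allclose(np.diag(net.deltas[0]), 1.0 / s2 - 1.0 / s1, atol=1e-7)


class TestLambdaMax:
    def test_identical_covariances_give_zero(self, rng):
        cov, de = random_difference_instance(rng, p=5, K=2)
        mats = cov.matrices.copy()
        mats[:, 1] = mats[:, 0]
        assert lambda_max(CovarianceSet(mats, cov.gene_ids), de, None) == 0.0

    def test_bound_is_tight_for_round_zero(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            cov, de = random_difference_instance(local, p=10, K=2)
            lam = lambda_max(cov, de, None)
            zero = fit(cov, de, None, SolverConfig(lambda_value=1.01 * lam))
            assert zero.support().sum() == 0
            round0 = fit(
                cov, de, None, SolverConfig(lambda_value=0.5 * lam, outer_max_iter=1)
            )
            assert round0.support().sum() > 0

    def test_unpenalized_pairs_reported(self, rng):
        cov, _ = random_difference_instance(rng, p=5, K=1)
        r = np.full((1, 5), 0.5)
        r[0, :2] = 0.0  # pair (0, 1) has tau = 0: penalty-free
        de = DEWeights(r)
        _, pairs = lambda_max(cov, de, None, return_unpenalized=True)
        assert (1, 0, 1) in pairs


class TestRoundZeroOracle:
    """Round-0 solutions against exhaustive enumeration at p = 3."""

    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        cov, de = random_difference_instance(rng, p=3, K=1)
        lam = 0.3 * lambda_max(cov, de, None)
        T = lam * de.pair_weights[0]  # W = 1
        return cov, de, lam, T

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration(self, seed):
        cov, de, lam, T = self._instance(seed)
        net = fit(
            cov,
            de,
            None,
            SolverConfig(
                lambda_value=lam, inner_tol=1e-13, inner_max_iter=50000, outer_max_iter=1
            ),
        )
        S1 = cov.matrices[0, 0] + 1e-8 * np.eye(3)
        S2 = cov.matrices[0, 1] + 1e-8 * np.eye(3)
        oracle = dtrace_lasso_oracle(S1, S2, T)
        assert np.allclose(net.deltas[0], oracle, atol=1e-3)
        assert kkt_max_violation(net.deltas[0], S1, S2, T) < 1e-6

    def test_weaker_prior_weight_never_shrinks_entry(self):
        """Decreasing W_ij cannot decrease |Delta_ij| of the convex solution."""
        rng = np.random.default_rng(5)
        cov, de = random_difference_instance(rng, p=3, K=1)
        lam = 0.4 * lambda_max(cov, de, None)
        S1 = cov.matrices[0, 0] + 1e-8 * np.eye(3)
        S2 = cov.matrices[0, 1] + 1e-8 * np.eye(3)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            W_hi = np.ones((3, 3))
            W_lo = np.ones((3, 3))
            W_lo[i, j] = W_lo[j, i] = 0.3
            sol_hi = dtrace_lasso_oracle(S1, S2, lam * de.pair_weights[0] * W_hi)
            sol_lo = dtrace_lasso_oracle(S1, S2, lam * de.pair_weights[0] * W_lo)
            assert abs(sol_lo[i, j]) >= abs(sol_hi[i, j]) - 1e-9
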