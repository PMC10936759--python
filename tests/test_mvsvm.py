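"""Tests for the two-view SVM: kernel blocks, dual QP, bias, decisions."""

import numpy as np
import pytest

from shsvm import mvsvm
from shsvm.hidden_space import HiddenSpaceConfig, HiddenSpaceModel
from shsvm.mvsvm import (
    MVSVMConfig,
    build_kernel_blocks,
    decision_function,
    fit,
    fit_svm_precomputed,
    kkt_residuals,
    predict,
    recover_bias,
    solve_dual,
    svm_single_view,
)
from shsvm.synthetic import TwoViewGenConfig, gen_two_view

from qp_oracle import barrier_qp, qp_objective


def _identity_hidden(d, r=None):
    r = r or d
    return HiddenSpaceModel(
        omega=np.eye(d)[:r], j_trace=[0.0], n_iters=0, converged=True,
        config=HiddenSpaceConfig(r=r),
    )


def _blocks_for(ds, cfg, omega=None):
    omega = np.eye(ds.xa.shape[1])[:2] if omega is None else omega
    ha, hb = ds.xa @ omega.T, ds.xb @ omega.T
    return build_kernel_blocks(ds.xa, ds.xb, ha, hb, ds.y, cfg)


class TestKernelBlocks:
    def test_lambda_zero_decouples_views(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=20, seed=0))
        blocks = _blocks_for(ds, MVSVMConfig(lam=0.0, sigma=1.0))
        assert np.array_equal(blocks.k_ab, np.zeros((20, 20)))

    def test_lambda_one_hidden_coefficients(self):
        cfg = MVSVMConfig(lam=1.0)
        assert cfg.diag_coeff == pytest.approx(3.0 / 5.0)
        assert cfg.cross_coeff == pytest.approx(2.0 / 5.0)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
    def test_assembled_kernel_is_psd(self, lam):
        ds = gen_two_view(TwoViewGenConfig(n_samples=30, seed=1))
        blocks = _blocks_for(ds, MVSVMConfig(lam=lam, sigma=1.5))
        min_eig = float(np.linalg.eigvalsh(blocks.k_full)[0])
        assert min_eig >= -1e-8

    def test_inconsistent_sample_counts_rejected(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=10, seed=2))
        with pytest.raises(ValueError, match="inconsistent"):
            build_kernel_blocks(
                ds.xa, ds.xb[:5], ds.xa[:, :2], ds.xb[:, :2], ds.y, MVSVMConfig()
            )


class TestSolveDual:
    def test_constraints_hold_at_solution(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=40, seed=3))
        cfg = MVSVMConfig(C_A=2.0, C_B=0.5, lam=0.4, sigma=1.0)
        blocks = _blocks_for(ds, cfg)
        alpha = solve_dual(blocks, ds.y, cfg.C_A, cfg.C_B)
        n = 40
        assert abs(np.dot(alpha[:n], ds.y)) <= 1e-6
        assert abs(np.dot(alpha[n:], ds.y)) <= 1e-6
        assert alpha.min() >= -1e-12
        assert np.all(alpha[:n] <= cfg.C_A + 1e-9)
        assert np.all(alpha[n:] <= cfg.C_B + 1e-9)

    def test_two_point_problem_matches_extended_single_view_svm(self):
        # 1-D toy (x=-1 -> y=-1, x=+1 -> y=+1), lambda=0: view A's block of
        # the joint dual must equal a standalone SVM on the concatenated
        # (original + hidden) view-A kernel
        xa = np.array([[-1.0], [1.0]])
        xb = np.array([[-2.0], [2.0]])
        y = np.array([-1.0, 1.0])
        omega = np.eye(1)
        cfg = MVSVMConfig(C_A=100.0, C_B=100.0, lam=0.0, sigma=1.0)
        blocks = build_kernel_blocks(xa, xb, xa, xb, y, cfg)
        alpha = solve_dual(blocks, y, cfg.C_A, cfg.C_B)
        gram_ext = blocks.kxa + blocks.diag_coeff * blocks.kha
        single = fit_svm_precomputed(gram_ext, y, cfg.C_A)
        assert np.allclose(alpha[:2], single.alpha, atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_dual_objective_matches_independent_solver(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        ds = gen_two_view(TwoViewGenConfig(n_samples=n, seed=seed, noise_sd=0.4))
        cfg = MVSVMConfig(
            C_A=float(rng.choice([0.5, 2.0])), C_B=float(rng.choice([0.5, 2.0])),
            lam=float(rng.choice([0.0, 0.5, 1.0])), sigma=1.2,
        )
        blocks = _blocks_for(ds, cfg)
        alpha = solve_dual(blocks, ds.y, cfg.C_A, cfg.C_B)
        eq = np.zeros((2, 2 * n)); eq[0, :n] = ds.y; eq[1, n:] = ds.y
        upper = np.concatenate([np.full(n, cfg.C_A), np.full(n, cfg.C_B)])
        oracle = barrier_qp(blocks.k_full, eq, upper)
        gap = abs(qp_objective(alpha, blocks.k_full) - qp_objective(oracle, blocks.k_full))
        assert gap / (1 + abs(qp_objective(oracle, blocks.k_full))) < 1e-6

    def test_kkt_residuals_small(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=50, seed=4))
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.6, sigma=1.0)
        blocks = _blocks_for(ds, cfg)
        alpha = solve_dual(blocks, ds.y, 1.0, 1.0)
        rep = kkt_residuals(alpha, blocks, ds.y, 1.0, 1.0)
        assert rep["stationarity"] <= 1e-6
        assert rep["equality"] <= 1e-6
        assert rep["bounds"] <= 1e-9

    def test_single_class_labels_rejected(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=10, seed=5))
        y = np.ones(10)
        blocks = build_kernel_blocks(
            ds.xa, ds.xb, ds.xa[:, :2], ds.xb[:, :2], y, MVSVMConfig()
        )
        with pytest.raises(ValueError, match="single-class"):
            solve_dual(blocks, y, 1.0, 1.0)


class TestBiasRecovery:
    def test_symmetric_two_point_problem_has_zero_bias(self):
        xa = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        cfg = MVSVMConfig(C_A=100.0, C_B=100.0, lam=0.2, sigma=1.0)
        blocks = build_kernel_blocks(xa, xa, xa, xa, y, cfg)
        alpha = solve_dual(blocks, y, cfg.C_A, cfg.C_B)
        b_a, b_b = recover_bias(alpha, blocks, y, cfg.C_A, cfg.C_B)
        assert b_a == pytest.approx(0.0, abs=1e-8)
        assert b_b == pytest.approx(0.0, abs=1e-8)

    def test_all_margin_vectors_agree_on_bias(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=60, seed=6, noise_sd=0.5))
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.5, sigma=1.5)
        blocks = _blocks_for(ds, cfg)
        alpha = solve_dual(blocks, ds.y, 1.0, 1.0)
        fa, fb = mvsvm._train_scores(alpha, blocks, ds.y)
        for scores, a in ((fa, alpha[:60]), (fb, alpha[60:])):
            margin = (a > 1e-6) & (a < 1.0 - 1e-6)
            if np.any(margin):
                biases = ds.y[margin] - scores[margin]
                assert np.max(biases) - np.min(biases) < 1e-6

    def test_margin_identity_holds_at_margin_vectors(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=50, seed=7, noise_sd=0.4))
        cfg = MVSVMConfig(C_A=2.0, C_B=2.0, lam=0.3, sigma=1.5)
        model = fit(ds, cfg)
        blocks = build_kernel_blocks(
            model.xa, model.xb, model.ha, model.hb, model.y, cfg
        )
        fa, fb = mvsvm._train_scores(model.alpha, blocks, model.y)
        n = 50
        for scores, a, b, c in (
            (fa, model.alpha[:n], model.b_a, cfg.C_A),
            (fb, model.alpha[n:], model.b_b, cfg.C_B),
        ):
            margin = (a > 1e-6 * c) & (a < c * (1 - 1e-6))
            for i in np.where(margin)[0]:
                assert model.y[i] * (scores[i] + b) == pytest.approx(1.0, abs=1e-6)


class TestDecisionFunction:
    def test_antisymmetric_data_scores_zero_at_center(self):
        # training set symmetric under x -> -x with flipped labels: the
        # decision function must vanish at the origin
        xa = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.5, sigma=1.0,
                          hidden_model=_identity_hidden(1))
        model = fit((xa, xa, y), cfg)
        score = decision_function(model, np.zeros((1, 1)), np.zeros((1, 1)))
        assert score[0] == pytest.approx(0.0, abs=1e-10)

    def test_separable_toy_training_labels_reproduced(self):
        ds = gen_two_view(
            TwoViewGenConfig(n_samples=30, class_separation=5.0, noise_sd=0.1, seed=8)
        )
        cfg = MVSVMConfig(C_A=10.0, C_B=10.0, lam=0.4, sigma=2.0,
                          hidden_config=HiddenSpaceConfig(r=2, seed=8))
        model = fit(ds, cfg)
        assert np.array_equal(predict(model, ds), ds.y)

    def test_lambda_zero_equals_decoupled_extended_view_svms(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=60, noise_sd=0.4, seed=9))
        hidden = _identity_hidden(6, r=2)
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.0, sigma=1.5, hidden_model=hidden)
        model = fit(ds, cfg)
        te = gen_two_view(TwoViewGenConfig(n_samples=40, noise_sd=0.4, seed=10))
        joint = decision_function(model, te.xa, te.xb)

        # independently train one extended-view SVM per view and average
        def extended_scores(xtr, xte, sigma):
            h_tr = xtr @ hidden.omega.T
            h_te = xte @ hidden.omega.T
            gram = mvsvm.gaussian_gram(xtr, None, sigma) + mvsvm.gaussian_gram(h_tr, None, sigma)
            single = fit_svm_precomputed(gram, ds.y, 1.0)
            cross = (
                mvsvm.gaussian_gram(xte, xtr, sigma)
                + mvsvm.gaussian_gram(h_te, h_tr, sigma)
            )
            return cross @ (single.alpha * ds.y) + single.b

        fa = extended_scores(ds.xa, te.xa, 1.5)
        fb = extended_scores(ds.xb, te.xb, 1.5)
        expected = 0.5 * (fa + fb)
        assert np.allclose(joint, expected, atol=1e-5)
        assert np.array_equal(
            predict(model, (te.xa, te.xb)), np.where(expected >= 0, 1.0, -1.0)
        )

    def test_refit_is_deterministic(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=40, seed=11))
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.5, sigma=1.0,
                          hidden_config=HiddenSpaceConfig(r=2, seed=11))
        m1 = fit(ds, cfg)
        m2 = fit(ds, cfg)
        assert np.array_equal(m1.alpha, m2.alpha)
        assert m1.b_a == m2.b_a and m1.b_b == m2.b_b

    def test_duplicating_samples_with_halved_C_keeps_decisions(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=24, noise_sd=0.5, seed=12))
        hidden = _identity_hidden(6, r=2)
        cfg1 = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.3, sigma=1.5, hidden_model=hidden)
        cfg2 = MVSVMConfig(C_A=0.5, C_B=0.5, lam=0.3, sigma=1.5, hidden_model=hidden)
        m1 = fit(ds, cfg1)
        xa2 = np.vstack([ds.xa, ds.xa])
        xb2 = np.vstack([ds.xb, ds.xb])
        y2 = np.concatenate([ds.y, ds.y])
        m2 = fit((xa2, xb2, y2), cfg2)
        q = gen_two_view(TwoViewGenConfig(n_samples=20, noise_sd=0.5, seed=13))
        s1 = decision_function(m1, q.xa, q.xb)
        s2 = decision_function(m2, q.xa, q.xb)
        assert np.allclose(s1, s2, atol=1e-4)

    def test_query_dimension_mismatch_rejected(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=20, seed=14))
        cfg = MVSVMConfig(hidden_config=HiddenSpaceConfig(r=2, seed=0))
        model = fit(ds, cfg)
        with pytest.raises(ValueError):
            decision_function(model, np.zeros((2, 3)), np.zeros((2, 6)))


class TestSingleViewSVM:
    def test_two_point_closed_form(self):
        # dual of the 2-point problem: alpha1 = alpha2 = 1/(K11 - K12),
        # b = 0, margin points at f = +/- 1
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = svm_single_view(X, y, C=1000.0, sigma=1.0)
        k11 = 1.0
        k12 = np.exp(-(2.0**2) / 2.0)
        expected_alpha = 1.0 / (k11 - k12)
        assert np.allclose(model.alpha, expected_alpha, atol=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(model.decision(X), y, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            svm_single_view(np.zeros((4, 2)), np.ones(4), 1.0, 1.0)

    def test_matches_decoupled_dual_blocks_at_lambda_zero(self):
        ds = gen_two_view(TwoViewGenConfig(n_samples=30, noise_sd=0.4, seed=15))
        hidden = _identity_hidden(6, r=2)
        cfg = MVSVMConfig(C_A=1.0, C_B=1.0, lam=0.0, sigma=1.5, hidden_model=hidden)
        blocks = build_kernel_blocks(
            ds.xa, ds.xb, ds.xa @ hidden.omega.T, ds.xb @ hidden.omega.T, ds.y, cfg
        )
        alpha = solve_dual(blocks, ds.y, 1.0, 1.0)
        single_a = fit_svm_precomputed(blocks.kxa + blocks.kha, ds.y, 1.0)
        single_b = fit_svm_precomputed(blocks.kxb + blocks.khb, ds.y, 1.0)
        assert np.allclose(alpha[:30], single_a.alpha, atol=1e-5)
        assert np.allclose(alpha[30:], single_b.alpha, atol=1e-5)
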