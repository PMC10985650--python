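import numpy as np
import pytest
from scipy import stats

from voxlmm import estimation as est
from voxlmm import inference as inf
from voxlmm.estimation import FsfsConfig, fsfs_fit_vectorised
from voxlmm.model_spec import assemble_full_D

from conftest import dense_forms, forms_as_set, make_single_voxel


def _fitted(seed=5, n=60, lks=(10,), qks=(2,), p=3):
    inst = make_single_voxel(seed, n, list(lks), list(qks), p=p)
    batch = forms_as_set(inst["forms"])
    fit = fsfs_fit_vectorised(batch, list(lks), list(qks),
                              FsfsConfig(tol=1e-12))
    return inst, batch, fit


class TestWaldT:
    def test_zero_contrast_value_gives_zero_statistic(self):
        inst, batch, fit = _fitted()
        fit.beta[:] = np.array([[1.0, 0.0, 3.0]])  # L beta = 0
        res = inf.wald_T(fit, batch, np.array([0.0, 1.0, 0.0]), [10], [2])
        assert res.statistic[0] == 0.0

    def test_matches_dense_formula(self):
        inst, batch, fit = _fitted(seed=6)
        L = np.array([0.0, 1.0, 0.0])
        n = inst["X"].shape[0]
        Z = inst["Z"]
        D = assemble_full_D(fit.D_block(0)[0:1], [10])
        V = np.eye(n) + Z @ D @ Z.T
        Vi = np.linalg.inv(V)
        A = np.linalg.inv(inst["X"].T @ Vi @ inst["X"])
        t_dense = (L @ fit.beta[0]) / np.sqrt(fit.sigma2[0] * L @ A @ L)
        res = inf.wald_T(fit, batch, L, [10], [2])
        assert res.statistic[0] == pytest.approx(t_dense, rel=1e-10)

    def test_zero_D_reproduces_classical_t(self):
        inst = make_single_voxel(7, 25, [], [], p=3)
        batch = forms_as_set(inst["forms"])
        fit = fsfs_fit_vectorised(batch, [], [], FsfsConfig())
        L = np.array([0.0, 1.0, 0.0])
        res = inf.wald_T(fit, batch, L, [], [])
        X, Y = inst["X"], inst["Y"]
        bols = np.linalg.lstsq(X, Y, rcond=None)[0]
        s2 = float((Y - X @ bols) @ (Y - X @ bols)) / (25 - 3)
        t_cl = (L @ bols) / np.sqrt(s2 * L @ np.linalg.inv(X.T @ X) @ L)
        assert res.statistic[0] == pytest.approx(t_cl, rel=1e-10)
        assert res.df[0] == 22
        p_cl = 2 * stats.t.sf(abs(t_cl), 22)
        assert res.p[0] == pytest.approx(p_cl, rel=1e-12)


class TestWaldF:
    def test_single_row_F_is_T_squared(self):
        inst, batch, fit = _fitted(seed=8)
        L = np.array([0.0, 0.0, 1.0])
        rt = inf.wald_T(fit, batch, L, [10], [2])
        rf = inf.wald_F(fit, batch, L, [10], [2])
        assert rf.statistic[0] == pytest.approx(rt.statistic[0] ** 2,
                                                rel=1e-10)
        assert rf.df[0] == pytest.approx(rt.df[0], rel=1e-10)

    def test_beta_in_null_space_gives_zero(self):
        inst, batch, fit = _fitted(seed=9)
        fit.beta[:] = np.array([[5.0, 0.0, 0.0]])
        L = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        rf = inf.wald_F(fit, batch, L, [10], [2])
        assert rf.statistic[0] == pytest.approx(0.0, abs=1e-14)

    def test_matches_dense_formula(self):
        inst, batch, fit = _fitted(seed=10)
        L = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, -1.0]])
        n = inst["X"].shape[0]
        D = assemble_full_D(fit.D_block(0)[0:1], [10])
        V = np.eye(n) + inst["Z"] @ D @ inst["Z"].T
        Vi = np.linalg.inv(V)
        A = np.linalg.inv(inst["X"].T @ Vi @ inst["X"])
        Lb = L @ fit.beta[0]
        f_dense = Lb @ np.linalg.solve(L @ A @ L.T, Lb) \
            / (fit.sigma2[0] * 2)
        rf = inf.wald_F(fit, batch, L, [10], [2])
        assert rf.statistic[0] == pytest.approx(f_dense, rel=1e-10)
        assert rf.rank == 2


class TestSatterthwaite:
    def test_no_random_effects_limit_is_n_minus_p(self):
        inst = make_single_voxel(11, 30, [], [], p=4)
        batch = forms_as_set(inst["forms"])
        fit = fsfs_fit_vectorised(batch, [], [], FsfsConfig())
        df = inf.satterthwaite_df(fit, batch, np.eye(4)[1], [], [])
        assert df[0] == 26

    def test_matches_finite_difference_oracle(self):
        """Balanced random-intercept design, between-level contrast: the
        closed-form derivative of S^2 in (sigma^2, vec D) agrees with
        central finite differences pushed through the same moment match."""
        inst, batch, fit = _fitted(seed=12, n=60, lks=(6,), qks=(1,))
        L = np.array([0.0, 1.0, 0.0])
        X, Z = inst["X"], inst["Z"]
        n = 60
        s2h = float(fit.sigma2[0])
        Dh = fit.D_block(0)[0]

        def S2(sig2, d):
            V = np.eye(n) + d * (Z @ Z.T)
            A = np.linalg.inv(X.T @ np.linalg.solve(V, X))
            return sig2 * (L @ A @ L)

        h = 1e-6
        grad_fd = np.array([
            (S2(s2h + h, Dh[0, 0]) - S2(s2h - h, Dh[0, 0])) / (2 * h),
            (S2(s2h, Dh[0, 0] + h) - S2(s2h, Dh[0, 0] - h)) / (2 * h)])
        kern, marg, A = inf._inference_kernel(batch, fit, [6], [1], None)
        info = inf.variance_information(kern, marg, fit.sigma2, A)[0]
        var_fd = grad_fd @ np.linalg.solve(info, grad_fd)
        df_fd = 2 * S2(s2h, Dh[0, 0]) ** 2 / var_fd
        df = inf.satterthwaite_df(fit, batch, L, [6], [1])
        assert df[0] == pytest.approx(df_fd, rel=1e-3)

    def test_positive_on_random_converged_instances(self):
        count = 0
        for s in range(100):
            inst, batch, fit = _fitted(seed=2000 + s, n=40, lks=(8,),
                                       qks=(1,))
            if not fit.converged[0]:
                continue
            df = inf.satterthwaite_df(fit, batch, np.array([0.0, 1.0, 0.0]),
                                      [8], [1])
            assert np.isfinite(df[0]) and df[0] > 0
            count += 1
        assert count >= 90


class TestPValues:
    def test_zero_statistic_two_sided_p_one(self):
        p = inf.p_values(np.array([0.0]), np.array([10.0]), "T")
        assert p[0] == 1.0

    def test_large_df_approaches_normal(self):
        p = inf.p_values(np.array([1.96]), np.array([1e7]), "T")
        assert p[0] == pytest.approx(2 * stats.norm.sf(1.96), abs=1e-6)

    def test_tabulated_t_quantile(self):
        # P(|T| > 2.228) = 0.05 at 10 df (standard t table)
        p = inf.p_values(np.array([2.228]), np.array([10.0]), "T")
        assert p[0] == pytest.approx(0.05, abs=5e-4)

    def test_nan_propagates(self):
        p = inf.p_values(np.array([np.nan, 1.0]), np.array([5.0, np.nan]),
                         "T")
        assert np.isnan(p).all()


class TestMultipleTesting:
    def test_single_test_reduces_to_alpha_rule(self):
        for pv in (0.04, 0.06):
            rej_b, _ = inf.multiple_testing(np.array([pv]), "bonferroni")
            rej_h, _ = inf.multiple_testing(np.array([pv]), "bh")
            assert rej_b[0] == rej_h[0] == (pv <= 0.05)

    def test_bh_step_up_hand_example(self):
        # thresholds k alpha/m = .0125, .025, .0375, .05; step-up stops at
        # k=2 since 0.04 > 0.0375
        p = np.array([0.01, 0.02, 0.04, 0.5])
        rej, _ = inf.multiple_testing(p, "bh", 0.05)
        assert rej.tolist() == [True, True, False, False]
        rej_b, _ = inf.multiple_testing(p, "bonferroni", 0.05)
        assert rej_b.tolist() == [True, False, False, False]

    def test_all_ones_rejects_nothing(self):
        rej, _ = inf.multiple_testing(np.ones(20), "bh")
        assert not rej.any()

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            inf.multiple_testing(np.array([]))


class TestLikelihoodRatio:
    def test_zero_statistic_gives_p_one(self):
        res = inf.likelihood_ratio_test(np.array([5.0]), np.array([5.0]),
                                        q=1, q_tilde=1)
        assert res.p[0] == 1.0

    def test_point_mass_component(self):
        # a = 0, b = 1: p = 0.5 P(chi2_1 > x) for x > 0
        res = inf.likelihood_ratio_test(np.array([0.0]), np.array([1.92]),
                                        q=1, q_tilde=1)
        assert res.df_pair == (0, 1)
        assert res.p[0] == pytest.approx(0.5 * stats.chi2.sf(3.84, 1),
                                         rel=1e-10)

    def test_even_mixture_hand_value(self):
        res = inf.likelihood_ratio_test(np.array([0.0]), np.array([1.92]),
                                        q=2, q_tilde=1)
        want = 0.5 * stats.chi2.sf(3.84, 1) + 0.5 * stats.chi2.sf(3.84, 2)
        assert res.p[0] == pytest.approx(want, rel=1e-10)

    def test_small_negative_clipped_large_negative_flagged(self):
        res = inf.likelihood_ratio_test(np.array([1.0, 1.0]),
                                        np.array([1.0 - 1e-8, 0.0]),
                                        q=1, q_tilde=1)
        assert res.statistic[0] == 0.0 and res.n_clipped == 1
        assert res.flagged[1] and np.isnan(res.p[1])

    def test_p_monotone_in_statistic(self):
        x = np.linspace(0, 20, 200)
        res = inf.likelihood_ratio_test(np.zeros_like(x), x / 2,
                                        q=2, q_tilde=1)
        assert np.all(np.diff(res.p) <= 1e-15)
        assert np.all((res.p >= 0) & (res.p <= 1))

    def test_null_rejection_rate_is_conservative(self):
        """1000 replicates under D = 0: rejection at alpha = 0.05 stays
        below alpha + 3 Monte-Carlo SEs (boundary mixture null)."""
        rng = np.random.default_rng(77)
        n, l = 50, 10
        inst = make_single_voxel(78, n, [l], [1], d_diag=0.0, d_offdiag=0.0)
        X, Z = inst["X"], inst["Z"]
        reps = 1000
        Y = (X @ inst["beta"])[:, None] + rng.normal(size=(n, reps))
        from voxlmm.product_forms import ProductFormSet
        batch = ProductFormSet(
            P=(X.T @ X)[None], R=(X.T @ Z)[None], U=(Z.T @ Z)[None],
            Q=(X.T @ Y).T, S=np.einsum("iv,iv->v", Y, Y), T=(Y.T @ Z),
            group_index=np.zeros(reps, dtype=np.int64),
            n_obs=np.full(reps, n, dtype=np.int64))
        full = fsfs_fit_vectorised(batch, [l], [1], FsfsConfig())
        null = fsfs_fit_vectorised(batch, [], [], FsfsConfig())
        res = inf.likelihood_ratio_test(null.loglik, full.loglik,
                                        q=1, q_tilde=1)
        rate = np.mean(res.p <= 0.05)
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * mc_se
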