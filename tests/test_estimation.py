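import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxlmm import estimation as est
from voxlmm.estimation import FsfsConfig, fsfs_fit, fsfs_fit_vectorised
from voxlmm.model_spec import assemble_full_D
from voxlmm.oracle import direct_reml
from voxlmm.product_forms import ProductForms

from conftest import dense_forms, forms_as_set, make_single_voxel, stack_forms


def dense_restricted_loglik(X, Y, Z, beta, sigma2, D_blocks, lks):
    """Straightforward dense evaluation of the REML criterion."""
    n, p = X.shape
    D = assemble_full_D(D_blocks, lks)
    V = np.eye(n) + Z @ D @ Z.T
    Vi = np.linalg.inv(V)
    e = Y - X @ beta
    XtViX = X.T @ Vi @ X
    return -0.5 * ((n - p) * np.log(sigma2) + e @ Vi @ e / sigma2
                   + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1])


class TestRemlCriterion:
    def test_matches_dense_evaluation(self):
        inst = make_single_voxel(1, 15, [3], [1], p=2)
        beta = np.array([1.0, -0.5])
        D = [np.array([[0.8]])]
        got = est.reml_criterion(inst["forms"], beta, 1.3, D, [3], [1])
        want = dense_restricted_loglik(inst["X"], inst["Y"], inst["Z"],
                                       beta, 1.3, D, [3])
        assert got == pytest.approx(want, rel=1e-10)

    def test_multi_effect_matches_dense(self):
        inst = make_single_voxel(2, 15, [3], [2], p=2)
        beta = np.array([0.5, 1.0])
        D = [np.array([[1.0, 0.3], [0.3, 0.7]])]
        got = est.reml_criterion(inst["forms"], beta, 0.9, D, [3], [2])
        want = dense_restricted_loglik(inst["X"], inst["Y"], inst["Z"],
                                       beta, 0.9, D, [3])
        assert got == pytest.approx(want, rel=1e-10)

    def test_zero_D_reduces_to_linear_model(self):
        inst = make_single_voxel(3, 18, [3], [1], p=2)
        X, Y = inst["X"], inst["Y"]
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        s2 = float((Y - X @ beta) @ (Y - X @ beta)) / (18 - 2)
        got = est.reml_criterion(inst["forms"], beta, s2,
                                 [np.zeros((1, 1))], [3], [1])
        want = -0.5 * ((18 - 2) * np.log(s2)
                       + (Y - X @ beta) @ (Y - X @ beta) / s2
                       + np.linalg.slogdet(X.T @ X)[1])
        assert got == pytest.approx(want, rel=1e-12)

    def test_shifting_response_matches_dense(self):
        inst = make_single_voxel(4, 15, [3], [1], p=2)
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]
        Y2 = Y + 2.0
        forms2 = dense_forms(X, Y2, Z)
        beta = np.array([1.0, 0.2])
        D = [np.array([[0.5]])]
        got = est.reml_criterion(forms2, beta, 1.1, D, [3], [1])
        want = dense_restricted_loglik(X, Y2, Z, beta, 1.1, D, [3])
        assert got == pytest.approx(want, rel=1e-10)

    def test_nonpositive_variance_rejected(self):
        inst = make_single_voxel(5, 12, [3], [1])
        with pytest.raises(ValueError):
            est.reml_criterion(inst["forms"], np.zeros(3), 0.0,
                               [np.eye(1)], [3], [1])


class TestGlsUpdate:
    def test_zero_D_gives_ols(self):
        inst = make_single_voxel(6, 20, [4], [1], p=3)
        beta, _ = est.gls_update(inst["forms"], [np.zeros((1, 1))], [4], [1])
        ols = np.linalg.solve(inst["forms"].P, inst["forms"].Q)
        assert np.allclose(beta, ols, atol=1e-12)

    def test_matches_dense_gls(self):
        inst = make_single_voxel(7, 12, [3], [1], p=2)
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]
        D = [np.array([[0.6]])]
        beta, s2 = est.gls_update(inst["forms"], D, [3], [1])
        V = np.eye(12) + Z @ assemble_full_D(D, [3]) @ Z.T
        Vi = np.linalg.inv(V)
        bd = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ Y)
        e = Y - X @ bd
        assert np.allclose(beta, bd, atol=1e-10)
        assert s2 == pytest.approx(e @ Vi @ e / (12 - 2), rel=1e-10)

    def test_ml_scale_uses_n(self):
        inst = make_single_voxel(7, 12, [3], [1], p=2)
        D = [np.array([[0.6]])]
        _, s2_reml = est.gls_update(inst["forms"], D, [3], [1], "reml")
        _, s2_ml = est.gls_update(inst["forms"], D, [3], [1], "ml")
        assert s2_ml == pytest.approx(s2_reml * (12 - 2) / 12, rel=1e-12)

    def test_duplicated_design_matches_dense_oracle(self):
        """Duplicating observations changes the GLS weighting (replicates
        double residual precision relative to the random effects), so the
        check is dense-oracle agreement on the duplicated design — plus
        exact invariance in the D = 0 (OLS) limit."""
        inst = make_single_voxel(8, 10, [2], [1], p=2)
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]
        D = [np.array([[0.4]])]
        X2, Y2, Z2 = np.tile(X, (2, 1)), np.tile(Y, 2), np.tile(Z, (2, 1))
        forms2 = dense_forms(X2, Y2, Z2)
        beta2, _ = est.gls_update(forms2, D, [2], [1])
        V2 = np.eye(20) + Z2 @ assemble_full_D(D, [2]) @ Z2.T
        Vi2 = np.linalg.inv(V2)
        bd = np.linalg.solve(X2.T @ Vi2 @ X2, X2.T @ Vi2 @ Y2)
        assert np.allclose(beta2, bd, atol=1e-10)
        b_ols1, _ = est.gls_update(inst["forms"], [np.zeros((1, 1))],
                                   [2], [1])
        b_ols2, _ = est.gls_update(forms2, [np.zeros((1, 1))], [2], [1])
        assert np.allclose(b_ols1, b_ols2, atol=1e-10)


class TestScoreAndFisher:
    def test_scalar_fisher_formula(self):
        inst = make_single_voxel(9, 18, [3], [1])
        D = [np.array([[0.7]])]
        X, Z = inst["X"], inst["Z"]
        V = np.eye(18) + Z @ assemble_full_D(D, [3]) @ Z.T
        Vi = np.linalg.inv(V)
        expected = 0.0
        for i in range(3):
            for j in range(3):
                expected += float(Z[:, i] @ Vi @ Z[:, j]) ** 2
        F = est.fisher_info_block(inst["forms"], D, [3], [1], 0)
        assert F[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_fisher_matches_dense_kronecker_sum(self):
        inst = make_single_voxel(10, 24, [4], [2])
        D = [np.array([[0.9, 0.2], [0.2, 0.6]])]
        X, Z = inst["X"], inst["Z"]
        V = np.eye(24) + Z @ assemble_full_D(D, [4]) @ Z.T
        Vi = np.linalg.inv(V)
        Fd = np.zeros((4, 4))
        for i in range(4):
            Zi = Z[:, 2 * i:2 * i + 2]
            for j in range(4):
                Zj = Z[:, 2 * j:2 * j + 2]
                Fd += np.kron(Zi.T @ Vi @ Zj, Zi.T @ Vi @ Zj)
        F = est.fisher_info_block(inst["forms"], D, [4], [2], 0)
        assert np.allclose(F, Fd, atol=1e-10 * abs(Fd).max())
        assert np.allclose(F, F.T, atol=1e-12 * abs(F).max())

    def test_score_matches_finite_differences(self):
        """The score is twice the gradient of the profiled restricted
        log-likelihood (the 1/2 cancels against the Fisher block)."""
        inst = make_single_voxel(11, 20, [4], [1])
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]

        def prof(d):
            D = assemble_full_D([[[d]]], [4])
            V = np.eye(20) + Z @ D @ Z.T
            Vi = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ Y)
            e = Y - X @ b
            s2 = e @ Vi @ e / (20 - 3)
            return dense_restricted_loglik(X, Y, Z, b, s2, [[[d]]], [4])

        d0 = 0.8
        h = 1e-6
        fd = (prof(d0 + h) - prof(d0 - h)) / (2 * h)
        beta, s2 = est.gls_update(inst["forms"], [np.array([[d0]])], [4], [1])
        sc = est.score_vector(inst["forms"], beta, s2, [np.array([[d0]])],
                              [4], [1], 0)
        assert sc[0] / 2 == pytest.approx(fd, rel=1e-5)

    def test_score_near_zero_at_oracle_optimum(self):
        inst = make_single_voxel(12, 60, [12], [1])
        orc = direct_reml(inst["X"], inst["Y"], inst["Z"], [12], [1])
        beta, s2 = est.gls_update(inst["forms"], orc.D_blocks, [12], [1])
        sc = est.score_vector(inst["forms"], beta, s2, orc.D_blocks,
                              [12], [1], 0)
        assert abs(sc[0]) <= 1e-5

    def test_scalar_score_hand_computation(self):
        """q_k=1, D=0, beta at OLS: the score reduces to a sum computable
        with elementary matrix algebra."""
        inst = make_single_voxel(13, 6, [2], [1], p=2)
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        e = Y - X @ beta
        s2 = float(e @ e) / (6 - 2)
        A = np.linalg.inv(X.T @ X)
        hand = 0.0
        for j in range(2):
            zj = Z[:, j]
            hand += (zj @ e) ** 2 / s2 - zj @ zj \
                + (zj @ X) @ A @ (X.T @ zj)
        sc = est.score_vector(inst["forms"], beta, s2,
                              [np.zeros((1, 1))], [2], [1], 0)
        assert sc[0] == pytest.approx(hand, rel=1e-10)


class TestNndProjection:
    def test_clipping_example(self):
        got = est.project_nnd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert np.allclose(got, [[1.5, 1.5], [1.5, 1.5]], atol=1e-12)

    def test_nnd_input_unchanged(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert np.allclose(est.project_nnd(A), A, atol=1e-14)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        A = A + A.T
        once = est.project_nnd(A)
        twice = est.project_nnd(once)
        assert np.allclose(once, twice, atol=1e-12)
        assert np.linalg.eigvalsh(once).min() >= -1e-12


def _interior(D_blocks, eps=1e-3):
    return all(np.linalg.eigvalsh(D).min() > eps for D in D_blocks)


class TestFsfsOracleEquivalence:
    """Estimates agree with direct dense REML maximisation whenever both
    land in the interior of the parameter space."""

    @pytest.mark.parametrize("family,n,lks,qks,n_inst", [
        ("one-factor/one-effect", 60, [20], [1], 50),
        ("one-factor/two-effects", 80, [10], [2], 50),
        ("two-factor", 120, [8, 5], [2, 1], 50),
    ])
    def test_small_instance_suite(self, family, n, lks, qks, n_inst):
        cfg = FsfsConfig(tol=1e-10)
        checked = 0
        for s in range(n_inst):
            inst = make_single_voxel(1000 + s, n, lks, qks)
            fit = fsfs_fit(inst["forms"], lks, qks, cfg)
            orc = direct_reml(inst["X"], inst["Y"], inst["Z"], lks, qks)
            if not (fit.converged and orc.success):
                continue
            if not (_interior(fit.D_blocks) and _interior(orc.D_blocks)):
                continue
            checked += 1
            for Df, Do in zip(fit.D_blocks, orc.D_blocks):
                assert np.abs(Df - Do).max() <= 1e-4, family
            assert np.abs(fit.beta - orc.beta).max() <= 1e-4
            assert fit.loglik == pytest.approx(orc.loglik, abs=1e-6)
        assert checked >= n_inst // 3  # boundary cases are excluded

    def test_design1_toy_tight_agreement(self):
        inst = make_single_voxel(55, 60, [20], [1])
        fit = fsfs_fit(inst["forms"], [20], [1], FsfsConfig(tol=1e-10))
        orc = direct_reml(inst["X"], inst["Y"], inst["Z"], [20], [1])
        assert np.abs(fit.D_blocks[0] - orc.D_blocks[0]).max() <= 1e-5
        assert np.abs(fit.beta - orc.beta).max() <= 1e-5

    def test_null_data_lands_on_boundary(self):
        """Data generated with D = 0: the estimate is non-negative, near
        zero, and never beats the oracle by more than round-off."""
        for s in range(5):
            inst = make_single_voxel(300 + s, 150, [15], [1],
                                     d_diag=0.0, d_offdiag=0.0)
            fit = fsfs_fit(inst["forms"], [15], [1], FsfsConfig(tol=1e-10))
            orc = direct_reml(inst["X"], inst["Y"], inst["Z"], [15], [1])
            assert fit.D_blocks[0][0, 0] >= 0.0
            assert fit.D_blocks[0][0, 0] < 0.5
            assert fit.loglik >= orc.loglik - 1e-6 \
                or fit.loglik == pytest.approx(orc.loglik, abs=1e-6)

    def test_iteration_counts_within_typical_range(self):
        iters = []
        for s in range(10):
            inst = make_single_voxel(400 + s, 60, [20], [1])
            fit = fsfs_fit(inst["forms"], [20], [1], FsfsConfig())
            assert fit.converged
            iters.append(fit.n_iter)
        assert np.median(iters) <= 30


class TestVectorisedFit:
    def test_vectorised_equals_looped(self):
        base = make_single_voxel(60, 30, [6], [1])
        rng = np.random.default_rng(61)
        X, Z = base["X"], base["Z"]
        forms_list = []
        for _ in range(50):
            b = rng.normal(size=6)
            Y = X @ base["beta"] + Z @ b + rng.normal(size=30)
            forms_list.append(dense_forms(X, Y, Z))
        batch = stack_forms(forms_list)
        cfg = FsfsConfig(tol=1e-10)
        res = fsfs_fit_vectorised(batch, [6], [1], cfg)
        for v in range(50):
            single = fsfs_fit(forms_list[v], [6], [1], cfg)
            assert np.abs(res.beta[v] - single.beta).max() <= 1e-10
            assert abs(res.sigma2[v] - single.sigma2) <= 1e-10
            assert np.abs(res.D_vec[v, 0]
                          - single.D_blocks[0][0, 0]) <= 1e-10

    def test_identical_voxels_identical_output(self):
        inst = make_single_voxel(62, 24, [4], [1])
        batch = stack_forms([inst["forms"]] * 5)
        res = fsfs_fit_vectorised(batch, [4], [1], FsfsConfig())
        assert np.ptp(res.D_vec, axis=0).max() == 0.0
        assert np.ptp(res.beta, axis=0).max() == 0.0

    def test_bad_voxel_is_isolated(self):
        """A voxel with a deficient design is flagged; the rest of the
        batch fits normally."""
        inst = make_single_voxel(63, 24, [4], [1])
        bad = ProductForms(P=np.zeros_like(inst["forms"].P),
                           Q=np.zeros_like(inst["forms"].Q),
                           R=np.zeros_like(inst["forms"].R), S=0.0,
                           T=np.zeros_like(inst["forms"].T),
                           U=np.zeros_like(inst["forms"].U), n_obs=0)
        batch = stack_forms([inst["forms"], bad, inst["forms"]])
        res = fsfs_fit_vectorised(batch, [4], [1], FsfsConfig())
        assert res.flagged[1]
        assert res.converged[0] and res.converged[2]
        assert np.allclose(res.beta[0], res.beta[2])

    def test_monotone_accepted_loglik(self):
        """Accepted restricted log-likelihoods never decrease beyond
        evaluation noise (step halving enforces monotonicity)."""
        base = make_single_voxel(64, 40, [8], [1])
        rng = np.random.default_rng(65)
        forms_list = []
        for _ in range(20):
            b = rng.normal(size=8)
            Y = base["X"] @ base["beta"] + base["Z"] @ b \
                + rng.normal(size=40)
            forms_list.append(dense_forms(base["X"], Y, base["Z"]))
        batch = stack_forms(forms_list)
        res = fsfs_fit_vectorised(batch, [8], [1],
                                  FsfsConfig(track_history=True))
        hist = np.asarray(res.history)
        diffs = np.diff(hist, axis=0)
        noise = 1e-8 * (1.0 + np.abs(hist[:-1]))
        assert np.all(diffs >= -noise)

    def test_scale_equivariance(self):
        """Y -> cY scales beta by c, sigma^2 by c^2, leaves D unchanged."""
        inst = make_single_voxel(66, 30, [6], [1])
        X, Y, Z = inst["X"], inst["Y"], inst["Z"]
        c = 3.7
        cfg = FsfsConfig(tol=1e-12)
        f1 = fsfs_fit(dense_forms(X, Y, Z), [6], [1], cfg)
        f2 = fsfs_fit(dense_forms(X, c * Y, Z), [6], [1], cfg)
        assert np.allclose(f2.beta, c * f1.beta, rtol=1e-6)
        assert f2.sigma2 == pytest.approx(c * c * f1.sigma2, rel=1e-6)
        assert np.allclose(f2.D_blocks[0], f1.D_blocks[0], atol=1e-6)

    def test_fast_path_matches_general_path(self):
        for lks, qks, seed in ([[6], [1], 70], [[5], [2], 71]):
            inst = make_single_voxel(seed, 40, lks, qks)
            batch = forms_as_set(inst["forms"])
            f_fast = fsfs_fit_vectorised(batch, lks, qks,
                                         FsfsConfig(use_fast_path=True))
            f_gen = fsfs_fit_vectorised(batch, lks, qks,
                                        FsfsConfig(use_fast_path=False))
            assert np.abs(f_fast.D_vec - f_gen.D_vec).max() <= 1e-10
            assert np.abs(f_fast.beta - f_gen.beta).max() <= 1e-10
            assert np.abs(f_fast.loglik - f_gen.loglik).max() <= 1e-8

    def test_r_zero_is_ols(self):
        inst = make_single_voxel(72, 25, [], [], p=3)
        batch = forms_as_set(inst["forms"])
        res = fsfs_fit_vectorised(batch, [], [], FsfsConfig())
        ols = np.linalg.solve(inst["forms"].P, inst["forms"].Q)
        assert np.allclose(res.beta[0], ols, atol=1e-10)
        rss = float((inst["Y"] - inst["X"] @ ols)
                    @ (inst["Y"] - inst["X"] @ ols))
        assert res.sigma2[0] == pytest.approx(rss / (25 - 3), rel=1e-10)
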