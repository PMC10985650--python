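"""Wald and likelihood-ratio inference on the fitted mixed model.

For a contrast L over the fixed effects, the Wald statistics are

    T = L beta_hat / sqrt(sigma2_hat L (X'V_hat^-1 X)^-1 L')
    F = (L beta_hat)' [L (X'V_hat^-1 X)^-1 L']^-1 (L beta_hat)
        / (sigma2_hat rank(L)),        V_hat = I + Z D_hat Z',

evaluated entirely in product forms.  Their reference t/F distributions are
approximate, with degrees of freedom estimated by the Welch-Satterthwaite
moment match  v = 2 (S^2)^2 / Var(S^2),  S^2 = sigma2 L (X'V^-1 X)^-1 L',
where Var(S^2) is a delta-method quadratic form: the closed-form gradient of
S^2 in the variance parameters eta = (sigma^2, vec(D_1), ..., vec(D_r)),
against the inverse expected (REML) information of eta.  The information is
assembled from the projected cross products Z'PZ with
P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1:

    I[s2, s2]        = (n_v - p) / (2 sigma^4)
    I[s2, vec(D_k)]  = (1 / 2 sigma^2) sum_j vec((Z'PZ)_jj)
    I[vec D_k, vec D_k'] = 1/2 sum_{i,j} (Z'PZ)_ij (x) (Z'PZ)_ij

(level-block sums; everything computable from P, Q, R, T, U and theta_hat).

Random-effect inclusion is tested by a restricted-likelihood ratio between
nested single-factor models; because the null lies on the boundary of the
parameter space the statistic is referred to an even 50/50 mixture of
chi-square distributions chi2_{q - q~} and chi2_q (chi2_0 a point mass
at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimation import FitResultBatch, _GeneralKernel, _gather_voxel_arrays, \
    FsfsConfig, _pack_blocks
from .product_forms import ProductFormSet

__all__ = [
    "ContrastSpec",
    "WaldResult",
    "LRTResult",
    "wald_T",
    "wald_F",
    "satterthwaite_df",
    "p_values",
    "multiple_testing",
    "likelihood_ratio_test",
]


@dataclass
class ContrastSpec:
    """Contrast matrix plus statistic kind ('T': single row, 'F': any rank)."""

    L: np.ndarray
    kind: str = "T"

    def __post_init__(self):
        L = np.atleast_2d(np.asarray(self.L, dtype=np.float64))
        if self.kind not in ("T", "F"):
            raise ValueError("contrast kind must be 'T' or 'F'")
        if self.kind == "T" and L.shape[0] != 1:
            raise ValueError("T contrasts must be a single row")
        if np.linalg.matrix_rank(L) < L.shape[0]:
            raise ValueError("contrast matrix must have full row rank")
        self.L = L

    @property
    def rank(self) -> int:
        return self.L.shape[0]


@dataclass
class WaldResult:
    statistic: np.ndarray      # (V,)
    df: np.ndarray             # (V,) denominator df estimate
    p: np.ndarray              # (V,)
    rank: int = 1              # numerator df (rank of L); 1 for T
    kind: str = "T"


@dataclass
class LRTResult:
    statistic: np.ndarray
    df_pair: tuple[int, int]
    p: np.ndarray
    n_clipped: int = 0
    flagged: np.ndarray | None = None


# ---------------------------------------------------------------------------
# internal: marginal quantities and the variance-parameter information
# ---------------------------------------------------------------------------

def _inference_kernel(forms: ProductFormSet, fit: FitResultBatch,
                      level_counts, effect_counts,
                      voxels: np.ndarray | None):
    if voxels is None:
        voxels = np.arange(forms.n_voxels)
    voxels = np.asarray(voxels, dtype=np.int64)
    arrays = _gather_voxel_arrays(forms, voxels, level_counts, effect_counts,
                                  fast=False)
    kern = _GeneralKernel(arrays, level_counts, effect_counts, FsfsConfig())
    marg = kern.marginal(fit.D_vec)
    A = np.linalg.inv(marg["XtViX"])
    return kern, marg, A


def _projected_G(kern, marg, A):
    """Z'PZ: V^-1 cross products with the fixed-effects projection removed."""
    ZtViX = marg["ZtViX"]                       # (V, q, p)
    corr = ZtViX @ A @ np.swapaxes(ZtViX, 1, 2)
    return marg["G"] - corr


def variance_information(kern, marg, sigma2, A) -> np.ndarray:
    """Expected REML information of eta = (sigma^2, vec(D_1), ..., vec(D_r))."""
    V = kern.V
    ZPZ = _projected_G(kern, marg, A)
    dims = [1] + [qk * qk for qk in kern.effect_counts]
    dtot = sum(dims)
    info = np.zeros((V, dtot, dtot))
    info[:, 0, 0] = (kern.nv - kern.p) / (2.0 * sigma2 ** 2)

    offs = np.cumsum([1] + [qk * qk for qk in kern.effect_counts])[:-1]
    diag_blocks = []
    for k, (lk, qk) in enumerate(zip(kern.level_counts, kern.effect_counts)):
        s = kern.slices[k]
        G5 = ZPZ[:, s, s.start:s.stop].reshape(V, lk, qk, lk, qk)
        Bjj = np.einsum("vjajb->vjab", G5)
        diag_blocks.append(Bjj)
        cross = Bjj.sum(axis=1).reshape(V, qk * qk) / (2.0 * sigma2[:, None])
        info[:, 0, offs[k]:offs[k] + qk * qk] = cross
        info[:, offs[k]:offs[k] + qk * qk, 0] = cross
    for k, (lk, qk) in enumerate(zip(kern.level_counts, kern.effect_counts)):
        sk = kern.slices[k]
        for k2 in range(k, len(kern.level_counts)):
            lk2, qk2 = kern.level_counts[k2], kern.effect_counts[k2]
            s2 = kern.slices[k2]
            G5 = ZPZ[:, sk, s2.start:s2.stop].reshape(V, lk, qk, lk2, qk2)
            B = np.ascontiguousarray(G5.transpose(0, 1, 3, 2, 4))
            Fkk = 0.5 * np.einsum("vijac,vijbd->vabcd", B, B).reshape(
                V, qk * qk, qk2 * qk2)
            info[:, offs[k]:offs[k] + qk * qk,
                 offs[k2]:offs[k2] + qk2 * qk2] = Fkk
            if k2 != k:
                info[:, offs[k2]:offs[k2] + qk2 * qk2,
                     offs[k]:offs[k] + qk * qk] = \
                    np.swapaxes(Fkk, 1, 2)
    return info


def _ws_gradient(kern, marg, A, sigma2, L) -> tuple[np.ndarray, np.ndarray]:
    """(S^2, dS^2/d eta) for a single-row contrast L, per voxel."""
    V = kern.V
    LA = np.einsum("p,vpq->vq", L.ravel(), A)            # L A
    LAL = np.einsum("vq,q->v", LA, L.ravel())            # L A L'
    S2 = sigma2 * LAL
    dims = 1 + sum(qk * qk for qk in kern.effect_counts)
    grad = np.zeros((V, dims))
    grad[:, 0] = LAL
    # a = L A X'V^-1 Z  (row per voxel)
    a = np.einsum("vp,vqp->vq", LA, marg["ZtViX"])
    offs = np.cumsum([1] + [qk * qk for qk in kern.effect_counts])[:-1]
    for k, (lk, qk) in enumerate(zip(kern.level_counts, kern.effect_counts)):
        s = kern.slices[k]
        ak = a[:, s].reshape(V, lk, qk)
        dk = sigma2[:, None, None] * np.einsum("vja,vjb->vab", ak, ak)
        grad[:, offs[k]:offs[k] + qk * qk] = dk.reshape(V, qk * qk)
    return S2, grad


def satterthwaite_df(fit: FitResultBatch, forms: ProductFormSet, L,
                     level_counts, effect_counts,
                     voxels: np.ndarray | None = None) -> np.ndarray:
    """Welch-Satterthwaite denominator df for a single-row contrast.

    In the no-random-effects limit this reduces analytically to n_v - p.
    Voxels with a non-invertible information matrix get NaN.
    """
    L = np.atleast_2d(np.asarray(L, dtype=np.float64))
    kern, marg, A = _inference_kernel(forms, fit, level_counts,
                                      effect_counts, voxels)
    sigma2 = fit.sigma2  # fit must be aligned with the voxel selection
    if len(level_counts) == 0:
        return kern.nv - kern.p
    info = variance_information(kern, marg, sigma2, A)
    S2, grad = _ws_gradient(kern, marg, A, sigma2, L)
    try:
        sol = np.linalg.solve(info, grad[..., None])[..., 0]
    except np.linalg.LinAlgError:
        sol = np.full_like(grad, np.nan)
        for v in range(info.shape[0]):
            try:
                sol[v] = np.linalg.solve(info[v], grad[v])
            except np.linalg.LinAlgError:
                pass
    var_S2 = np.einsum("vd,vd->v", grad, sol)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * S2 ** 2 / var_S2
    df = np.where(np.isfinite(df) & (df > 0), df, np.nan)
    return df


def wald_T(fit: FitResultBatch, forms: ProductFormSet, L,
           level_counts, effect_counts,
           voxels: np.ndarray | None = None,
           two_sided: bool = True) -> WaldResult:
    """Wald T statistic, Welch-Satterthwaite df and p-value per voxel."""
    L = np.atleast_2d(np.asarray(L, dtype=np.float64))
    if L.shape[0] != 1:
        raise ValueError("wald_T needs a single-row contrast")
    kern, marg, A = _inference_kernel(forms, fit, level_counts,
                                      effect_counts, voxels)
    Lb = np.einsum("p,vp->v", L.ravel(), fit.beta)
    LAL = np.einsum("p,vpq,q->v", L.ravel(), A, L.ravel())
    var = fit.sigma2 * LAL
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, Lb / np.sqrt(var), np.nan)
    if len(level_counts) == 0:
        df = kern.nv - kern.p
    else:
        df = satterthwaite_df(fit, forms, L, level_counts, effect_counts,
                              voxels)
    p = p_values(stat, df, kind="T", rank=1, two_sided=two_sided)
    return WaldResult(statistic=stat, df=df, p=p, rank=1, kind="T")


def wald_F(fit: FitResultBatch, forms: ProductFormSet, L,
           level_counts, effect_counts,
           voxels: np.ndarray | None = None) -> WaldResult:
    """Wald F statistic with moment-combined Welch-Satterthwaite ddf.

    The denominator df combines per-direction WS estimates over the
    eigen-directions of L (X'V^-1 X)^-1 L', the standard multi-row
    extension of the scalar moment match.  For rank-1 L, F = T^2 and the
    df equals the T df.
    """
    L = np.atleast_2d(np.asarray(L, dtype=np.float64))
    rank = L.shape[0]
    kern, marg, A = _inference_kernel(forms, fit, level_counts,
                                      effect_counts, voxels)
    Lb = np.einsum("rp,vp->vr", L, fit.beta)
    M = np.einsum("rp,vpq,sq->vrs", L, A, L)       # L A L'
    try:
        sol = np.linalg.solve(M, Lb[..., None])[..., 0]
    except np.linalg.LinAlgError:
        sol = np.full_like(Lb, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.einsum("vr,vr->v", Lb, sol) / (fit.sigma2 * rank)
    stat = np.where(np.isfinite(stat), stat, np.nan)

    if len(level_counts) == 0:
        df = kern.nv - kern.p
    elif rank == 1:
        df = satterthwaite_df(fit, forms, L, level_counts, effect_counts,
                              voxels)
    else:
        # per-eigendirection df, combined by moment matching
        w, vecs = np.linalg.eigh(M)
        V = stat.shape[0]
        nus = np.empty((V, rank))
        for r_i in range(rank):
            # direction r_i of the contrast space, voxel-wise rotation is
            # close to constant; use the leading voxel's rotation for the
            # direction definition, per-voxel df estimation
            Lr = vecs[:, :, r_i]
            # build per-voxel single-row contrast u' L
            nu_r = np.empty(V)
            Lrow = np.einsum("vr,rp->vp", Lr, L)
            for v in range(V):
                nu_r[v] = satterthwaite_df(
                    _subset_fit(fit, v), _subset_forms(forms, v,
                                                       fit, voxels),
                    Lrow[v], level_counts, effect_counts)[0]
            nus[:, r_i] = nu_r
        with np.errstate(invalid="ignore", divide="ignore"):
            E = np.nansum(np.where(nus > 2, nus / (nus - 2), np.nan), axis=1)
            df = np.where(E > rank, 2 * E / (E - rank), np.nan)
    p = p_values(stat, df, kind="F", rank=rank)
    return WaldResult(statistic=stat, df=df, p=p, rank=rank, kind="F")


def _subset_fit(fit: FitResultBatch, v: int) -> FitResultBatch:
    return FitResultBatch(
        beta=fit.beta[v:v + 1], sigma2=fit.sigma2[v:v + 1],
        D_vec=fit.D_vec[v:v + 1], loglik=fit.loglik[v:v + 1],
        n_iter=fit.n_iter[v:v + 1], converged=fit.converged[v:v + 1],
        flagged=fit.flagged[v:v + 1],
        level_counts=fit.level_counts, effect_counts=fit.effect_counts)


def _subset_forms(forms: ProductFormSet, v: int, fit, voxels) -> ProductFormSet:
    vi = v if voxels is None else int(np.asarray(voxels)[v])
    pf = forms.voxel(vi)
    return ProductFormSet(
        P=pf.P[None], R=pf.R[None], U=pf.U[None], Q=pf.Q[None],
        S=np.atleast_1d(pf.S), T=pf.T[None],
        group_index=np.zeros(1, dtype=np.int64),
        n_obs=np.atleast_1d(np.int64(pf.n_obs)))


def p_values(stat: np.ndarray, df: np.ndarray, kind: str = "T",
             rank: int = 1, two_sided: bool = True) -> np.ndarray:
    """t / F tail probabilities; NaN statistics or df propagate to NaN."""
    stat = np.asarray(stat, dtype=np.float64)
    df = np.broadcast_to(np.asarray(df, dtype=np.float64), stat.shape)
    p = np.full(stat.shape, np.nan)
    ok = np.isfinite(stat) & np.isfinite(df) & (df > 0)
    if kind == "T":
        if two_sided:
            p[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df[ok])
        else:
            p[ok] = stats.t.sf(stat[ok], df[ok])
    elif kind == "F":
        p[ok] = stats.f.sf(stat[ok], rank, df[ok])
    else:
        raise ValueError("kind must be 'T' or 'F'")
    return np.clip(p, 0.0, 1.0)


def multiple_testing(p: np.ndarray, method: str = "bonferroni",
                     alpha: float = 0.05):
    """Family-wise (Bonferroni) or FDR (Benjamini-Hochberg) correction.

    Returns (significance mask, adjusted p-values) over the supplied map;
    NaN entries (flagged voxels) are never declared significant.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("empty p-value map")
    ok = np.isfinite(p)
    reject = np.zeros(p.shape, dtype=bool)
    adj = np.full(p.shape, np.nan)
    if ok.any():
        sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh",
                     "BH": "fdr_bh", "fdr": "fdr_bh"}.get(method)
        if sm_method is None:
            raise ValueError(f"unknown correction method: {method}")
        rej, p_adj, _, _ = multipletests(p[ok], alpha=alpha,
                                         method=sm_method)
        reject[ok] = rej
        adj[ok] = p_adj
    return reject, adj


def _mixture_sf(x: np.ndarray, a: int, b: int) -> np.ndarray:
    """Survival function of the even chi2_a / chi2_b mixture.

    chi2_0 is a point mass at zero; P(X > x) uses the closed-lower-tail
    convention P(X >= 0) = 1, so x = 0 maps to p = 1 for any df pair.
    """
    x = np.asarray(x, dtype=np.float64)

    def comp(df):
        out = np.ones_like(x)
        pos = x > 0
        if df == 0:
            out[pos] = 0.0
        else:
            out[pos] = stats.chi2.sf(x[pos], df)
        return out

    return 0.5 * comp(a) + 0.5 * comp(b)


def likelihood_ratio_test(loglik_null: np.ndarray, loglik_full: np.ndarray,
                          q: int, q_tilde: int,
                          n_factors: int = 1) -> LRTResult:
    """Mixture-chi-square LRT for dropping q~ random effects (single factor).

    The statistic 2 (l_full - l_null) is clipped at zero (boundary null);
    voxels with a deficit beyond -1e-6 are flagged (non-nested fits or
    convergence failure) and get NaN p-values.  Only single-random-factor
    model pairs are supported: the even two-component mixture reference
    does not describe the boundary null of crossed multi-factor designs.
    """
    if n_factors != 1:
        raise ValueError(
            "the mixture chi-square reference applies to comparisons of "
            "models with a single random factor; multi-factor comparisons "
            "need a different boundary-null distribution")
    ln = np.asarray(loglik_null, dtype=np.float64)
    lf = np.asarray(loglik_full, dtype=np.float64)
    if not 0 < q_tilde <= q:
        raise ValueError("need 0 < q_tilde <= q (q~ effects removed)")
    raw = 2.0 * (lf - ln)
    flagged = ~np.isfinite(raw) | (raw < -1e-6)
    n_clipped = int(np.sum((raw < 0) & ~flagged))
    stat = np.clip(raw, 0.0, None)
    a, b = q - q_tilde, q
    p = _mixture_sf(stat, a, b)
    p[flagged] = np.nan
    stat = np.where(flagged, np.nan, stat)
    return LRTResult(statistic=stat, df_pair=(a, b), p=p,
                     n_clipped=n_clipped, flagged=flagged)
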