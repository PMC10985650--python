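"""Per-voxel REML estimation by Full Simplified Fisher Scoring (FSFS).

Everything here is expressed in the product forms (P, Q, R, S, T, U): with
V = I + ZDZ' the Woodbury identity and the matrix determinant lemma give

    X'V^-1 X = P - R D (I_q + U D)^-1 R'
    X'V^-1 Y = Q - R D (I_q + U D)^-1 T'
    Y'V^-1 Y = S - T D (I_q + U D)^-1 T'
    Z'V^-1 Z = (I_q + U D)^-1 U
    Z'V^-1 X = (I_q + U D)^-1 R'
    log|V|   = log|I_q + U D|

so no quantity of size n is ever touched.  Each FSFS iteration performs a
GLS update of (beta, sigma^2) followed by one Fisher-scoring step on the
full vectorisation vec(D_k) of each factor's covariance block,

    vec(D_k) <- vec(D_k) + alpha * (F^k)^-1 d^k,

with F^k = sum_{i,j} B_ij (x) B_ij (B_ij the level blocks of Z'V^-1 Z) and
score d^k = sum_j vec(sigma^-2 t_j t_j' - B_jj + C_jj), where
t_j = Z_j'V^-1 e and C_jj the level blocks of
Z'V^-1 X (X'V^-1 X)^-1 X'V^-1 Z.  (The common factor 1/2 of the true
gradient and information cancels in the product (F^k)^-1 d^k; the
sigma^-2 standardisation of the residual term is required for the fixed
point to be the REML maximiser.)  After every step D_k is projected onto
the non-negative definite cone by eigenvalue clipping; the step size is
halved whenever the restricted log-likelihood would decrease, so accepted
iterations are monotone.

For single-factor models (r = 1) Z'Z is block-diagonal across levels, so
all q x q operations collapse to per-level q_k x q_k operations; this fast
path returns results identical (to ~1e-12) to the general path and is
selected automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .product_forms import ProductForms, ProductFormSet

__all__ = [
    "FsfsConfig",
    "ThetaEstimate",
    "FitResultBatch",
    "project_nnd",
    "reml_criterion",
    "gls_update",
    "fisher_info_block",
    "score_vector",
    "fsfs_fit",
    "fsfs_fit_vectorised",
]

_D_FLOOR = 1e-6  # floor for the moment-based initial D_k scale


@dataclass
class FsfsConfig:
    """Optimiser settings.

    tol:
        convergence tolerance on the absolute change in restricted
        log-likelihood between accepted iterations (default 1e-6).
    max_iter:
        iteration cap; exceeding it flags the voxel non-converged
        (default 1e4).
    variance_scale:
        denominator of the GLS variance update: ``"reml"`` uses n_v - p
        (the maximiser of the restricted likelihood, the default) and
        ``"ml"`` uses n_v.
    max_halvings:
        step-size halvings allowed per iteration before the covariance
        update is skipped.
    use_fast_path:
        None = auto (single-factor designs take the block-diagonal path);
        True/False force it.
    track_history:
        record the accepted restricted log-likelihood after every outer
        iteration (diagnostics / monotonicity checks).
    """

    tol: float = 1e-6
    max_iter: int = 10_000
    safe_mode: bool = True
    voxel_batch_size: int | None = None
    variance_scale: str = "reml"
    max_halvings: int = 20
    use_fast_path: bool | None = None
    track_history: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.variance_scale not in ("reml", "ml"):
            raise ValueError("variance_scale must be 'reml' or 'ml'")


@dataclass
class ThetaEstimate:
    """REML estimate for a single voxel."""

    beta: np.ndarray
    sigma2: float
    D_blocks: list[np.ndarray]
    loglik: float
    n_iter: int
    converged: bool
    flagged: bool = False


@dataclass
class FitResultBatch:
    """REML estimates for a batch of voxels (arrays over the voxel axis)."""

    beta: np.ndarray          # (V, p)
    sigma2: np.ndarray        # (V,)
    D_vec: np.ndarray         # (V, sum_k q_k^2), row-major vec per factor
    loglik: np.ndarray        # (V,)
    n_iter: np.ndarray        # (V,)
    converged: np.ndarray     # (V,) bool
    flagged: np.ndarray       # (V,) bool
    level_counts: list[int] = field(default_factory=list)
    effect_counts: list[int] = field(default_factory=list)
    history: list | None = None  # accepted llh per iteration, if tracked

    def D_block(self, k: int) -> np.ndarray:
        """(V, q_k, q_k) estimated within-level covariance of factor k."""
        off = sum(qk * qk for qk in self.effect_counts[:k])
        qk = self.effect_counts[k]
        return self.D_vec[:, off : off + qk * qk].reshape(-1, qk, qk)

    def theta(self, v: int) -> ThetaEstimate:
        return ThetaEstimate(
            beta=self.beta[v].copy(),
            sigma2=float(self.sigma2[v]),
            D_blocks=[self.D_block(k)[v].copy()
                      for k in range(len(self.effect_counts))],
            loglik=float(self.loglik[v]),
            n_iter=int(self.n_iter[v]),
            converged=bool(self.converged[v]),
            flagged=bool(self.flagged[v]),
        )


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def project_nnd(M: np.ndarray) -> np.ndarray:
    """Nearest non-negative definite matrix: symmetrise, clip eigenvalues.

    Accepts a single (q, q) matrix or a stack (..., q, q).  Idempotent on
    the feasible set.
    """
    M = np.asarray(M, dtype=np.float64)
    sym = 0.5 * (M + np.swapaxes(M, -1, -2))
    if sym.shape[-1] == 1:
        return np.maximum(sym, 0.0)
    w, v = np.linalg.eigh(sym)
    w = np.maximum(w, 0.0)
    out = (v * w[..., None, :]) @ np.swapaxes(v, -1, -2)
    return 0.5 * (out + np.swapaxes(out, -1, -2))


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve symmetric positive-definite stacked systems with jitter retry.

    One retry adds 1e-10 * trace jitter to the diagonal; a second failure
    propagates (callers translate that into per-voxel flags).
    """
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pass
    tr = np.einsum("...ii->...", A)
    jitter = 1e-10 * tr[..., None, None] * np.eye(A.shape[-1])
    try:
        return np.linalg.solve(A + jitter, b)
    except np.linalg.LinAlgError:
        # isolate the failing systems: NaN-fill them, keep the batch alive
        A2 = (A + jitter).reshape(-1, A.shape[-2], A.shape[-1])
        b2 = np.broadcast_to(b, A.shape[:-2] + b.shape[-2:]).reshape(
            -1, b.shape[-2], b.shape[-1])
        out = np.full(b2.shape, np.nan)
        for i in range(A2.shape[0]):
            try:
                out[i] = np.linalg.solve(A2[i], b2[i])
            except np.linalg.LinAlgError:
                pass
        return out.reshape(A.shape[:-2] + b.shape[-2:])


def _pack_blocks(blocks: list[np.ndarray], V: int,
                 effect_counts: list[int]) -> np.ndarray:
    """Stack per-factor (V, qk, qk) blocks into (V, sum qk^2) rows."""
    parts = [np.broadcast_to(b, (V, qk, qk)).reshape(V, qk * qk)
             for b, qk in zip(blocks, effect_counts)]
    if not parts:
        return np.zeros((V, 0))
    return np.concatenate(parts, axis=1)


def _unpack_block(D_vec: np.ndarray, k: int, effect_counts: list[int]):
    off = sum(qk * qk for qk in effect_counts[:k])
    qk = effect_counts[k]
    return D_vec[:, off : off + qk * qk].reshape(-1, qk, qk)


# ---------------------------------------------------------------------------
# computation kernels: general (dense q) and single-factor (block diagonal)
# ---------------------------------------------------------------------------

class _GeneralKernel:
    """Dense-in-q product-form evaluation for arbitrary factor structures."""

    fast = False

    def __init__(self, arrays: dict, level_counts, effect_counts, config):
        self.P = arrays["P"]
        self.Q = arrays["Q"]
        self.R = arrays["R"]
        self.S = arrays["S"]
        self.T = arrays["T"]
        self.U = arrays["U"]
        self.nv = arrays["n_obs"].astype(np.float64)
        self.level_counts = list(level_counts)
        self.effect_counts = list(effect_counts)
        self.config = config
        self.V = self.Q.shape[0]
        self.p = self.Q.shape[1]
        self.q = self.T.shape[1]
        self.slices = []
        start = 0
        for lk, qk in zip(self.level_counts, self.effect_counts):
            self.slices.append(slice(start, start + lk * qk))
            start += lk * qk

    def subset(self, idx):
        arrays = {"P": self.P[idx], "Q": self.Q[idx], "R": self.R[idx],
                  "S": self.S[idx], "T": self.T[idx], "U": self.U[idx],
                  "n_obs": self.nv[idx]}
        return _GeneralKernel(arrays, self.level_counts, self.effect_counts,
                              self.config)

    def assemble_D(self, D_vec: np.ndarray) -> np.ndarray:
        V = D_vec.shape[0]
        D = np.zeros((V, self.q, self.q))
        for k, (lk, qk) in enumerate(zip(self.level_counts,
                                         self.effect_counts)):
            Dk = _unpack_block(D_vec, k, self.effect_counts)
            s0 = self.slices[k].start
            for j in range(lk):
                a = s0 + j * qk
                D[:, a : a + qk, a : a + qk] = Dk
        return D

    def marginal(self, D_vec: np.ndarray) -> dict:
        """All V^-1-weighted cross products at covariance D."""
        D = self.assemble_D(D_vec)
        V, p, q = self.V, self.p, self.q
        A = np.eye(q)[None] + self.U @ D
        rhs = np.concatenate(
            [self.U, np.swapaxes(self.R, 1, 2), self.T[:, :, None]], axis=2)
        sol = np.linalg.solve(A, rhs)
        G = sol[:, :, :q]                       # Z'V^-1 Z
        ZtViX = sol[:, :, q : q + p]            # Z'V^-1 X
        ZtViY = sol[:, :, -1]                   # Z'V^-1 Y
        RD = self.R @ D
        XtViX = self.P - RD @ ZtViX
        XtViX = 0.5 * (XtViX + np.swapaxes(XtViX, 1, 2))
        XtViY = self.Q - np.einsum("vpa,va->vp", RD, ZtViY)
        TD = np.einsum("va,vab->vb", self.T, D)
        YtViY = self.S - np.einsum("va,va->v", TD, ZtViY)
        sign, logdetV = np.linalg.slogdet(A)
        logdetV = np.where(sign > 0, logdetV, np.nan)
        return {"G": G, "ZtViX": ZtViX, "ZtViY": ZtViY, "XtViX": XtViX,
                "XtViY": XtViY, "YtViY": YtViY, "logdetV": logdetV}

    def gls(self, marg: dict) -> dict:
        beta = _solve_spd(marg["XtViX"], marg["XtViY"][..., None])[..., 0]
        eVe = (marg["YtViY"] - 2.0 * np.einsum("vp,vp->v", beta, marg["XtViY"])
               + np.einsum("vp,vpq,vq->v", beta, marg["XtViX"], beta))
        eVe = np.maximum(eVe, 0.0)
        denom = self.nv - self.p if self.config.variance_scale == "reml" \
            else self.nv
        sigma2 = eVe / denom
        return {"beta": beta, "sigma2": sigma2, "eVe": eVe}

    def criterion(self, marg: dict, beta, sigma2, eVe=None) -> np.ndarray:
        if eVe is None:
            eVe = (marg["YtViY"]
                   - 2.0 * np.einsum("vp,vp->v", beta, marg["XtViY"])
                   + np.einsum("vp,vpq,vq->v", beta, marg["XtViX"], beta))
        sign, logdetXtViX = np.linalg.slogdet(marg["XtViX"])
        logdetXtViX = np.where(sign > 0, logdetXtViX, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = -0.5 * ((self.nv - self.p) * np.log(sigma2)
                          + eVe / sigma2 + marg["logdetV"] + logdetXtViX)
        return val

    def score_and_fisher(self, marg: dict, beta, sigma2):
        """Per-factor score vectors and Fisher blocks (full representation)."""
        Zt_e = marg["ZtViY"] - np.einsum("vqp,vp->vq", marg["ZtViX"], beta)
        AinvXtZ = _solve_spd(marg["XtViX"],
                             np.swapaxes(marg["ZtViX"], 1, 2))
        C = marg["ZtViX"] @ AinvXtZ               # Z'V^-1 X A^-1 X'V^-1 Z
        inv_s2 = 1.0 / sigma2
        scores, fishers = [], []
        for k, (lk, qk) in enumerate(zip(self.level_counts,
                                         self.effect_counts)):
            s = self.slices[k]
            t = Zt_e[:, s].reshape(-1, lk, qk)
            G5 = marg["G"][:, s, s.start:s.stop].reshape(-1, lk, qk, lk, qk)
            C5 = C[:, s, s.start:s.stop].reshape(-1, lk, qk, lk, qk)
            Gjj = np.einsum("vjajb->vjab", G5)
            Cjj = np.einsum("vjajb->vjab", C5)
            smat = (inv_s2[:, None, None] * np.einsum("vja,vjb->vab", t, t)
                    - Gjj.sum(axis=1) + Cjj.sum(axis=1))
            B = np.ascontiguousarray(G5.transpose(0, 1, 3, 2, 4))
            F = np.einsum("vijac,vijbd->vabcd", B, B)
            scores.append(smat.reshape(-1, qk * qk))
            fishers.append(F.reshape(-1, qk * qk, qk * qk))
        return scores, fishers


class _SingleFactorKernel:
    """Block-diagonal evaluation for r = 1: U = diag(U_1, ..., U_l).

    Every (I_q + UD) solve factors into l independent q_1 x q_1 solves, and
    the off-diagonal level blocks of Z'V^-1 Z vanish, which collapses the
    Fisher block to sum_j B_jj (x) B_jj.
    """

    fast = True

    def __init__(self, arrays: dict, level_counts, effect_counts, config):
        self.P = arrays["P"]          # (V, p, p)
        self.Q = arrays["Q"]          # (V, p)
        self.Rb = arrays["Rb"]        # (V, l, p, qk)
        self.S = arrays["S"]          # (V,)
        self.Tb = arrays["Tb"]        # (V, l, qk)
        self.Ub = arrays["Ub"]        # (V, l, qk, qk)
        self.nv = arrays["n_obs"].astype(np.float64)
        self.level_counts = list(level_counts)
        self.effect_counts = list(effect_counts)
        self.config = config
        self.V, self.p = self.Q.shape
        self.l = self.Ub.shape[1]
        self.qk = self.Ub.shape[2]

    def subset(self, idx):
        arrays = {"P": self.P[idx], "Q": self.Q[idx], "Rb": self.Rb[idx],
                  "S": self.S[idx], "Tb": self.Tb[idx], "Ub": self.Ub[idx],
                  "n_obs": self.nv[idx]}
        return _SingleFactorKernel(arrays, self.level_counts,
                                   self.effect_counts, self.config)

    @staticmethod
    def _inv_small(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inverse and log-determinant of stacked 1x1/2x2 (else LAPACK)."""
        qk = A.shape[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            if qk == 1:
                det = A[..., 0, 0]
                inv = np.where(det != 0, 1.0 / det, np.nan)[..., None, None]
                logdet = np.log(np.where(det > 0, det, np.nan))
            elif qk == 2:
                a, b = A[..., 0, 0], A[..., 0, 1]
                c, d = A[..., 1, 0], A[..., 1, 1]
                det = a * d - b * c
                inv = np.empty_like(A)
                idet = np.where(det != 0, 1.0 / det, np.nan)
                inv[..., 0, 0] = d * idet
                inv[..., 0, 1] = -b * idet
                inv[..., 1, 0] = -c * idet
                inv[..., 1, 1] = a * idet
                logdet = np.log(np.where(det > 0, det, np.nan))
            else:
                inv = np.linalg.inv(A)
                sign, logdet = np.linalg.slogdet(A)
                logdet = np.where(sign > 0, logdet, np.nan)
        return inv, logdet

    def marginal(self, D_vec: np.ndarray) -> dict:
        qk = self.qk
        Dk = D_vec.reshape(-1, qk, qk)
        A = np.eye(qk)[None, None] + self.Ub @ Dk[:, None]
        Kinv, logdet = self._inv_small(A)
        Gjj = Kinv @ self.Ub                                   # (V,l,qk,qk)
        ZtViXb = np.einsum("vjab,vjpb->vjap", Kinv, self.Rb)   # (V,l,qk,p)
        ZtViYb = np.einsum("vjab,vjb->vja", Kinv, self.Tb)     # (V,l,qk)
        RDb = np.einsum("vjpa,vab->vjpb", self.Rb, Dk)
        XtViX = self.P - np.einsum("vjpa,vjaq->vpq", RDb, ZtViXb)
        XtViX = 0.5 * (XtViX + np.swapaxes(XtViX, 1, 2))
        XtViY = self.Q - np.einsum("vjpa,vja->vp", RDb, ZtViYb)
        TDb = np.einsum("vja,vab->vjb", self.Tb, Dk)
        YtViY = self.S - np.einsum("vja,vja->v", TDb, ZtViYb)
        logdetV = logdet.sum(axis=1)
        return {"Gjj": Gjj, "ZtViXb": ZtViXb, "ZtViYb": ZtViYb,
                "XtViX": XtViX, "XtViY": XtViY, "YtViY": YtViY,
                "logdetV": logdetV}

    gls = _GeneralKernel.gls
    criterion = _GeneralKernel.criterion

    def score_and_fisher(self, marg: dict, beta, sigma2):
        t = marg["ZtViYb"] - np.einsum("vjap,vp->vja", marg["ZtViXb"], beta)
        Ainv = self._inv_small(marg["XtViX"])[0] if self.p <= 2 \
            else np.linalg.inv(marg["XtViX"])
        Cjj = np.einsum("vjap,vpq,vjbq->vjab", marg["ZtViXb"], Ainv,
                        marg["ZtViXb"])
        inv_s2 = 1.0 / sigma2
        smat = (inv_s2[:, None, None] * np.einsum("vja,vjb->vab", t, t)
                - marg["Gjj"].sum(axis=1) + Cjj.sum(axis=1))
        F = np.einsum("vjac,vjbd->vabcd", marg["Gjj"], marg["Gjj"])
        qk = self.qk
        return ([smat.reshape(-1, qk * qk)],
                [F.reshape(-1, qk * qk, qk * qk)])


def _gather_voxel_arrays(forms: ProductFormSet, voxels: np.ndarray,
                         level_counts, effect_counts,
                         fast: bool) -> dict:
    """Expand group-wise forms to per-voxel arrays for a voxel batch."""
    g = forms.group_index[voxels]
    out = {"Q": forms.Q[voxels], "S": forms.S[voxels],
           "T": forms.T[voxels], "n_obs": forms.n_obs[voxels],
           "P": forms.P[g]}
    if fast:
        lk, qk = level_counts[0], effect_counts[0]
        p = forms.p
        Ub = forms.U.reshape(-1, lk, qk, lk, qk)
        Ub = np.ascontiguousarray(np.einsum("gjajb->gjab", Ub))
        Rb = np.ascontiguousarray(
            forms.R.reshape(-1, p, lk, qk).transpose(0, 2, 1, 3))
        out["Ub"] = Ub[g]
        out["Rb"] = Rb[g]
        out["Tb"] = forms.T[voxels].reshape(-1, lk, qk)
    else:
        out["R"] = forms.R[g]
        out["U"] = forms.U[g]
    return out


def _make_kernel(forms, voxels, level_counts, effect_counts,
                 config: FsfsConfig):
    fast = config.use_fast_path
    if fast is None:
        fast = len(level_counts) == 1
    if fast and len(level_counts) != 1:
        raise ValueError("fast path applies only to single-factor designs")
    arrays = _gather_voxel_arrays(forms, voxels, level_counts, effect_counts,
                                  fast)
    cls = _SingleFactorKernel if fast else _GeneralKernel
    return cls(arrays, level_counts, effect_counts, config)


# ---------------------------------------------------------------------------
# single-voxel spec-level operations (thin wrappers over the general kernel)
# ---------------------------------------------------------------------------

def _single_voxel_kernel(forms: ProductForms, level_counts, effect_counts,
                         config: FsfsConfig | None = None) -> _GeneralKernel:
    config = config or FsfsConfig()
    arrays = {
        "P": forms.P[None], "Q": forms.Q.reshape(1, -1), "R": forms.R[None],
        "S": np.atleast_1d(np.float64(forms.S)), "T": forms.T.reshape(1, -1),
        "U": forms.U[None],
        "n_obs": np.atleast_1d(np.float64(forms.n_obs)),
    }
    return _GeneralKernel(arrays, level_counts, effect_counts, config)


def reml_criterion(forms: ProductForms, beta, sigma2, D_blocks,
                   level_counts, effect_counts) -> float:
    """Restricted log-likelihood at (beta, sigma^2, {D_k}), constants dropped.

    Uses the voxel's observation count n_v in place of n, so the zero-ed-row
    formulation matches the row-deleted one exactly.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    kern = _single_voxel_kernel(forms, level_counts, effect_counts)
    D_vec = _pack_blocks([np.atleast_2d(np.asarray(b, dtype=np.float64))
                          for b in D_blocks], 1, list(effect_counts))
    marg = kern.marginal(D_vec)
    beta = np.asarray(beta, dtype=np.float64).reshape(1, -1)
    val = kern.criterion(marg, beta, np.atleast_1d(np.float64(sigma2)))
    return float(val[0])


def gls_update(forms: ProductForms, D_blocks, level_counts, effect_counts,
               variance_scale: str = "reml") -> tuple[np.ndarray, float]:
    """GLS update (beta, sigma^2) at fixed D, via product forms only."""
    config = FsfsConfig(variance_scale=variance_scale)
    kern = _single_voxel_kernel(forms, level_counts, effect_counts, config)
    D_vec = _pack_blocks([np.atleast_2d(np.asarray(b, dtype=np.float64))
                          for b in D_blocks], 1, list(effect_counts))
    fit = kern.gls(kern.marginal(D_vec))
    return fit["beta"][0], float(fit["sigma2"][0])


def _theta_marg(forms, beta, sigma2, D_blocks, level_counts, effect_counts):
    kern = _single_voxel_kernel(forms, level_counts, effect_counts)
    D_vec = _pack_blocks([np.atleast_2d(np.asarray(b, dtype=np.float64))
                          for b in D_blocks], 1, list(effect_counts))
    marg = kern.marginal(D_vec)
    return kern, marg


def fisher_info_block(forms: ProductForms, D_blocks, level_counts,
                      effect_counts, k: int) -> np.ndarray:
    """F^k = sum_{i,j} B_ij (x) B_ij for factor k ((q_k^2 x q_k^2))."""
    kern, marg = _theta_marg(forms, None, None, D_blocks, level_counts,
                             effect_counts)
    fit = kern.gls(marg)
    _, fishers = kern.score_and_fisher(marg, fit["beta"], fit["sigma2"])
    return fishers[k][0]


def score_vector(forms: ProductForms, beta, sigma2, D_blocks, level_counts,
                 effect_counts, k: int) -> np.ndarray:
    """Score d^k of the restricted likelihood w.r.t. vec(D_k) (times 2)."""
    kern, marg = _theta_marg(forms, beta, sigma2, D_blocks, level_counts,
                             effect_counts)
    beta = np.asarray(beta, dtype=np.float64).reshape(1, -1)
    scores, _ = kern.score_and_fisher(marg, beta,
                                      np.atleast_1d(np.float64(sigma2)))
    return scores[k][0]


# ---------------------------------------------------------------------------
# the FSFS driver
# ---------------------------------------------------------------------------

def _initial_values(kern, config: FsfsConfig):
    """OLS start: beta0 = P^-1 Q, sigma2_0 = RSS/(n_v - p), D_k0 = tau_k I.

    tau_k is a method-of-moments scale: the variance across levels of the
    standardised level sums of OLS residuals (first effect of each level),
    relative to sigma2_0, floored at 1e-6.
    """
    V = kern.V
    beta0 = _solve_spd(kern.P, kern.Q[..., None])[..., 0]
    rss = (kern.S - 2.0 * np.einsum("vp,vp->v", beta0, kern.Q)
           + np.einsum("vp,vpq,vq->v", beta0, kern.P, beta0))
    rss = np.maximum(rss, 1e-300)
    sigma2_0 = rss / np.maximum(kern.nv - kern.p, 1.0)

    if kern.fast:
        Zres = kern.Tb - np.einsum("vjpa,vp->vja", kern.Rb, beta0)
        counts = np.einsum("vjaa->vja", kern.Ub)
        num = Zres[..., 0]
        cnt = counts[..., 0]
    else:
        # first-effect component of Z'e per level, for each factor
        num_list, cnt_list = [], []
        Zres_full = kern.T - np.einsum("vpq,vp->vq", kern.R, beta0)
        diagU = np.einsum("vqq->vq", kern.U)
        for k, (lk, qk) in enumerate(zip(kern.level_counts,
                                         kern.effect_counts)):
            s = kern.slices[k]
            num_list.append(Zres_full[:, s].reshape(V, lk, qk)[..., 0])
            cnt_list.append(diagU[:, s].reshape(V, lk, qk)[..., 0])
        num, cnt = num_list, cnt_list

    blocks = []
    for k, qk in enumerate(kern.effect_counts):
        nk = num if kern.fast else num[k]
        ck = cnt if kern.fast else cnt[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            means = np.where(ck > 1e-12, nk / np.maximum(ck, 1e-12), 0.0)
        tau = np.var(means, axis=1) / sigma2_0
        tau = np.maximum(np.nan_to_num(tau), _D_FLOOR)
        blocks.append(tau[:, None, None] * np.eye(qk)[None])
    D_vec = _pack_blocks(blocks, V, kern.effect_counts) if blocks \
        else np.zeros((V, 0))
    return D_vec


def _project_vec(D_vec: np.ndarray, effect_counts) -> np.ndarray:
    parts = []
    for k, qk in enumerate(effect_counts):
        Dk = _unpack_block(D_vec, k, effect_counts)
        parts.append(project_nnd(Dk).reshape(-1, qk * qk))
    return np.concatenate(parts, axis=1) if parts else D_vec


def _profiled(kern, D_vec):
    marg = kern.marginal(D_vec)
    fit = kern.gls(marg)
    llh = kern.criterion(marg, fit["beta"], fit["sigma2"], eVe=fit["eVe"])
    return marg, fit, llh


def fsfs_fit_vectorised(forms: ProductFormSet, level_counts, effect_counts,
                        config: FsfsConfig | None = None,
                        voxels: np.ndarray | None = None) -> FitResultBatch:
    """Fit every voxel in the batch by FSFS, broadcast across voxels.

    Per-voxel step halving and convergence are tracked independently; a
    converged (or flagged) voxel's state freezes while the rest of the batch
    continues.  A numerically failing voxel is flagged, never fatal.
    """
    config = config or FsfsConfig()
    if voxels is None:
        voxels = np.arange(forms.n_voxels)
    voxels = np.asarray(voxels, dtype=np.int64)
    level_counts = list(level_counts)
    effect_counts = list(effect_counts)
    V = voxels.shape[0]
    p = forms.p

    if len(level_counts) == 0:
        return _ols_fit(forms, voxels, config)

    kern = _make_kernel(forms, voxels, level_counts, effect_counts, config)
    dtot = sum(qk * qk for qk in effect_counts)

    D_vec = _initial_values(kern, config)
    _, fit, llh = _profiled(kern, D_vec)
    beta, sigma2 = fit["beta"], fit["sigma2"]

    converged = np.zeros(V, dtype=bool)
    flagged = ~np.isfinite(llh)
    n_iter = np.zeros(V, dtype=np.int64)
    active = ~(converged | flagged)
    history = [llh.copy()] if config.track_history else None
    best_llh = llh.copy()
    no_progress = np.zeros(V, dtype=np.int64)

    for _ in range(config.max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        sub = kern.subset(idx)
        D_sub = D_vec[idx]
        marg, fitv, llh_cur = _profiled(sub, D_sub)
        scores, fishers = sub.score_and_fisher(marg, fitv["beta"],
                                               fitv["sigma2"])
        steps = []
        for sc, Fm in zip(scores, fishers):
            try:
                st = _solve_spd(Fm, sc[..., None])[..., 0]
            except np.linalg.LinAlgError:
                st = np.full_like(sc, np.nan)
            steps.append(st)
        step = np.concatenate(steps, axis=1)
        bad_step = ~np.isfinite(step).all(axis=1)
        step = np.where(bad_step[:, None], 0.0, step)

        # per-voxel step halving against the profiled criterion.  The
        # criterion value carries O(1e-9) evaluation noise from product-form
        # cancellation, so "no decrease" is tested with a noise-scaled
        # slack; genuine decreases are orders of magnitude larger.
        m = idx.shape[0]
        slack = 1e-10 * (1.0 + np.abs(llh_cur))
        alpha = np.ones(m)
        accepted = np.zeros(m, dtype=bool)
        new_D = D_sub.copy()
        new_llh = llh_cur.copy()
        new_beta = fitv["beta"].copy()
        new_sig = fitv["sigma2"].copy()
        trying = ~bad_step

        def _try_alpha(tr, alphas):
            """Evaluate the projected step at per-voxel alphas; return llh."""
            D_prop = _project_vec(D_sub[tr] + alphas[:, None] * step[tr],
                                  effect_counts)
            sub2 = sub.subset(tr)
            _, fit2, llh2 = _profiled(sub2, D_prop)
            return D_prop, fit2, llh2

        def _adopt(tr, ok, D_prop, fit2, llh2):
            acc = tr[ok]
            pos = np.nonzero(ok)[0]
            new_D[acc] = D_prop[pos]
            new_llh[acc] = llh2[pos]
            new_beta[acc] = fit2["beta"][pos]
            new_sig[acc] = fit2["sigma2"][pos]
            accepted[acc] = True

        for _h in range(config.max_halvings + 1):
            if not trying.any():
                break
            tr = np.nonzero(trying)[0]
            D_prop, fit2, llh2 = _try_alpha(tr, alpha[tr])
            ok = np.isfinite(llh2) & (llh2 >= llh_cur[tr] - slack[tr])
            _adopt(tr, ok, D_prop, fit2, llh2)
            trying[tr[ok]] = False
            alpha[trying] *= 0.5

        # refine the accepted step size along the Fisher direction with a
        # secant solve on the analytic directional derivative
        # g(alpha) = d l_R / d alpha = (1/2) sum_k score_k(D + alpha s) . s_k.
        # Likelihood *differences* saturate at float noise long before the
        # gradient does, so this reaches ~1e-10 parameter accuracy where a
        # value-based line search stalls around 1e-6.  The plain halved step
        # is kept whenever the refined point would decrease the likelihood,
        # so accepted iterations stay monotone.
        ref = np.nonzero(accepted)[0]
        if ref.size:
            def _dirderiv(kern_sub, marg_r, fit_r, rows):
                sc_r, _ = kern_sub.score_and_fisher(marg_r, fit_r["beta"],
                                                    fit_r["sigma2"])
                sc_cat = np.concatenate(sc_r, axis=1)
                return 0.5 * np.einsum("vd,vd->v", sc_cat, step[rows])

            sub_ref = sub.subset(ref)
            sc_cat0 = np.concatenate(scores, axis=1)[ref]
            g0 = 0.5 * np.einsum("vd,vd->v", sc_cat0, step[ref])
            a0 = np.zeros(ref.size)
            a1 = alpha[ref].copy()
            # scalar covariances profit from a tight line solve (the step
            # direction is the whole search space); for larger blocks the
            # direction itself limits accuracy, so fewer rounds suffice
            n_rounds = 6 if step.shape[1] == 1 else 3
            for _round in range(n_rounds):
                D_r = _project_vec(D_sub[ref] + a1[:, None] * step[ref],
                                   effect_counts)
                marg_r = sub_ref.marginal(D_r)
                fit_r = sub_ref.gls(marg_r)
                g1 = _dirderiv(sub_ref, marg_r, fit_r, ref)
                with np.errstate(invalid="ignore", divide="ignore"):
                    a2 = a1 - g1 * (a1 - a0) / (g1 - g0)
                good = (np.isfinite(a2) & (a2 > 0)
                        & (a2 < 8.0 * alpha[ref]) & (g1 != g0))
                a0, g0 = a1, g1
                a1 = np.where(good, a2, a1)
            D_r = _project_vec(D_sub[ref] + a1[:, None] * step[ref],
                               effect_counts)
            marg_r = sub_ref.marginal(D_r)
            fit_r = sub_ref.gls(marg_r)
            llh_r = sub_ref.criterion(marg_r, fit_r["beta"],
                                      fit_r["sigma2"], eVe=fit_r["eVe"])
            ok_r = np.isfinite(llh_r) & (llh_r >= llh_cur[ref] - slack[ref]) \
                & (llh_r >= new_llh[ref] - slack[ref])
            _adopt(ref, ok_r, D_r, fit_r, llh_r)

        delta = np.where(accepted, new_llh - llh_cur, 0.0)
        D_move = np.max(np.abs(new_D - D_sub), axis=1) if dtot else \
            np.zeros(m)
        D_vec[idx] = new_D
        llh[idx] = new_llh
        beta[idx] = new_beta
        sigma2[idx] = new_sig
        n_iter[idx] += 1

        if history is not None:
            history.append(llh.copy())
        # primary rule: likelihood change below tolerance.  Secondary
        # rules guard against evaluation-noise chatter at the optimum
        # (D stops moving) and against projection bounce at a boundary
        # optimum (no gain beyond tolerance for 3 straight iterations).
        improved = new_llh > best_llh[idx] + config.tol
        best_llh[idx] = np.maximum(best_llh[idx], new_llh)
        no_progress[idx] = np.where(improved, 0, no_progress[idx] + 1)
        stalled = D_move < 1e-11 * (1.0 + np.max(np.abs(new_D), axis=1)
                                    if dtot else 1.0)
        conv_now = (np.abs(delta) < config.tol) | stalled \
            | (no_progress[idx] >= 3)
        converged[idx[conv_now]] = True
        flagged[idx[~np.isfinite(new_llh)]] = True
        active = ~(converged | flagged)
        active &= n_iter < config.max_iter

    return FitResultBatch(
        beta=beta, sigma2=sigma2, D_vec=D_vec, loglik=llh, n_iter=n_iter,
        converged=converged, flagged=flagged,
        level_counts=level_counts, effect_counts=effect_counts,
        history=history,
    )


def _ols_fit(forms: ProductFormSet, voxels, config: FsfsConfig):
    """Degenerate r = 0 path: ordinary linear model, REML variance scale."""
    g = forms.group_index[voxels]
    P = forms.P[g]
    Q = forms.Q[voxels]
    S = forms.S[voxels]
    nv = forms.n_obs[voxels].astype(np.float64)
    p = forms.p
    beta = _solve_spd(P, Q[..., None])[..., 0]
    rss = np.maximum(S - 2 * np.einsum("vp,vp->v", beta, Q)
                     + np.einsum("vp,vpq,vq->v", beta, P, beta), 0.0)
    denom = nv - p if config.variance_scale == "reml" else nv
    sigma2 = rss / denom
    sign, logdetP = np.linalg.slogdet(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        llh = -0.5 * ((nv - p) * np.log(sigma2) + rss / sigma2 + logdetP)
    V = voxels.shape[0]
    return FitResultBatch(
        beta=beta, sigma2=sigma2, D_vec=np.zeros((V, 0)), loglik=llh,
        n_iter=np.zeros(V, dtype=np.int64),
        converged=np.isfinite(llh), flagged=~np.isfinite(llh),
        level_counts=[], effect_counts=[],
    )


def fsfs_fit(forms: ProductForms, level_counts, effect_counts,
             config: FsfsConfig | None = None) -> ThetaEstimate:
    """Fit one voxel: a batch-of-one call into the vectorised engine."""
    fset = ProductFormSet(
        P=forms.P[None], R=forms.R[None], U=forms.U[None],
        Q=forms.Q.reshape(1, -1), S=np.atleast_1d(np.float64(forms.S)),
        T=forms.T.reshape(1, -1),
        group_index=np.zeros(1, dtype=np.int64),
        n_obs=np.atleast_1d(np.int64(forms.n_obs)),
    )
    res = fsfs_fit_vectorised(fset, level_counts, effect_counts, config)
    return res.theta(0)
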