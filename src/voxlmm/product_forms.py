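"""Product-form computation: the sufficient statistics for REML.

For each voxel the six cross-products

    P = X_v'X_v,  Q = X_v'Y_v,  R = X_v'Z_v,
    S = Y_v'Y_v,  T = Y_v'Z_v,  U = Z_v'Z_v

are sufficient for REML estimation and Wald/likelihood-ratio inference, and
their dimensions depend only on (p, q), never on n.  They are computed by an
image-wise batched map-reduce: rows (images) are partitioned into B evenly
sized batches, each batch computes partial forms, and a central reducer sums
them (A'B = sum_b A^(b)'B^(b)).  Design-dependent forms (P, R, U) are
computed once per missingness-pattern group; response-dependent forms
(Q, S, T) per voxel.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .missingness import PatternGroup

__all__ = [
    "ProductForms",
    "ProductFormSet",
    "BatchPlan",
    "compute_batch_product_forms",
    "reduce_product_forms",
    "rank_filter",
    "save_partial_forms",
    "load_partial_forms",
]


@dataclass
class ProductForms:
    """The six product-form matrices for a single voxel."""

    P: np.ndarray  # (p, p)
    Q: np.ndarray  # (p,)
    R: np.ndarray  # (p, q)
    S: float
    T: np.ndarray  # (q,)
    U: np.ndarray  # (q, q)
    n_obs: int


@dataclass
class ProductFormSet:
    """Product forms for all voxels, stored group-wise where possible.

    P, R, U are per missingness-pattern group ((G,p,p), (G,p,q), (G,q,q));
    Q, S, T are per voxel ((V,p), (V,), (V,q)); ``group_index`` maps each
    voxel to its group.  Nothing here scales with the number of images n.
    """

    P: np.ndarray
    R: np.ndarray
    U: np.ndarray
    Q: np.ndarray
    S: np.ndarray
    T: np.ndarray
    group_index: np.ndarray
    n_obs: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.Q.shape[0]

    @property
    def p(self) -> int:
        return self.P.shape[1]

    @property
    def q(self) -> int:
        return self.U.shape[1]

    def voxel(self, v: int) -> ProductForms:
        g = int(self.group_index[v])
        return ProductForms(
            P=self.P[g].copy(),
            Q=self.Q[v].copy(),
            R=self.R[g].copy(),
            S=float(self.S[v]),
            T=self.T[v].copy(),
            U=self.U[g].copy(),
            n_obs=int(self.n_obs[v]),
        )

    def _arrays(self) -> dict[str, np.ndarray]:
        return {
            "P": self.P, "R": self.R, "U": self.U,
            "Q": self.Q, "S": self.S, "T": self.T,
            "group_index": self.group_index, "n_obs": self.n_obs,
        }


@dataclass
class BatchPlan:
    """Row partition for image-wise batching: sizes differ by at most 1."""

    n: int
    n_batches: int

    def __post_init__(self):
        if not 1 <= self.n_batches <= self.n:
            raise ValueError(f"need 1 <= B <= n, got B={self.n_batches}, n={self.n}")

    @property
    def row_slices(self) -> list[slice]:
        edges = np.linspace(0, self.n, self.n_batches + 1).astype(int)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def compute_batch_product_forms(
    X: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    indicators: np.ndarray,
    groups: list[PatternGroup],
    rows: slice | None = None,
) -> ProductFormSet:
    """Partial product forms for one image batch.

    Parameters
    ----------
    X, Z:
        Batch rows of the fixed/random design ((nb, p), (nb, q)).  ``Z`` may
        have zero columns for the pure linear model.
    Y:
        (nb, V) response values for the batch's images at the analysis-mask
        voxels.  Missing entries need not be pre-zeroed.
    indicators:
        (nb, V) 0/1 observation indicators for the batch rows.
    groups:
        Pattern groups over the *full* indicator array; within the batch the
        patterns are restricted to the batch rows.
    rows:
        Row slice of the full design this batch covers; used to restrict the
        group patterns (defaults to all rows).
    """
    X = np.asarray(X, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    nb, p = X.shape
    q = Z.shape[1]
    V = Y.shape[1]
    ind = np.asarray(indicators, dtype=np.float64)
    Ym = np.where(ind > 0, np.nan_to_num(np.asarray(Y, dtype=np.float64)), 0.0)

    G = len(groups)
    P = np.zeros((G, p, p))
    R = np.zeros((G, p, q))
    U = np.zeros((G, q, q))
    group_index = np.empty(V, dtype=np.int64)
    for g, grp in enumerate(groups):
        group_index[grp.voxels] = g
        m = grp.pattern.indicator if rows is None else grp.pattern.indicator[rows]
        if m.shape[0] != nb:
            raise ValueError("group pattern length does not match batch rows")
        sel = m.astype(bool)
        Xs = X[sel]
        Zs = Z[sel]
        P[g] = Xs.T @ Xs
        R[g] = Xs.T @ Zs
        U[g] = Zs.T @ Zs

    # response entries already carry the voxel's indicator, so plain products
    # give the zero-ed-row cross terms
    Q = Ym.T @ X
    T = Ym.T @ Z
    S = np.einsum("iv,iv->v", Ym, Ym)
    n_obs = ind.sum(axis=0).astype(np.int64)
    return ProductFormSet(P=P, R=R, U=U, Q=Q, S=S, T=T,
                          group_index=group_index, n_obs=n_obs)


def reduce_product_forms(partials: list[ProductFormSet | None]) -> ProductFormSet:
    """Sum partial forms over batches, in fixed batch order.

    Summation order is the list order, so results are bit-identical from run
    to run regardless of which worker produced each partial first.
    """
    missing = [b for b, part in enumerate(partials) if part is None]
    if missing:
        raise ValueError(f"missing product-form batches: {missing}")
    if not partials:
        raise ValueError("no batches to reduce")
    first = partials[0]
    out = ProductFormSet(
        P=first.P.copy(), R=first.R.copy(), U=first.U.copy(),
        Q=first.Q.copy(), S=first.S.copy(), T=first.T.copy(),
        group_index=first.group_index.copy(), n_obs=first.n_obs.copy(),
    )
    for part in partials[1:]:
        if not np.array_equal(part.group_index, out.group_index):
            raise ValueError("batches disagree on pattern-group assignment")
        out.P += part.P
        out.R += part.R
        out.U += part.U
        out.Q += part.Q
        out.S += part.S
        out.T += part.T
        out.n_obs += part.n_obs
    return out


def _numerical_rank(A: np.ndarray) -> int:
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    tol = max(A.shape) * np.finfo(np.float64).eps * (s[0] if s.size else 0.0)
    return int(np.sum(s > tol))


def rank_filter(
    forms: ProductFormSet, safe_mode: bool = True
) -> tuple[np.ndarray, dict]:
    """Drop voxels whose observed design is rank deficient.

    A voxel is flagged when rank(P_v) < p or rank(U_v) < q (e.g. a factor
    level with no observed rows at that voxel).  With ``safe_mode`` the
    flagged voxels are removed from the analysis; without it they are kept
    and only reported, which generally leads to convergence failures.
    """
    p, q = forms.p, forms.q
    G = forms.P.shape[0]
    group_ok = np.ones(G, dtype=bool)
    for g in range(G):
        if _numerical_rank(forms.P[g]) < p:
            group_ok[g] = False
        elif q > 0 and _numerical_rank(forms.U[g]) < q:
            group_ok[g] = False
    ok = group_ok[forms.group_index] & (forms.n_obs > 0)
    report = {
        "n_voxels": int(forms.n_voxels),
        "n_rank_deficient": int(np.sum(~ok)),
        "safe_mode": bool(safe_mode),
        "dropped": int(np.sum(~ok)) if safe_mode else 0,
    }
    retained = ok if safe_mode else (forms.n_obs > 0)
    return retained, report


def save_partial_forms(path_prefix, batch_id: int, forms: ProductFormSet) -> None:
    """Persist one batch's partial forms as flat arrays + JSON sidecar."""
    arrays = forms._arrays()
    np.savez(f"{path_prefix}_batch{batch_id}.npz", **arrays)
    checksum = 0
    for name in sorted(arrays):
        checksum = zlib.adler32(np.ascontiguousarray(arrays[name]).tobytes(),
                                checksum)
    sidecar = {
        "batch_id": batch_id,
        "n_voxels": int(forms.n_voxels),
        "p": int(forms.p),
        "q": int(forms.q),
        "checksum": checksum,
    }
    with open(f"{path_prefix}_batch{batch_id}.json", "w") as fh:
        json.dump(sidecar, fh)


def load_partial_forms(path_prefix, batch_id: int) -> ProductFormSet:
    with open(f"{path_prefix}_batch{batch_id}.json") as fh:
        sidecar = json.load(fh)
    data = np.load(f"{path_prefix}_batch{batch_id}.npz")
    forms = ProductFormSet(**{k: data[k] for k in data.files})
    checksum = 0
    arrays = forms._arrays()
    for name in sorted(arrays):
        checksum = zlib.adler32(np.ascontiguousarray(arrays[name]).tobytes(),
                                checksum)
    if checksum != sidecar["checksum"]:
        raise IOError(f"checksum mismatch for batch {batch_id}")
    return forms
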