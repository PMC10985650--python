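import numpy as np
import pytest

from voxlmm.model_spec import FactorSpec, ModelSpec
from voxlmm.product_forms import ProductForms, ProductFormSet


def make_single_voxel(seed, n, lks, qks, p=3, beta=None, sigma2=1.0,
                      d_diag=1.0, d_offdiag=0.5):
    """One univariate LMM draw plus its product forms.

    Returns a dict with the dense design (X, Y, Z), the factor structure and
    the six product forms — the shared raw material for estimation and
    inference tests.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)]
                        + [rng.uniform(-0.5, 0.5, n) for _ in range(p - 1)])
    beta = np.asarray(beta if beta is not None
                      else np.arange(p, 0, -1), dtype=np.float64)
    factors = []
    for lk, qk in zip(lks, qks):
        reps = int(np.ceil(n / lk))
        g = rng.permutation(np.tile(np.arange(1, lk + 1), reps)[:n])
        z = np.column_stack([np.ones(n)]
                            + [rng.uniform(-0.5, 0.5, n)
                               for _ in range(qk - 1)])
        factors.append(FactorSpec(g, z))
    model = ModelSpec(X, factors)
    Z = model.random_design()
    b = []
    for lk, qk in zip(lks, qks):
        Dk = np.full((qk, qk), d_offdiag)
        np.fill_diagonal(Dk, d_diag)
        w, v = np.linalg.eigh(Dk)
        L = v * np.sqrt(np.clip(w, 0.0, None))
        b.append((np.sqrt(sigma2) * (L @ rng.normal(size=(qk, lk)))).T.ravel())
    b = np.concatenate(b) if b else np.zeros(0)
    Y = X @ beta + (Z @ b if Z.size else 0.0) \
        + np.sqrt(sigma2) * rng.normal(size=n)
    forms = dense_forms(X, Y, Z)
    return {"X": X, "Y": Y, "Z": Z, "model": model, "forms": forms,
            "lks": list(lks), "qks": list(qks), "beta": beta, "b": b}


def dense_forms(X, Y, Z, n_obs=None) -> ProductForms:
    """Product forms by direct dense multiplication (the trivial oracle)."""
    return ProductForms(P=X.T @ X, Q=X.T @ Y, R=X.T @ Z, S=float(Y @ Y),
                        T=Y @ Z, U=Z.T @ Z,
                        n_obs=int(n_obs if n_obs is not None else X.shape[0]))


def forms_as_set(forms: ProductForms) -> ProductFormSet:
    return ProductFormSet(
        P=forms.P[None], R=forms.R[None], U=forms.U[None],
        Q=forms.Q.reshape(1, -1), S=np.atleast_1d(np.float64(forms.S)),
        T=forms.T.reshape(1, -1), group_index=np.zeros(1, dtype=np.int64),
        n_obs=np.atleast_1d(np.int64(forms.n_obs)))


def stack_forms(forms_list) -> ProductFormSet:
    """Stack single-voxel forms sharing a design into one voxel batch."""
    f0 = forms_list[0]
    return ProductFormSet(
        P=f0.P[None], R=f0.R[None], U=f0.U[None],
        Q=np.stack([f.Q for f in forms_list]),
        S=np.asarray([f.S for f in forms_list], dtype=np.float64),
        T=np.stack([f.T for f in forms_list]),
        group_index=np.zeros(len(forms_list), dtype=np.int64),
        n_obs=np.asarray([f.n_obs for f in forms_list], dtype=np.int64))


@pytest.fixture(scope="session")
def small_image_instance():
    """A small simulated design-1 image shared across pipeline-level tests."""
    from voxlmm.simulation import SimulationConfig, simulate_instance
    cfg = SimulationConfig(design=1, n=40, dims=(12, 12, 12),
                           level_counts=[10], seed=123)
    return simulate_instance(cfg)
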