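"""Synthetic image-shaped LMM data for validation and benchmarking.

Three generative designs mirror the standard use cases of the estimator:

* design 1 — one factor grouping one random effect (random intercept) into
  100 levels (r=1, q1=1, l1=100);
* design 2 — one factor grouping two random effects (intercept + slope)
  into 50 levels (r=1, q1=2, l1=50);
* design 3 — two crossed factors: 20 levels x 2 effects and 10 levels x 1
  effect (r=2, q1=2, q2=1, l1=20, l2=10).

Defaults: beta = [4, 3, 2, 1, 0]', sigma^2 = 1, within-level covariance
with unit diagonal and 0.5 off-diagonal, uniform[-0.5, 0.5] regressors, the
first random effect an intercept, and (100 x 100 x 100) volumes; tests and
desk-scale runs override the grid size, which changes only the number of
voxels, not the model.  Per voxel, Y = X beta + Z b_v + eps_v with
b_v ~ N(0, sigma^2 D) and eps_v ~ N(0, sigma^2 I); the response volumes are
then smoothed with an isotropic Gaussian kernel (FWHM 5 voxels,
sigma = FWHM/2.3548) to induce spatial correlation, and finally each image
is masked by a randomly perturbed brain-shaped mask, creating the
edge-of-brain missingness the estimator has to absorb.  Because smoothing
scales the b and eps fields by the same kernel, the sigma^2-relative
covariance D of the smoothed data is unchanged — which is what makes D
recovery a meaningful check on smoothed responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model_spec import FactorSpec, ModelSpec

__all__ = [
    "SimulationConfig",
    "SimulatedInstance",
    "design_params",
    "make_base_mask",
    "simulate_design",
    "simulate_images",
    "simulate_instance",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ~1/2.3548


def design_params(design: int) -> tuple[list[int], list[int]]:
    """(level counts, effect counts) for the three generative designs."""
    if design == 1:
        return [100], [1]
    if design == 2:
        return [50], [2]
    if design == 3:
        return [20, 10], [2, 1]
    raise ValueError(f"unknown design id {design}")


@dataclass
class SimulationConfig:
    design: int = 1
    n: int = 200
    dims: tuple[int, int, int] = (100, 100, 100)
    fwhm: float = 5.0
    beta: np.ndarray = field(
        default_factory=lambda: np.array([4.0, 3.0, 2.0, 1.0, 0.0]))
    sigma2: float = 1.0
    d_diag: float = 1.0
    d_offdiag: float = 0.5
    missingness_threshold = "50%"
    mask_dropout: float = 0.1   # per-image drop probability on the boundary shell
    level_counts: list[int] | None = None   # override for scaled-down runs
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        lks, qks = design_params(self.design)
        if self.level_counts is not None:
            if len(self.level_counts) != len(lks):
                raise ValueError("level_counts must match the design's "
                                 "factor count")
            lks = list(self.level_counts)
        self.lks, self.qks = lks, qks
        if self.n < max(lks):
            raise ValueError(f"n={self.n} smaller than a level count {lks}")

    def true_D_blocks(self) -> list[np.ndarray]:
        out = []
        for qk in self.qks:
            Dk = np.full((qk, qk), self.d_offdiag)
            np.fill_diagonal(Dk, self.d_diag)
            out.append(Dk)
        return out


@dataclass
class SimulatedInstance:
    """One simulated dataset plus its generating truth."""

    model: ModelSpec
    config: SimulationConfig
    response: np.ndarray        # (n, *dims), masked (missing encoded 0)
    image_masks: np.ndarray     # (n, *dims) bool
    analysis_mask: np.ndarray   # (*dims,) bool
    truth: dict

    @property
    def mask_voxels(self) -> np.ndarray:
        return np.flatnonzero(self.analysis_mask.ravel())

    def data_matrix(self) -> np.ndarray:
        """(n, V) response at analysis-mask voxels, missing encoded 0."""
        return self.response.reshape(self.response.shape[0], -1)[
            :, self.mask_voxels]

    def mask_matrix(self) -> np.ndarray:
        """(n, V) per-image observation mask at analysis-mask voxels."""
        return self.image_masks.reshape(self.response.shape[0], -1)[
            :, self.mask_voxels]


def _assign_levels(rng: np.random.Generator, n: int,
                   n_levels: int) -> np.ndarray:
    """Balanced uniform level assignment: every level occupied, sizes
    differing by at most one, order fully randomised.

    Marginally each observation is equally likely to sit in any level, the
    stated generative property.  Plain iid draws cannot realise the design
    sizes (n=200 over 100 levels leaves ~13 levels empty, and with two
    effects per level any level with fewer than two observations makes
    Z'Z singular), so the balanced layout is the only reading under which
    the prescribed (n, l_k) combinations produce estimable designs.
    """
    reps = int(np.ceil(n / n_levels))
    pool = np.concatenate([rng.permutation(np.arange(1, n_levels + 1))
                           for _ in range(reps)])[:n]
    return rng.permutation(pool)


def simulate_design(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> ModelSpec:
    """Draw the fixed and random design: X = [1, 4 x uniform regressors],
    z_k = [1, uniform extra effects], uniform level assignment."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n
    p = config.beta.shape[0]
    X = np.column_stack([np.ones(n)]
                        + [rng.uniform(-0.5, 0.5, n) for _ in range(p - 1)])
    factors = []
    for lk, qk in zip(config.lks, config.qks):
        g = _assign_levels(rng, n, lk)
        z = np.column_stack([np.ones(n)]
                            + [rng.uniform(-0.5, 0.5, n)
                               for _ in range(qk - 1)])
        factors.append(FactorSpec(g, z))
    return ModelSpec(X, factors)


def make_base_mask(dims) -> np.ndarray:
    """Brain-shaped analysis mask: a centred ellipsoid covering ~45% of the
    volume (semi-axes 0.475 of each dimension)."""
    dims = tuple(int(d) for d in dims)
    if min(dims) < 8:
        raise ValueError("mask dims must be at least (8, 8, 8)")
    axes = [np.arange(d) - (d - 1) / 2.0 for d in dims]
    grids = np.meshgrid(*axes, indexing="ij")
    r2 = sum((gr / (0.475 * d)) ** 2 for gr, d in zip(grids, dims))
    return r2 <= 1.0


def _perturbed_mask(base: np.ndarray, sigma: float, drop_prob: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Randomly perturb the mask boundary to mimic edge-of-brain dropout.

    A smoothed (hence spatially contiguous) Gaussian field is thresholded
    at its upper ``drop_prob`` quantile; boundary-shell voxels (the two
    outermost layers of the mask) where the field exceeds the threshold are
    removed.  Deep-interior voxels are never touched, and each shell voxel
    is missing with probability ~``drop_prob`` per image.  Zero strength
    returns the base mask unchanged."""
    if drop_prob == 0.0:
        return base.copy()
    from scipy.stats import norm
    shell = base & ~ndimage.binary_erosion(base, iterations=2)
    noise = ndimage.gaussian_filter(rng.standard_normal(base.shape), sigma)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    drop = shell & (noise > norm.isf(drop_prob))
    return base & ~drop


def simulate_images(model: ModelSpec, config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> SimulatedInstance:
    """Generate the response volumes for a drawn design.

    Order follows the generative pipeline: assemble Y per voxel, smooth the
    response volumes, then apply the per-image perturbed masks (missing
    entries encoded as 0).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    dims = tuple(config.dims)
    n = config.n
    n_vox = int(np.prod(dims))
    Z = model.random_design()
    q = Z.shape[1]
    D_blocks = config.true_D_blocks()
    sig = np.sqrt(config.sigma2)

    # random-effect field b: independent across voxels and levels, D_k
    # covariance within a level
    b = np.empty((q, n_vox))
    off = 0
    for Dk, lk, qk in zip(D_blocks, config.lks, config.qks):
        L = np.linalg.cholesky(Dk)
        eps = rng.standard_normal((lk, qk, n_vox))
        b[off:off + lk * qk] = (sig * np.einsum("ab,lbv->lav", L, eps)
                                ).reshape(lk * qk, n_vox)
        off += lk * qk

    noise = sig * rng.standard_normal((n, n_vox))
    Y = (model.fixed_design @ config.beta)[:, None] + Z @ b + noise
    Y = Y.reshape((n,) + dims)

    if config.fwhm > 0:
        sigma_k = config.fwhm * FWHM_TO_SIGMA
        for i in range(n):
            Y[i] = ndimage.gaussian_filter(Y[i], sigma_k)

    base = make_base_mask(dims)
    sigma_m = 5.0 * FWHM_TO_SIGMA
    masks = np.empty((n,) + dims, dtype=bool)
    for i in range(n):
        masks[i] = _perturbed_mask(base, sigma_m, config.mask_dropout, rng)
    Y = np.where(masks, Y, 0.0)

    truth = {
        "beta": config.beta.copy(),
        "sigma2": float(config.sigma2),
        "D_blocks": [Dk.copy() for Dk in D_blocks],
        "b": b,
        "design": config.design,
        "seed": config.seed,
    }
    return SimulatedInstance(model=model, config=config, response=Y,
                             image_masks=masks, analysis_mask=base,
                             truth=truth)


def simulate_instance(config: SimulationConfig) -> SimulatedInstance:
    """Draw design and images from a single seeded generator stream."""
    rng = np.random.default_rng(config.seed)
    model = simulate_design(config, rng)
    return simulate_images(model, config, rng)
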