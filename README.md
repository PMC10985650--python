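# voxlmm

Mass-univariate **linear mixed models** for 3-D image data: per-voxel REML
estimation by vectorised Fisher scoring on compressed *product forms*, with
voxel-wise missing-data handling, Welch–Satterthwaite Wald inference and
mixture-χ² likelihood-ratio tests for random effects.

## Who this is for

Large-n neuroimaging group analyses (longitudinal designs, multi-site
pooling, repeated measures) fit one mixed model per voxel:

    Y_v = X β_v + Z b_v + ε_v,   ε_v ~ N(0, σ_v² M_v),   b_v ~ N(0, σ_v² D_v)

with a shared fixed-effects design `X` (n × p), a random-effects design `Z`
(n × q) built from grouping factors (levels × effects: a factor
vector plus a raw regressor matrix per factor), and a per-voxel diagonal missingness matrix
`M_v` that zero-es out design rows where the voxel lacks data — so voxels
near cortical boundaries stay in the analysis instead of being discarded.

Standard univariate mixed-model tools fit one model at a time and scale
poorly to hundreds of thousands of voxels and tens of thousands of images.
voxlmm instead

1. reduces each voxel to six cross products
   `P = X'X, Q = X'Y, R = X'Z, S = Y'Y, T = Y'Z, U = Z'Z`
   via an image-wise map-reduce (memory after reduction is independent of
   n, and the reduce contract is a drop-in for a cluster scheduler);
2. maximises the restricted likelihood
   `l_R = -½[(n_v−p) log σ² + σ⁻² e'V⁻¹e + log|V| + log|X'V⁻¹X|]`,
   `V = I + ZDZ'`, by **Full Simplified Fisher Scoring**: GLS updates for
   (β, σ²) alternating with per-factor scoring steps
   `vec(D_k) ← vec(D_k) + α (F^k)⁻¹ ∂^k`, everything evaluated through the
   Woodbury identity in product-form space and broadcast across voxels;
3. outputs parameter, contrast, Wald-statistic and p-value maps (raw and
   −log₁₀) as NIfTI, with Welch–Satterthwaite degrees of freedom from
   closed-form derivatives, Bonferroni/Benjamini–Hochberg correction, and
   boundary-aware mixture-χ² likelihood-ratio tests between nested fits.

See `docs/methods.md` for the full model, algorithm and design notes.

## Worked example

Simulate a small dataset (random-intercept design with 8 levels, 30
images on a 16³ grid, FWHM-5 smoothing, randomly perturbed brain-shaped
masks) and fit it:

```sh
voxlmm simulate --design 1 --n 30 --levels 8 --dims 16 16 16 --seed 5 \
    --out /tmp/demo
voxlmm fit --config /tmp/demo/config.yaml --image-batches 2
```

The fit prints its run report:

```json
{
  "n_images": 30,
  "n_mask_voxels": 1856,
  "n_after_threshold": 1856,
  "n_rank_dropped": 0,
  "n_fit": 1856,
  "n_converged": 1856,
  "n_flagged": 0,
  "n_pattern_groups": 348,
  "median_iterations": 2.0
}
```

All 1856 voxels of the ellipsoidal analysis mask survive the default 50%
missingness threshold (boundary voxels miss ~10% of the images each, well
under half), none loses a whole factor level (`rank(U_v) < q` would drop
it), and every voxel converges in a median of 2 scoring iterations,
sharing design computations across 348 distinct missingness patterns.
`/tmp/demo/analysis/` then holds
`beta1..beta5.nii.gz` (fixed effects), `sigma2.nii.gz`, `D1_elem1.nii.gz`
(the level variance, σ²-relative), per-contrast statistic/df/p maps, a
convergence map and `n_obs.nii.gz`.

The same analysis is available as a library call:

```python
from voxlmm import SimulationConfig, simulate_instance, analyse_instance

inst = simulate_instance(SimulationConfig(design=1, n=200, dims=(12, 12, 12)))
forms, fit, voxels = analyse_instance(inst)
print(fit.beta[fit.converged].mean(axis=0))   # -> approx [4, 3, 2, 1, 0]
print(fit.D_block(0)[fit.converged].mean())   # -> approx 1.0
```

which recovers the generating fixed effects `β = [4, 3, 2, 1, 0]'` and the
σ²-relative random-intercept variance `d = 1`.

Completed analyses can be compared with a likelihood-ratio test for the
random effects (`voxlmm lrt --null <dir> --full <dir> --q 1 --q-tilde 1`),
and a single voxel can be re-fit by slow direct dense REML maximisation for
debugging (`voxlmm oracle --x X.csv --y y.csv --factor g.csv
--regressors z.csv`).

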