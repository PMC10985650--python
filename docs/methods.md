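# Methods

## Model

At every voxel `v` of a 3-D analysis grid, voxlmm fits the linear mixed
model

    Y_v = X_v beta_v + Z_v b_v + eps_v,
    eps_v ~ N(0, sigma_v^2 M_v),   b_v ~ N(0, sigma_v^2 D_v),

where `X` (n x p) is the fixed-effects design shared by all voxels, `Z`
(n x q) the random-effects design built from per-factor grouping vectors
and raw regressors (row-wise Khatri-Rao pairing of the level indicator
with the regressors, columns level-major), and `M_v` a diagonal 0/1
missingness matrix that zero-es out the rows where voxel `v` has no data.
`D` is block-diagonal, `D = ⊕_k I_{l_k} ⊗ D_k`, with one `q_k x q_k`
within-level covariance `D_k` per grouping factor, and is parameterised
*relative to* `sigma^2` (so `D` is unitless; rescaling the response leaves
`D_hat` unchanged).

Estimation maximises the restricted likelihood (constants dropped,
`n_v = tr(M_v)` observations at the voxel):

    l_R(theta) = -1/2 [ (n_v - p) log sigma^2 + sigma^-2 e'V^-1 e
                        + log|V| + log|X'V^-1 X| ],   V = I + Z D Z'.

## Product forms

Only the six cross products `P = X'X`, `Q = X'Y`, `R = X'Z`, `S = Y'Y`,
`T = Y'Z`, `U = Z'Z` (per voxel, after zero-ing) are kept after the input
stage; every later quantity is evaluated through the Woodbury identity and
the determinant lemma:

    X'V^-1 X = P - R D (I_q + U D)^-1 R'        log|V| = log|I_q + U D|
    X'V^-1 Y = Q - R D (I_q + U D)^-1 T'        Z'V^-1 Z = (I_q + U D)^-1 U
    Y'V^-1 Y = S - T D (I_q + U D)^-1 T'        Z'V^-1 X = (I_q + U D)^-1 R'

so per-voxel memory and flops are independent of n.  Zero-ed rows
contribute nothing to any cross product, which makes the zero-ed-row model
numerically identical to deleting the rows (with `n_v` replacing `n`
everywhere); this equality is tested directly.  The forms are computed by
an image-wise map-reduce: rows are split into B nearly equal batches, each
batch produces partial forms, and a central reducer sums them in fixed
batch order.  Design-dependent forms (P, R, U) are computed once per
missingness-pattern group, keyed exactly on the pattern bytes.

Voxels with `rank(P) < p` or `rank(U) < q` (numerical rank: singular
values above `max(p,q) * eps * sigma_max`) are dropped by default.  One
caveat discovered while validating the crossed-factor generative design:
a model whose factors *both* carry intercept random effects is
structurally rank-deficient in Z (each factor's intercept columns sum to
the ones vector), so `rank(U) = q - 1` everywhere while the model itself
remains perfectly estimable (`I + UD` and `X'V^-1X` stay nonsingular).
Such designs must be run with `safe_mode` off, which keeps the voxels and
only reports the deficiency.

## Fisher scoring (FSFS)

Each iteration alternates a GLS update

    beta  <- (X'V^-1 X)^-1 X'V^-1 Y,
    sigma^2 <- e'V^-1 e / (n_v - p)        (default "reml" scale)

with one scoring step per factor on the full vectorisation of `D_k`:

    vec(D_k) <- vec(D_k) + alpha (F^k)^-1 d^k,
    F^k = sum_{i,j} B_ij ⊗ B_ij,           B_ij = Z_i' V^-1 Z_j,
    d^k = sum_j vec( sigma^-2 t_j t_j' - B_jj + C_jj ),

with `t_j = Z_j'V^-1 e` and `C_jj` the level blocks of
`Z'V^-1X (X'V^-1X)^-1 X'V^-1Z`.  `d^k` is exactly twice the gradient of
l_R in `vec(D_k)` and `F^k` twice the (simplified) expected information;
the common factor 2 cancels in the step.  The `sigma^-2` standardisation
of the residual outer product is required for the fixed point to be the
REML maximiser (verified against finite differences and against the dense
oracle).  After every step `D_k` is symmetrised and projected onto the
non-negative-definite cone by eigenvalue clipping.

Two denominators are available for the variance update: `n_v - p` (the
maximiser of l_R, the default) and `n_v` (the classical ML-flavoured GLS
update); the oracle comparisons pin the default as the one that matches
direct REML maximisation.

**Step size.** `alpha` starts at 1 each iteration and is halved (at most
20 times) while the proposed step would decrease l_R, so accepted
iterations are monotone.  The accepted step is then *refined* along the
same direction by a secant solve on the analytic directional derivative
`(1/2) score . step`.  This matters quantitatively: the plain fixed-step
scoring iteration is linearly contractive with rate roughly `1/m` (m =
observations per level — about 0.5 for a 100-level design at n = 200), so
a likelihood-difference stopping rule at 1e-10 would leave ~1e-6 parameter
error; the line refinement restores superlinear convergence for scalar
covariance blocks and brings the gap to the direct maximiser down to
~1e-10.  The refinement uses the gradient rather than likelihood values
because l_R evaluated through the product forms carries O(1e-9)
cancellation noise (S and T D (I+UD)^-1 T' are large and nearly equal),
which drowns value-based line searches near the optimum; acceptance tests
therefore also allow a noise-scaled slack of `1e-10 (1 + |l_R|)`.

**Convergence.** A voxel converges when the change in l_R between
accepted iterations falls below `tol` (default 1e-6), when the covariance
estimate stops moving (relative step below 1e-11, guarding against
evaluation-noise chatter), or when three consecutive iterations produce
no gain beyond `tol` (guarding against projection bounce at boundary
optima, where an eigenvalue of `D_hat` is clipped at zero).  Exceeding
`max_iter` (default 1e4) flags the voxel non-converged; numerical
failures flag the voxel and never abort the batch.

**Starting values.** `beta_0` is OLS (`P^-1 Q`), `sigma^2_0` the OLS
residual variance, and `D_k,0 = tau_k I` with `tau_k` the variance across
levels of the standardised level sums of OLS residuals, relative to
`sigma^2_0` and floored at 1e-6.  The oracle-equivalence suite shows the
final estimates do not depend on this choice beyond round-off.

**Vectorisation.** All operations broadcast over a voxel axis; each voxel
carries its own step size, convergence flag and (frozen) state.  For
single-factor models `U` is block-diagonal across levels, so every
`q x q` solve factors into `l` independent `q_k x q_k` solves with
closed-form 1x1/2x2 inverses — the general path and this fast path agree
to ~1e-12 and the fast path is selected automatically.

## Inference

Wald statistics use the estimated marginal covariance
`V_hat = I + Z D_hat Z'`:

    T = L beta_hat / sqrt(sigma2_hat L (X'V_hat^-1 X)^-1 L'),
    F = (L beta_hat)' [L (X'V_hat^-1 X)^-1 L']^-1 (L beta_hat)
        / (sigma2_hat rank L).

Degrees of freedom come from the Welch-Satterthwaite moment match
`v = 2 (S^2)^2 / Var(S^2)` with `S^2 = sigma^2 L (X'V^-1X)^-1 L'`.  The
gradient of `S^2` in `eta = (sigma^2, vec D_1, ..., vec D_r)` is closed
form (`dS^2/d vec D_k = sigma^2 sum_j vec(a_j' a_j)`, with
`a_j = L (X'V^-1X)^-1 X'V^-1 Z_j`), and `Var(eta_hat)` is the inverse
expected REML information assembled from the projected cross products
`Z'PZ`, `P = V^-1 - V^-1X(X'V^-1X)^-1X'V^-1` (expected, not observed,
information — consistent with the scoring machinery).  Both pieces are
validated against central finite differences; in the no-random-effects
limit the formula collapses to `v = n_v - p` exactly.  For multi-row
contrasts the denominator df combines per-eigendirection estimates by the
standard moment match `ddf = 2E/(E - rank L)`, `E = sum nu_i/(nu_i - 2)`.

T-tests are two-sided by default (configurable).  Multiple-testing
control is Bonferroni (FWE) or Benjamini-Hochberg (FDR), delegated to
statsmodels.  Random-effect inclusion is tested by a restricted-likelihood
ratio between nested single-factor fits; because the null pins variance
components to the boundary, the statistic (clipped at zero) is referred to
an even 50/50 mixture of chi-square distributions with `q - q~` and `q`
degrees of freedom, `chi^2_0` being a point mass at zero (so the p-value
at statistic 0 is 1).  Multi-factor LRT comparisons are rejected with an
explanatory error.

## Independent oracle

`voxlmm.oracle` maximises the same restricted likelihood by direct search
over dense `V = I + ZDZ'`: beta and sigma^2 are profiled in closed form,
and `D` is optimised over a log-Cholesky parameterisation (feasible by
construction — no projections, so the oracle shares no machinery with the
scoring path).  Scalar-covariance problems are solved by a log-grid
bracket plus Brent root solve on the dense analytic derivative, reaching
~1e-12 parameter accuracy; other designs use multi-start L-BFGS-B.  A
vectorised spectral variant (`scalar_reml_batch`) evaluates the identical
dense criterion through the eigendecomposition of `Z_v Z_v'` per
missingness-pattern group and locates the maximiser by 60 bisection steps
on the derivative sign — this is what makes oracle comparison over every
voxel of a whole image feasible.

## Synthetic data

The simulator reproduces three generative designs: (1) one factor, one
random intercept, 100 levels; (2) one factor, intercept + slope, 50
levels; (3) two crossed factors, 20 x 2 effects and 10 x 1 effect.
Defaults: `beta = [4, 3, 2, 1, 0]'`, `sigma^2 = 1`, within-level
covariance with unit diagonal and 0.5 off-diagonal, uniform[-0.5, 0.5]
regressors (first random effect an intercept), volumes of 100^3 voxels.
Tests and the acceptance runs override only the grid (16^3 / 12^3), the
number of instances (10 / 25) and, where noted, the level counts; these
sizes were chosen so the whole validation battery runs on a single
workstation core in minutes while leaving hundreds of voxels and tens of
levels per fit.

Levels are assigned by a balanced random permutation (marginally uniform,
level sizes within 1).  Pure iid assignment cannot realise the stated
designs: at n = 200 over 100 levels ~13 levels would be empty, and in the
two-effect design ~9% of levels would hold fewer than two observations,
making `Z'Z` singular at every voxel.

Per voxel, `b` and `eps` are drawn independently across voxels (Gaussian
fields), the response volumes are smoothed with an isotropic Gaussian
kernel of FWHM 5 voxels (`sigma = FWHM / 2.3548`), and each image is then
masked.  Because smoothing scales the `b` and `eps` fields by the same
kernel, the *sigma^2-relative* covariance `D` of the smoothed data is
unchanged — which is why recovery of `D` (and of `beta`, which smoothing
leaves in place) remains a meaningful check on smoothed responses, while
`sigma^2` itself shrinks by the kernel's variance-reduction factor and is
not a recovery target.

The analysis mask is a centred ellipsoid (semi-axes 0.475 of each
dimension, ~45% of the volume) standing in for a brain mask.  Per-image
masks drop each voxel of the two-layer boundary shell with probability
0.1 per image, using a smoothed (spatially contiguous) Gaussian field
thresholded at its upper decile — edge-of-brain missingness with
controllable severity; deep-interior voxels are never dropped.  With the
default 50% missingness threshold this leaves partial-missingness voxels
in the analysis rather than removing the whole shell.

What the simulator does *not* emulate: physiological or scanner artefact
structure, spatially varying effect sizes, non-Gaussian noise, and the
spatial covariance of `b`/`eps` after smoothing is not characterised —
so passing recovery tests speak to estimator correctness under the stated
model, not to robustness on real fMRI data.

## Numerical choices

- Linear systems: stacked LAPACK solves; symmetric systems retried once
  with `1e-10 * trace` diagonal jitter, then isolated per voxel (NaN +
  flag) rather than aborting the batch.
- `log|I + UD|` via LU `slogdet`; non-positive determinants flag the
  voxel.
- Rank decisions use SVD with tolerance `max(p, q) * eps * sigma_max`.
- Reduction over image batches is sequential in fixed batch order, so a
  fixed configuration reproduces bitwise; changing B changes float
  summation order and reproduces to ~1e-12 (forms) / ~1e-6 (estimates).
- The NND projection symmetrises before eigendecomposition and is
  idempotent on the feasible set.

## Known limitations

- The LRT applies only to nested single-factor model pairs, as designed.
- Boundary voxels (clipped `D_hat` eigenvalues) converge to the
  constrained optimum; their agreement with unconstrained-interior oracle
  solutions is necessarily looser, mirroring the larger reported
  differences for the multi-effect designs.
- The multi-row-contrast denominator df uses the eigendirection moment
  combination; other software makes different choices and small
  differences are expected there.
- Image-wise batching re-reads images once per stage; for datasets far
  larger than memory this trades I/O for the O(n/B) memory bound.
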