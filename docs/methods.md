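# Methods

## Model

Topographic factor analysis (TFA) treats an fMRI session as an exchangeable
set of N brain images over V voxels and explains the N × V activation
matrix **Y** as a noisy weighted sum of K latent spatial *sources*:

    Y ≈ W F,     y_nv ~ N( (W F)_nv , σ² )

Each source k is an isotropic Gaussian radial basis function (RBF) with
center μ_k ∈ ℝ^D (D = 2 or 3, same units as the voxel coordinates) and log
width λ_k:

    F_kv = exp( −‖r_v − μ_k‖² / exp(λ_k) )

so exp(λ_k) is the squared length scale of the source's spatial falloff and
exp(λ_k/2) is the distance at which activation drops to e^(−1). W is the
N × K matrix of per-image source activations. Gaussian priors complete the
model: centers ~ N(c, diag(Σ)) with c the centroid of the masked voxel
cloud and Σ the per-dimension coordinate variances (so the prior covers the
imaged volume), log widths ~ N(1, s²_λ), weights ~ N(0, s²_w) i.i.d.

All Gaussian scale parameters in the package are carried as **log
precisions** (variance = exp(−log precision)); this keeps every parameter
unconstrained, which matters for the stochastic optimizer below. Sources
may sit outside the brain mask; a wide source just outside a cortical patch
explains it as well as one inside, so a source should be read as the set of
structures it spreads mass over, not as a point.

### Default hyperparameters

| parameter | default | notes |
|---|---|---|
| voxel noise | 0.1 (standard deviation) | interpretation configurable (`voxel_noise_is` ∈ std/variance/precision) because conventions differ across implementations |
| weight prior | N(0, 2²) | broad relative to standardized BOLD units |
| log-width prior | N(1, 2²) | broad; mean squared length scale e ≈ 2.7 coordinate units² |
| center prior | N(centroid, coord variances) | computed from the dataset |

The weight and log-width prior standard deviations are set to 2 — roughly
twice the data/coordinate scale — deliberately broad so the likelihood
dominates.

## Inference

The posterior over {W, μ, λ} is approximated by a fully factorized
(mean-field) Gaussian family: one (mean, log precision) pair per scalar
latent variable. The evidence lower bound (ELBO) is maximized by black-box
stochastic gradient ascent using the score-function estimator

    ∇_αᵢ ELBO ≈ (1/M) Σ_m ∇_αᵢ log q(ξ_m) · [ log p(ξ_m, Y) − log q(ξ_m) ]

with M = 500 joint draws per outer iteration (one batch shared by all
parameter updates in that iteration). The Gaussian factor scores are
analytic: ∂/∂mean = e^λ (x − mean), ∂/∂λ = ½ − ½ e^λ (x − mean)²; both are
verified against finite differences in the test suite.

Three standard variance-reduction / adaptation devices are used:

- **Control variates.** The score h itself has mean zero, so h·f − a*·h has
  the same expectation for any a*; the variance-optimal
  a* = Cov(h f, h)/Var(h) is estimated per parameter coordinate from the
  same batch (coordinates with Var(h) = 0 pass through unadjusted).
- **Rao-Blackwellization over the factorization.** Each factor's score is
  paired only with the log-density terms its latent variable appears in:
  a weight factor sees its own image's likelihood plus its own prior and
  entropy; center/width factors see the likelihood plus the global
  prior/entropy terms. Terms outside a factor's scope are independent of
  its score, so dropping them leaves the estimator's expectation unchanged
  while removing most of its variance — without it the weight log-precision
  updates crawl (cross-image noise poisons the AdaGrad accumulators).
- **AdaGrad learning rates** per parameter: rate = η/(δ + √Σ g²) with
  η = maxStepSize = 1 and δ = 10⁻⁶; every step is additionally clipped at
  ±maxStepSize per coordinate.

### Subsampling

Each outer iteration draws a fresh uniform subset of N′ = min(100, N)
images and a *contiguous* subset of V′ = min(1000, V) voxels, realized as
the V′ Euclidean-nearest voxels to a uniformly drawn seed voxel (respects
arbitrary mask shapes). The weight-prior/entropy sums are scaled by N/N′
and the likelihood by (N/N′)(V/V′), which keeps every stochastic quantity
an unbiased estimate of its full-data counterpart (verified by simulation
in the tests).

### Weight re-solve

After the global (center/width) updates of each iteration, the subsampled
images' weight means are re-solved exactly as the conditional MAP given the
current source point estimates:

    W = Y Fᵀ (F Fᵀ + σ² τ_w I)⁻¹

where τ_w is the weight prior precision. The ridge term coincides with
plain regression whenever the basis is well conditioned, but stays finite
when two sources transiently collapse onto each other during the noisy
early iterations — with plain least squares a singular Gram matrix produces
astronomically large weights and the objective overflows. The public
`solve_weights` operation used for initialization and analysis remains
exact ordinary least squares (with a pseudoinverse fallback and warning for
exactly rank-deficient bases).

### Convergence, divergence, and the final update

The per-iteration ELBO estimate is smoothed over a 25-iteration window;
the fit stops when the smoothed value changes by less than a relative
tolerance of 10⁻⁴ between consecutive windows, or at the iteration cap.
A divergence guard aborts when the smoothed ELBO falls more than
`divergence_factor` (default 5) times max(|best smoothed value|, recent
trace spread, 1) below its best value; the spread term is needed because
the estimate varies strongly across contiguous-voxel-neighborhood draws and
a tighter guard misfires on healthy fits.

Because image subsampling may never visit some images, a **final update**
freezes the global parameters, uses all images and all voxels, sets every
weight mean to the (ridge) regression solution, and iterates score-gradient
updates of the weight log precisions until the largest step falls below a
tolerance. On a frozen-source instance this converges to the exact Gaussian
posterior (mean error ~10⁻¹⁴, variance error < 0.1%; the mean is exact
because the ridge solve *is* the conjugate posterior mean).

## Initialization

**Hotspot initialization** works on the mean image: subtract its scalar
mean, take absolute values ("fold"), then repeat K times: place a center at
the peak voxel of the current residual (ties → lowest voxel index), fit the
log width by bounded scalar least squares with the amplitude pinned to the
peak value (search range [log(0.25 s²), log(4 · span²)], s = voxel spacing,
span = bounding-box diagonal), subtract the amplitude-scaled source image,
and continue on the residual as-is (no re-folding; subtraction may leave a
negative "hole"). Weight means then come from ordinary least squares of all
images against the resulting basis, per image.

Two pragmatic refinements, both optional and on by default:

- **Local polish (`refine=True`).** Snapping centers to voxels leaves a
  dipole artifact after subtraction (the misalignment residual can reach
  ~40% of the source amplitude), which can outrank genuinely fainter
  hotspots and make all K placements pile onto one dominant blob. Each
  placed source is therefore re-fit continuously — center within ±2 voxel
  spacings of the peak, log width within its bounds, amplitude within
  [0.2, 2] × the peak value — by bounded least squares before subtraction.
  `refine=False` reproduces the plain peak-voxel procedure.
- **Subset restarts (`restarts=R`).** A source whose weights average to
  ≈0 across all images leaves *no trace* in the full mean image (the weight
  prior is zero-mean, so this happens regularly). The mean over a random
  image subset, however, fluctuates away from zero. With R > 1 additional
  hotspot candidates are computed from random image subsets (fractions 1/2,
  1/4, 1/10 cycling) and the candidate with the smallest full-data
  reconstruction error — the dominant ELBO term at initialization — is
  kept. This is the package's best-of-R-restarts helper.

Initial log precisions: weight factors start at their *conditional
posterior precision* given the initial sources (log(τ_w + Σ_v F²_kv/σ²)),
which is both the statistically correct local factor for regression-solved
means and ~2 orders of magnitude less gradient noise than a generic broad
value; center factors start at one voxel spacing of standard deviation and
log-width factors at sd ≈ 0.3. All are overridable.

**Random initialization** draws all means from the prior by running the
generative process once.

## Networks and reliability

The K × K covariance of the weight matrix across a set of images is the
source-interaction network (positive = excitatory, negative = inhibitory
reading). Per-condition networks use the images of one condition.
Split-half reliability: per-condition networks are built separately from
odd and even epochs; the confusion matrix entry (i, j) is the Pearson
correlation between the vectorized strict upper triangles of condition i's
odd network and condition j's even network; the observed statistic is a
Welch two-sample t comparing diagonal vs off-diagonal confusion entries;
the null distribution comes from uniformly permuting the confusion matrix's
rows (columns fixed), with the one-sided, +1-smoothed
p = (1 + #{t_perm ≥ t_obs})/(1 + n_permutations). Multi-participant
aggregation averages the confusion matrices element-wise and repeats the
same test. Percentile thresholding of networks is visualization-only and
never precedes the statistics.

## Model selection

Cross-validation scores how well sources fitted on out-of-fold images
predict the across-image covariance of *held-out voxels*: per fold, sources
are fit to out-of-fold images; voxels are split into two random halves;
in-fold weights are solved by plain per-image least squares on one half;
the sources are evaluated at the other half's coordinates to predict its
activations; the score is the Pearson correlation between observed and
predicted across-image covariance matrices of the held-out voxels
(all entries by default, strict-upper-triangle optional). Six folds × two
voxel groups give 12 scores per candidate K; the summary is the median
with a 10 000-resample percentile bootstrap 95% CI; K* is the argmax median
(ties → smallest; a still-rising curve at the top of the grid warns).
The held-out weight solve is deliberately *unregularized*: redundant
sources inflate the weight-estimate variance, and that inflation is exactly
the overfitting cost the procedure is meant to expose — a prior-matched
ridge solve shrinks surplus sources toward zero and flattens the selection
curve into a plateau.

## Synthetic data

The generator runs the model's own generative process and stores the
ground truth. Defaults are chosen once to represent realistic study
conditions:

- `generate_tfa_dataset(K, N, grid, snr, seed, separated)` — noise variance
  set so var(W F)/σ² equals the requested SNR (the bundle carries the
  realized σ² so downstream likelihoods are calibrated). The generator's
  log-width prior uses sd 0.5 (not the deliberately broad inference prior,
  which generates sources wider than a desk-scale grid). `separated=True`
  means *recoverable* truth: pairwise center gaps of at least twice the
  mean source width exp(λ/2), and all centers inside the voxel bounding
  box; centers are placed by sequential rejection.
- `generate_condition_dataset` — condition c draws weights from
  N(0, base·I + effect · u_c u_cᵀ) with u_c a random unit vector (positive
  definite by construction; effect = 0 is the exchangeable null of the
  permutation test). Epochs are assigned round-robin within condition.
  This low-rank covariance construction is test scaffolding, not a claim
  about real condition structure.
- `generate_fig4_demo` — a 40 × 40 2-D image set built from 25 sources on
  a jittered 5 × 5 lattice with alternating-sign weight means, for the
  hotspot-initialization demonstrations.

What the generator does *not* emulate: hemodynamic response dynamics,
temporal autocorrelation between images, spatially correlated noise, and
irregularly shaped activation patches. Passing the recovery tests therefore
shows the estimator is correct under the model's own assumptions, not that
real fMRI sources are spherical RBFs.

## Validation sizes and observed behavior

The test suite and `scripts/acceptance.py` run everything at desk scale,
sizes chosen so the full pipeline exercises every code path on one CPU:

- parameter recovery: K = 3 separated sources on a 10 × 10 × 5 grid
  (V = 500), N = 100, SNR = 5, 16 init restarts, M = 500, up to 250
  iterations, 5 replicates — median matched-center error ≈ 0.02–0.3 voxel
  spacings and weight-truth correlation > 0.99.
- model selection: K_true = 3 on a 10 × 10 grid, N = 60, SNR = 1 (single
  fMRI images are noisy; with much higher SNR extra sources cost so little
  that the selection curve plateaus and selection is uninformative),
  K grid {1, 2, 3, 5, 8}, light fits (10 iterations, M = 100) — the median
  curve peaks in {2, 3, 4} in ≥ 4/5 replicates.
- permutation test: 200 null replicates (effect 0) for the type-I rate;
  power at the generator's large effect (effect 4, six conditions of 120
  images, K = 5) — type-I ≈ 0.04, power 1.0.
- conjugate oracle: V = 36, N = 5, weight log precisions started 1.5 below
  the posterior value — recovered within 0.1%.

## Known limitations

- Score-function gradients remain noisy for global parameters; a source
  placed far from any unexplained activation feels essentially no gradient,
  so initialization quality (and the subset restarts) carries real weight.
  A genuinely invisible source — weights averaging ≈ 0 in *every* subset —
  is unrecoverable by the mean-image initialization, and such replicates
  fail recovery; this is a property of the procedure, not a bug.
- AdaGrad's first step is always ±maxStepSize per coordinate (accumulators
  start at zero), so the first iterations random-walk slightly before the
  rates decay; with well-initialized weight precisions this is harmless.
- The mean-field family cannot represent posterior correlations between
  sources (e.g., the anti-correlation of two overlapping sources' weights);
  variances are per-coordinate.
- Images are treated as exchangeable; no temporal model.
- Spherical sources only; ellipsoidal or mixture source shapes are out of
  scope.
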