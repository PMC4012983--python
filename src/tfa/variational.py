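"""Black-box stochastic variational inference for the TFA model.

The posterior over source centers, log widths and per-image weights is
approximated by a fully factorized (mean-field) Gaussian family; each latent
variable carries one variational mean and one variational log precision.
The evidence lower bound (ELBO) is maximized by stochastic gradient ascent
using the score-function (REINFORCE) estimator

    grad_i ELBO ~= (1/M) sum_m  d/d(alpha_i) log q(xi_m) * [log p(xi_m, Y) - log q(xi_m)]

with the score itself used as a control variate (optimal coefficient
estimated per parameter from the same batch), Rao-Blackwellization over the
mean-field factorization (each factor's score is paired only with the
log-density terms its latent appears in), per-parameter AdaGrad learning
rates, and stochastic subsampling of both images and (contiguous) voxels.
Per-image weight means are re-solved as the conditional MAP (prior-matched
ridge regression) after every update of the global source parameters, which
keeps the local parameters at a conditional optimum throughout the fit.  A
final full-data pass updates the weight parameters of every image with the
sources frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    LOG_2PI,
    Hyperparameters,
    ImageDataset,
    SourceSet,
    _basis,
    _resolve_subset,
    gaussian_logpdf,
)

__all__ = [
    "VariationalState",
    "LatentSample",
    "LatentSamples",
    "FitConfig",
    "FitResult",
    "FitDivergedError",
    "sample_q",
    "log_q",
    "elbo_estimate",
    "score_gradient",
    "flatten_gradient",
    "control_variate_adjust",
    "adagrad_rate",
    "contiguous_voxel_subset",
    "fit",
    "final_update",
]

#: variational parameter groups, in flattening order
PARAM_GROUPS = (
    "weight_mean",
    "weight_log_precision",
    "center_mean",
    "center_log_precision",
    "width_mean",
    "width_log_precision",
)

GLOBAL_GROUPS = ("center_mean", "center_log_precision", "width_mean", "width_log_precision")


class FitDivergedError(RuntimeError):
    """Raised when the smoothed ELBO trace collapses during optimization."""


@dataclass
class VariationalState:
    """Means and log precisions of every mean-field Gaussian factor.

    Shapes: weight parameters are (N, K); center parameters (K, D); width
    parameters (K,).  ``grad_sq`` holds the per-parameter AdaGrad
    accumulators (same shapes), and ``iteration`` counts outer updates.
    """

    weight_mean: np.ndarray
    weight_log_precision: np.ndarray
    center_mean: np.ndarray
    center_log_precision: np.ndarray
    width_mean: np.ndarray
    width_log_precision: np.ndarray
    grad_sq: dict = field(default_factory=dict)
    iteration: int = 0

    def __post_init__(self):
        self.weight_mean = np.atleast_2d(np.asarray(self.weight_mean, dtype=float))
        self.weight_log_precision = np.atleast_2d(
            np.asarray(self.weight_log_precision, dtype=float)
        )
        self.center_mean = np.atleast_2d(np.asarray(self.center_mean, dtype=float))
        self.center_log_precision = np.atleast_2d(
            np.asarray(self.center_log_precision, dtype=float)
        )
        self.width_mean = np.atleast_1d(np.asarray(self.width_mean, dtype=float))
        self.width_log_precision = np.atleast_1d(
            np.asarray(self.width_log_precision, dtype=float)
        )
        n, k = self.weight_mean.shape
        if self.weight_log_precision.shape != (n, k):
            raise ValueError("weight mean/log-precision shape mismatch")
        if self.center_mean.shape[0] != k or self.center_log_precision.shape != self.center_mean.shape:
            raise ValueError("center parameter shape mismatch")
        if self.width_mean.shape != (k,) or self.width_log_precision.shape != (k,):
            raise ValueError("width parameter shape mismatch")
        for name in PARAM_GROUPS:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")

    @property
    def n_images(self) -> int:
        return self.weight_mean.shape[0]

    @property
    def n_sources(self) -> int:
        return self.weight_mean.shape[1]

    @property
    def n_dims(self) -> int:
        return self.center_mean.shape[1]

    @property
    def n_parameters(self) -> int:
        return sum(getattr(self, g).size for g in PARAM_GROUPS)

    def copy(self) -> "VariationalState":
        return VariationalState(
            weight_mean=self.weight_mean.copy(),
            weight_log_precision=self.weight_log_precision.copy(),
            center_mean=self.center_mean.copy(),
            center_log_precision=self.center_log_precision.copy(),
            width_mean=self.width_mean.copy(),
            width_log_precision=self.width_log_precision.copy(),
            grad_sq={k: v.copy() for k, v in self.grad_sq.items()},
            iteration=self.iteration,
        )

    def point_sources(self) -> SourceSet:
        """Point estimate of the sources: the variational means."""
        return SourceSet(self.center_mean.copy(), self.width_mean.copy())


@dataclass
class LatentSample:
    """One joint draw from q: per-image weights plus (optionally) globals."""

    weights: np.ndarray
    centers: Optional[np.ndarray] = None
    log_widths: Optional[np.ndarray] = None


class LatentSamples(Sequence):
    """A batch of M mean-field draws, stored as stacked arrays.

    ``weights`` has shape (M, N', K).  When ``globals_sampled`` is False the
    batch represents a weights-only draw with the sources held at their
    variational means (centers/log_widths are None); this is the regime of
    the final full-data update.
    """

    def __init__(self, weights, centers, log_widths, image_subset):
        self.weights = weights
        self.centers = centers
        self.log_widths = log_widths
        self.image_subset = image_subset

    @property
    def globals_sampled(self) -> bool:
        return self.centers is not None

    def __len__(self) -> int:
        return self.weights.shape[0]

    def __getitem__(self, m) -> LatentSample:
        if isinstance(m, slice):
            raise TypeError("slicing a sample batch is not supported")
        return LatentSample(
            weights=self.weights[m],
            centers=None if self.centers is None else self.centers[m],
            log_widths=None if self.log_widths is None else self.log_widths[m],
        )


@dataclass
class FitConfig:
    """Settings for the stochastic fit.

    ``n_samples`` is the Monte-Carlo batch size M per outer iteration
    (default 500).  ``image_subsample`` / ``voxel_subsample`` default to
    min(100, N) and min(1000, V).  Steps are clipped per coordinate at
    ``max_step_size`` (default 1).  Convergence is declared when the
    moving-average ELBO (window ``elbo_window``) changes by less than
    ``elbo_tol`` in relative terms; a collapse of the smoothed ELBO by more
    than ``divergence_factor`` (relative) aborts the fit.
    """

    n_sources: int = 1
    n_samples: int = 500
    image_subsample: Optional[int] = None
    voxel_subsample: Optional[int] = None
    max_step_size: float = 1.0
    adagrad_delta: float = 1e-6
    elbo_tol: float = 1e-4
    elbo_window: int = 25
    max_iters: int = 500
    final_max_iters: int = 200
    final_tol: float = 1e-3
    divergence_factor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 (control variates need 2 samples)")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.max_step_size <= 0:
            raise ValueError("max_step_size must be positive")

    def resolve_subsamples(self, n_images: int, n_voxels: int) -> tuple[int, int]:
        n_sub = self.image_subsample if self.image_subsample is not None else min(100, n_images)
        v_sub = self.voxel_subsample if self.voxel_subsample is not None else min(1000, n_voxels)
        n_sub = int(min(max(n_sub, 1), n_images))
        v_sub = int(min(max(v_sub, 1), n_voxels))
        return n_sub, v_sub


@dataclass
class FitResult:
    state: VariationalState
    elbo_trace: np.ndarray
    final_trace: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def sources(self) -> SourceSet:
        return self.state.point_sources()

    @property
    def weights(self) -> np.ndarray:
        return self.state.weight_mean


# ---------------------------------------------------------------------------
# Sampling from and scoring the variational distribution
# ---------------------------------------------------------------------------

def sample_q(
    state: VariationalState,
    M: int,
    image_subset=None,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    sample_globals: bool = True,
) -> LatentSamples:
    """Draw M independent joint samples from the mean-field family."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    img = _resolve_subset(image_subset, state.n_images, "image")
    wm = state.weight_mean[img]
    w_sd = np.exp(-0.5 * state.weight_log_precision[img])
    weights = wm + w_sd * rng.standard_normal((M,) + wm.shape)
    if sample_globals:
        c_sd = np.exp(-0.5 * state.center_log_precision)
        centers = state.center_mean + c_sd * rng.standard_normal(
            (M,) + state.center_mean.shape
        )
        lw_sd = np.exp(-0.5 * state.width_log_precision)
        log_widths = state.width_mean + lw_sd * rng.standard_normal(
            (M,) + state.width_mean.shape
        )
    else:
        centers = None
        log_widths = None
    return LatentSamples(weights, centers, log_widths, img)


def _log_q_batch(
    state: VariationalState,
    samples: LatentSamples,
    weight_scale: float = 1.0,
) -> np.ndarray:
    """Per-sample log q, with the weight factors scaled by N/N'."""
    img = samples.image_subset
    lq = weight_scale * np.sum(
        gaussian_logpdf(
            samples.weights, state.weight_mean[img], state.weight_log_precision[img]
        ),
        axis=(1, 2),
    )
    if samples.globals_sampled:
        lq = lq + np.sum(
            gaussian_logpdf(samples.centers, state.center_mean, state.center_log_precision),
            axis=(1, 2),
        )
        lq = lq + np.sum(
            gaussian_logpdf(samples.log_widths, state.width_mean, state.width_log_precision),
            axis=1,
        )
    return lq


def log_q(state: VariationalState, sample: LatentSample, image_subset=None) -> float:
    """Log density of one joint draw under the factorized family."""
    img = _resolve_subset(image_subset, state.n_images, "image")
    if sample.weights.shape != (img.size, state.n_sources):
        raise ValueError(
            f"sample weights shape {sample.weights.shape} does not match "
            f"subset ({img.size}, {state.n_sources})"
        )
    total = float(
        np.sum(
            gaussian_logpdf(
                sample.weights, state.weight_mean[img], state.weight_log_precision[img]
            )
        )
    )
    if sample.centers is not None:
        if sample.centers.shape != state.center_mean.shape:
            raise ValueError("sample centers shape mismatch")
        total += float(
            np.sum(
                gaussian_logpdf(sample.centers, state.center_mean, state.center_log_precision)
            )
        )
    if sample.log_widths is not None:
        total += float(
            np.sum(
                gaussian_logpdf(
                    sample.log_widths, state.width_mean, state.width_log_precision
                )
            )
        )
    return total


# ---------------------------------------------------------------------------
# Per-sample joint / ELBO machinery
# ---------------------------------------------------------------------------

class _SampleTerms:
    """Per-sample decomposition of log p - log q over the factorization.

    Holds per-image likelihoods (M, N'), per-element weight prior and
    entropy terms (M, N', K), and scalar global prior/entropy terms (M,),
    together with the N/N' and V/V' subsampling scales.  This is what makes
    Rao-Blackwellized per-factor gradient targets cheap: each mean-field
    factor's score is paired only with the terms its latent touches.
    """

    __slots__ = (
        "lik_per_image", "weight_prior", "weight_logq",
        "global_prior", "global_logq", "n_scale", "v_scale",
    )

    def __init__(self, lik_per_image, weight_prior, weight_logq,
                 global_prior, global_logq, n_scale, v_scale):
        self.lik_per_image = lik_per_image
        self.weight_prior = weight_prior
        self.weight_logq = weight_logq
        self.global_prior = global_prior
        self.global_logq = global_logq
        self.n_scale = n_scale
        self.v_scale = v_scale

    def total(self) -> np.ndarray:
        """Unbiased per-sample estimate of the full-data log p - log q."""
        out = self.global_prior - self.global_logq
        out = out + self.n_scale * np.sum(
            self.weight_prior - self.weight_logq, axis=(1, 2)
        )
        if self.lik_per_image is not None:
            out = out + self.n_scale * self.v_scale * self.lik_per_image.sum(axis=1)
        return out

    def weight_target(self) -> np.ndarray:
        """(M, N', K) per-factor target for weight-parameter scores."""
        t = self.weight_prior - self.weight_logq
        if self.lik_per_image is not None:
            t = t + self.v_scale * self.lik_per_image[:, :, None]
        return self.n_scale * t

    def global_target(self) -> np.ndarray:
        """(M,) target for source center/width scores."""
        out = self.global_prior - self.global_logq
        if self.lik_per_image is not None:
            out = out + self.n_scale * self.v_scale * self.lik_per_image.sum(axis=1)
        return out


def _sample_terms(
    state: VariationalState,
    data: ImageDataset,
    hyper: Hyperparameters,
    samples: LatentSamples,
    voxel_subset=None,
    include_likelihood: bool = True,
) -> _SampleTerms:
    """Evaluate every factor's log densities for a batch of samples."""
    img = samples.image_subset
    vox = _resolve_subset(voxel_subset, data.n_voxels, "voxel")
    n_scale = data.n_images / img.size
    v_scale = data.n_voxels / vox.size
    hyper = hyper.require_center_prior(data.n_dims)
    m = len(samples)

    if samples.globals_sampled:
        centers, log_widths = samples.centers, samples.log_widths
        global_prior = np.sum(
            gaussian_logpdf(centers, hyper.center_mean, hyper.center_log_precision_diag),
            axis=(1, 2),
        ) + np.sum(
            gaussian_logpdf(log_widths, hyper.width_mean, hyper.width_log_precision),
            axis=1,
        )
        global_logq = np.sum(
            gaussian_logpdf(centers, state.center_mean, state.center_log_precision),
            axis=(1, 2),
        ) + np.sum(
            gaussian_logpdf(log_widths, state.width_mean, state.width_log_precision),
            axis=1,
        )
    else:
        # sources pinned at their variational means: constant prior, no entropy
        centers, log_widths = state.center_mean, state.width_mean
        const = float(
            np.sum(
                gaussian_logpdf(centers, hyper.center_mean, hyper.center_log_precision_diag)
            )
            + np.sum(
                gaussian_logpdf(log_widths, hyper.width_mean, hyper.width_log_precision)
            )
        )
        global_prior = np.full(m, const)
        global_logq = np.zeros(m)

    weight_prior = gaussian_logpdf(
        samples.weights, hyper.weight_mean, hyper.weight_log_precision
    )
    weight_logq = gaussian_logpdf(
        samples.weights, state.weight_mean[img], state.weight_log_precision[img]
    )

    lik = None
    if include_likelihood:
        y = data.activations[np.ix_(img, vox)]
        coords_sub = data.coords[vox]
        var = hyper.noise_variance
        w = samples.weights
        yss = np.sum(y * y, axis=1)  # (N',)
        if samples.globals_sampled:
            f_b = _basis(centers, log_widths, coords_sub)  # (M, K, V')
            cross = np.einsum("mnk,mkn->mn", w, np.einsum("mkv,nv->mkn", f_b, y))
            h_mat = np.einsum("mkv,mlv->mkl", f_b, f_b)
            quad = np.einsum("mnk,mkl,mnl->mn", w, h_mat, w)
        else:
            f_fix = _basis(centers, log_widths, coords_sub)  # (K, V')
            cross = np.einsum("mnk,kn->mn", w, f_fix @ y.T)
            h_mat = f_fix @ f_fix.T
            quad = np.einsum("mnk,kl,mnl->mn", w, h_mat, w)
        ssr = yss - 2.0 * cross + quad  # (M, N')
        count = vox.size
        lik = -0.5 * count * (LOG_2PI + math.log(var)) - ssr / (2.0 * var)

    return _SampleTerms(lik, weight_prior, weight_logq, global_prior, global_logq,
                        n_scale, v_scale)


def _per_sample_f(
    state: VariationalState,
    data: ImageDataset,
    hyper: Hyperparameters,
    samples: LatentSamples,
    voxel_subset=None,
    include_likelihood: bool = True,
) -> np.ndarray:
    """log p(xi, Y) - log q(xi) for every sample, with subsampling scalings.

    The weight-prior, likelihood and weight-entropy sums are scaled by N/N'
    (and the likelihood additionally by V/V') so each entry is an unbiased
    estimate of the full-data integrand.
    """
    return _sample_terms(
        state, data, hyper, samples, voxel_subset=voxel_subset,
        include_likelihood=include_likelihood,
    ).total()


def elbo_estimate(
    state: VariationalState,
    data: ImageDataset,
    hyper: Hyperparameters,
    n_samples: int = 500,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    image_subset=None,
    voxel_subset=None,
    include_likelihood: bool = True,
    sample_globals: bool = True,
) -> float:
    """Monte-Carlo ELBO: mean of log p - log q over draws from q."""
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = sample_q(
        state, n_samples, image_subset=image_subset, rng=rng, sample_globals=sample_globals
    )
    f = _per_sample_f(
        state, data, hyper, samples, voxel_subset=voxel_subset,
        include_likelihood=include_likelihood,
    )
    return float(f.mean())


# ---------------------------------------------------------------------------
# Gradient estimation
# ---------------------------------------------------------------------------

def control_variate_adjust(per_sample_score, per_sample_h):
    """Subtract the optimally scaled score from a per-sample gradient term.

    ``per_sample_score`` is the raw integrand h*f and ``per_sample_h`` the
    score h (both with samples along axis 0).  Returns the adjusted
    per-sample values and the coefficient a* = Cov(h f, h) / Var(h),
    computed per parameter coordinate from the same batch.  Since E[h] = 0,
    the adjustment leaves the estimator's expectation unchanged.  Coordinates
    with Var(h) = 0 are passed through with a* = 0.
    """
    s = np.asarray(per_sample_score, dtype=float)
    h = np.asarray(per_sample_h, dtype=float)
    if s.shape != h.shape:
        raise ValueError("score and h must have matching shapes")
    m = s.shape[0]
    if m < 2:
        raise ValueError("control variates need at least 2 samples")
    hc = h - h.mean(axis=0)
    sc = s - s.mean(axis=0)
    var_h = np.sum(hc * hc, axis=0) / (m - 1)
    cov = np.sum(sc * hc, axis=0) / (m - 1)
    safe = np.where(var_h > 0, var_h, 1.0)
    a = np.where(var_h > 0, cov / safe, 0.0)
    return s - a * h, a


def _score_arrays(state: VariationalState, samples: LatentSamples) -> dict:
    """Per-sample scores d log q / d alpha for every factor in the batch."""
    img = samples.image_subset
    out = {}
    wm = state.weight_mean[img]
    wp = np.exp(state.weight_log_precision[img])
    dev = samples.weights - wm
    out["weight_mean"] = wp * dev
    out["weight_log_precision"] = 0.5 - 0.5 * wp * dev ** 2
    if samples.globals_sampled:
        cp = np.exp(state.center_log_precision)
        cdev = samples.centers - state.center_mean
        out["center_mean"] = cp * cdev
        out["center_log_precision"] = 0.5 - 0.5 * cp * cdev ** 2
        lwp = np.exp(state.width_log_precision)
        ldev = samples.log_widths - state.width_mean
        out["width_mean"] = lwp * ldev
        out["width_log_precision"] = 0.5 - 0.5 * lwp * ldev ** 2
    return out


def _adjusted_group_gradients(scores: dict, terms: _SampleTerms,
                              rao_blackwellize: bool = True) -> dict:
    """Control-variate-adjusted gradient per parameter group.

    With ``rao_blackwellize`` each mean-field factor's score is paired only
    with the log-density terms its latent variable appears in (its image's
    likelihood plus its own prior and entropy for weights; the likelihood
    plus global prior/entropy for centers and widths).  Terms outside a
    factor's scope have zero expectation against its score, so dropping
    them preserves the estimator's mean while removing most of its
    variance.  With ``rao_blackwellize=False`` every score is paired with
    the full log p - log q.
    """
    f_total = terms.total()
    w_target = terms.weight_target() if rao_blackwellize else None
    g_target = terms.global_target() if rao_blackwellize else f_total
    grads = {}
    for name, h in scores.items():
        if name.startswith("weight"):
            t = w_target if rao_blackwellize else f_total.reshape(-1, 1, 1)
        else:
            t = g_target.reshape((-1,) + (1,) * (h.ndim - 1))
        adjusted, _ = control_variate_adjust(h * t, h)
        grads[name] = adjusted.mean(axis=0)
    return grads


def score_gradient(
    state: VariationalState,
    data: ImageDataset,
    hyper: Hyperparameters,
    samples: LatentSamples,
    voxel_subset=None,
    rao_blackwellize: bool = True,
) -> dict:
    """Control-variate-adjusted score-function gradient of the ELBO.

    Each entry estimates E_q[ d log q/d alpha * (log p - log q) ] for its
    parameter group; by default the pairing is Rao-Blackwellized over the
    mean-field factorization (see ``_adjusted_group_gradients``), which
    leaves the expectation unchanged.  Weight gradients cover only the
    images in the sample batch's subset.  Requires at least two samples.
    """
    if len(samples) < 2:
        raise ValueError("score_gradient needs at least 2 samples")
    terms = _sample_terms(state, data, hyper, samples, voxel_subset=voxel_subset)
    scores = _score_arrays(state, samples)
    return _adjusted_group_gradients(scores, terms, rao_blackwellize)


def flatten_gradient(grads: dict) -> np.ndarray:
    """Concatenate group gradients in canonical order into one vector."""
    return np.concatenate([np.ravel(grads[g]) for g in PARAM_GROUPS if g in grads])


def adagrad_rate(grad_sq_accumulator, max_step_size: float, delta: float = 1e-6):
    """Per-parameter AdaGrad learning rate: eta / (delta + sqrt(accum))."""
    acc = np.asarray(grad_sq_accumulator, dtype=float)
    if np.any(acc < 0):
        raise ValueError("gradient-square accumulator must be non-negative")
    return max_step_size / (delta + np.sqrt(acc))


# ---------------------------------------------------------------------------
# Subsampling helpers
# ---------------------------------------------------------------------------

def contiguous_voxel_subset(
    coords: np.ndarray,
    n_voxels: int,
    rng: np.random.Generator,
    tree: Optional[cKDTree] = None,
) -> np.ndarray:
    """Indices of the n_voxels nearest voxels to a uniformly drawn seed voxel.

    Realizes "contiguous" voxel subsampling as a Euclidean neighborhood in
    the masked voxel cloud, which respects arbitrary mask shapes.
    """
    v = coords.shape[0]
    if n_voxels >= v:
        return np.arange(v)
    if tree is None:
        tree = cKDTree(coords)
    seed_voxel = int(rng.integers(v))
    _, idx = tree.query(coords[seed_voxel], k=n_voxels)
    return np.atleast_1d(idx)


def _solve_weight_rows(y: np.ndarray, f_mat: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Per-row least-squares weights: solves y ~ W f_mat.

    ``ridge`` adds a diagonal to the basis Gram matrix; with
    ``ridge = noise_variance * prior_precision`` this is the conditional MAP
    of the weights under the model, which coincides with plain regression
    whenever the basis is well conditioned but stays finite when two sources
    collapse onto each other.
    """
    gram = f_mat @ f_mat.T + ridge * np.eye(f_mat.shape[0])
    rhs = f_mat @ y.T
    try:
        sol = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(gram) @ rhs
    return sol.T


# ---------------------------------------------------------------------------
# The fitting loop
# ---------------------------------------------------------------------------

def _apply_update(state, name, grad, rows, config):
    """AdaGrad step for one parameter group, clipped at max_step_size."""
    acc = state.grad_sq[name]
    param = getattr(state, name)
    if rows is None:
        acc += grad ** 2
        step = adagrad_rate(acc, config.max_step_size, config.adagrad_delta) * grad
        np.clip(step, -config.max_step_size, config.max_step_size, out=step)
        param += step
    else:
        acc_rows = acc[rows] + grad ** 2
        acc[rows] = acc_rows
        step = adagrad_rate(acc_rows, config.max_step_size, config.adagrad_delta) * grad
        np.clip(step, -config.max_step_size, config.max_step_size, out=step)
        param[rows] = param[rows] + step


def _init_accumulators(state: VariationalState) -> None:
    for name in PARAM_GROUPS:
        if name not in state.grad_sq:
            state.grad_sq[name] = np.zeros_like(getattr(state, name))


def _smoothed(trace, window):
    return float(np.mean(trace[-window:]))


def _diverged(trace, best_smoothed, window, factor) -> bool:
    """Collapse detector for the smoothed ELBO trace.

    The per-iteration estimate varies with the drawn voxel neighborhood, so
    only a drop of ``factor`` times the larger of the objective's magnitude
    and its recent spread counts as divergence.
    """
    if len(trace) < 2 * window:
        return False
    current = _smoothed(trace, window)
    spread = float(np.std(trace[-2 * window: -window]))
    guard_scale = max(abs(best_smoothed), spread, 1.0)
    return current < best_smoothed - factor * guard_scale


def fit(
    data: ImageDataset,
    config: FitConfig,
    init: VariationalState,
    hyper: Optional[Hyperparameters] = None,
    update_globals: bool = True,
    run_final_update: bool = True,
    callback=None,
) -> FitResult:
    """Run the stochastic variational fitting loop.

    Each outer iteration draws a fresh image subset and a contiguous voxel
    subset, draws one batch of M samples from q (shared by every parameter
    update in the iteration), applies control-variate-adjusted AdaGrad steps
    to the global source parameters and the weight log precisions, and then
    re-solves the subsampled images' weight means by exact least squares
    against the current source point estimates.  Terminates on the smoothed
    relative-ELBO rule or at ``max_iters``, then (by default) runs the final
    full-data weight update with the sources frozen.
    """
    if hyper is None:
        hyper = Hyperparameters.from_dataset(data.coords)
    hyper = hyper.require_center_prior(data.n_dims)
    state = init.copy()
    _init_accumulators(state)
    n, v = data.n_images, data.n_voxels
    n_sub, v_sub = config.resolve_subsamples(n, v)
    rng = np.random.default_rng(config.seed)
    tree = cKDTree(data.coords) if v_sub < v else None

    trace = []
    converged = False
    best_smoothed = -np.inf
    window = max(2, config.elbo_window)
    for _ in range(config.max_iters):
        state.iteration += 1
        img = np.sort(rng.choice(n, size=n_sub, replace=False))
        vox = contiguous_voxel_subset(data.coords, v_sub, rng, tree=tree)
        samples = sample_q(state, config.n_samples, image_subset=img, rng=rng)
        terms = _sample_terms(state, data, hyper, samples, voxel_subset=vox)
        trace.append(float(terms.total().mean()))

        scores = _score_arrays(state, samples)
        grads = _adjusted_group_gradients(scores, terms)
        for name in PARAM_GROUPS:
            if name == "weight_mean":
                continue  # handled by the exact regression re-solve below
            if name in GLOBAL_GROUPS and not update_globals:
                continue
            rows = img if name.startswith("weight") else None
            _apply_update(state, name, grads[name], rows, config)

        # weight re-solve: local parameters follow the updated sources
        f_full = _basis(state.center_mean, state.width_mean, data.coords)
        ridge = hyper.noise_variance * math.exp(hyper.weight_log_precision)
        state.weight_mean[img] = _solve_weight_rows(
            data.activations[img], f_full, ridge=ridge
        )

        if callback is not None:
            callback(state, trace)

        if len(trace) >= 2 * window:
            current = _smoothed(trace, window)
            previous = float(np.mean(trace[-2 * window: -window]))
            best_smoothed = max(best_smoothed, current)
            if _diverged(trace, best_smoothed, window, config.divergence_factor):
                raise FitDivergedError(
                    f"smoothed ELBO collapsed from {best_smoothed:.3g} to "
                    f"{current:.3g} after {state.iteration} iterations"
                )
            if abs(current - previous) < config.elbo_tol * (abs(previous) + 1.0):
                converged = True
                break

    final_trace = np.empty(0)
    if run_final_update:
        state, final_trace = final_update(state, data, config, hyper, return_trace=True)
    return FitResult(
        state=state,
        elbo_trace=np.asarray(trace),
        final_trace=np.asarray(final_trace),
        converged=converged,
        n_iterations=len(trace),
    )


def final_update(
    state: VariationalState,
    data: ImageDataset,
    config: FitConfig,
    hyper: Optional[Hyperparameters] = None,
    return_trace: bool = False,
):
    """Full-data refinement of the per-image weight parameters.

    The global source parameters are frozen at their current values; every
    image and every voxel is used.  Weight means are set to the exact least
    squares solution against the frozen basis, and weight log precisions are
    iterated with score-function gradients (weights-only samples) until they
    stabilize.
    """
    if hyper is None:
        hyper = Hyperparameters.from_dataset(data.coords)
    hyper = hyper.require_center_prior(data.n_dims)
    state = state.copy()
    _init_accumulators(state)
    # fresh accumulators for the local phase so frozen-global history does
    # not throttle the weight updates
    state.grad_sq["weight_log_precision"] = np.zeros_like(state.weight_log_precision)
    rng = np.random.default_rng(config.seed + 1)

    f_full = _basis(state.center_mean, state.width_mean, data.coords)
    ridge = hyper.noise_variance * math.exp(hyper.weight_log_precision)
    state.weight_mean[:] = _solve_weight_rows(data.activations, f_full, ridge=ridge)

    trace = []
    for _ in range(config.final_max_iters):
        samples = sample_q(state, config.n_samples, rng=rng, sample_globals=False)
        terms = _sample_terms(state, data, hyper, samples)
        trace.append(float(terms.total().mean()))
        scores = _score_arrays(state, samples)
        adjusted, _ = control_variate_adjust(
            scores["weight_log_precision"] * terms.weight_target(),
            scores["weight_log_precision"],
        )
        grad = adjusted.mean(axis=0)
        before = state.weight_log_precision.copy()
        _apply_update(state, "weight_log_precision", grad, None, config)
        state.iteration += 1
        # converged when the (noise-dominated) gradient no longer produces
        # a consistent drift of any log precision
        delta = np.max(np.abs(state.weight_log_precision - before))
        if delta < config.final_tol and len(trace) >= 10:
            break
    if return_trace:
        return state, np.asarray(trace)
    return state
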