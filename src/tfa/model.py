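"""Generative model for topographic factor analysis (TFA).

TFA explains each brain image in an fMRI dataset as a noisy weighted sum of
``K`` latent spatial *sources*.  Each source is an isotropic Gaussian radial
basis function (RBF) with a center ``mu_k`` (in the same units as the voxel
coordinates) and a log width ``lambda_k``; evaluated at location ``r`` the
source activation is::

    f(r; mu, lambda) = exp(-||r - mu||^2 / exp(lambda))

Stacking the K sources evaluated at the V voxel locations gives the K x V
basis matrix ``F``, and an N x V image set is modelled as ``Y ~ W F + noise``
with per-image source weights ``W`` (N x K) and i.i.d. Gaussian voxel noise.
Gaussian priors are placed on centers, log widths and weights; every Gaussian
scale in the package is carried as a *log precision* (variance =
``exp(-log_precision)``), which keeps all parameters unconstrained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SourceSet",
    "ImageDataset",
    "Hyperparameters",
    "rbf_evaluate",
    "build_basis_matrix",
    "sample_generative",
    "log_joint",
    "reconstruct",
    "gaussian_logpdf",
]

LOG_2PI = math.log(2.0 * math.pi)


def gaussian_logpdf(x, mean, log_precision):
    """Log density of N(mean, var = exp(-log_precision)), elementwise.

    Broadcasts like numpy arithmetic; returns an array of the broadcast shape.
    """
    x = np.asarray(x, dtype=float)
    prec = np.exp(log_precision)
    return 0.5 * (np.asarray(log_precision) - LOG_2PI) - 0.5 * prec * (x - mean) ** 2


def _check_finite(name, arr):
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")


@dataclass
class SourceSet:
    """K spherical RBF sources: centers (K, D) and log widths (K,).

    Centers are free to lie anywhere in coordinate space, including outside
    the brain mask: a wide source just outside a cortical patch can explain
    it as well as one inside.
    """

    centers: np.ndarray
    log_widths: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.log_widths = np.atleast_1d(np.asarray(self.log_widths, dtype=float))
        if self.centers.ndim != 2:
            raise ValueError("centers must be a K x D array")
        k, d = self.centers.shape
        if k < 1:
            raise ValueError("need at least one source")
        if d not in (2, 3):
            raise ValueError(f"spatial dimension must be 2 or 3, got {d}")
        if self.log_widths.shape != (k,):
            raise ValueError("log_widths must have one entry per source")
        _check_finite("centers", self.centers)
        _check_finite("log_widths", self.log_widths)

    @property
    def n_sources(self) -> int:
        return self.centers.shape[0]

    @property
    def n_dims(self) -> int:
        return self.centers.shape[1]


@dataclass
class ImageDataset:
    """An N x V activation matrix with per-voxel spatial coordinates.

    ``activations[n, v]`` is the (standardized) BOLD activation of voxel ``v``
    in image ``n``; ``coords[v]`` is that voxel's D-dimensional location.
    Grid shape and affine are opaque provenance carried through from NIfTI
    ingestion so reconstructions can be written back to the original grid.
    """

    activations: np.ndarray
    coords: np.ndarray
    mask_shape: Optional[tuple] = None
    affine: Optional[np.ndarray] = None
    condition_labels: Optional[np.ndarray] = None
    epoch_labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.activations = np.atleast_2d(np.asarray(self.activations, dtype=float))
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n, v = self.activations.shape
        if n < 1 or v < 1:
            raise ValueError("need at least one image and one voxel")
        if self.coords.shape[0] != v:
            raise ValueError(
                f"coords rows ({self.coords.shape[0]}) must match voxel count ({v})"
            )
        _check_finite("activations", self.activations)
        _check_finite("coords", self.coords)
        if self.condition_labels is not None:
            self.condition_labels = np.asarray(self.condition_labels)
            if self.condition_labels.shape != (n,):
                raise ValueError("condition_labels must have one entry per image")
        if self.epoch_labels is not None:
            self.epoch_labels = np.asarray(self.epoch_labels)
            if self.epoch_labels.shape != (n,):
                raise ValueError("epoch_labels must have one entry per image")

    @property
    def n_images(self) -> int:
        return self.activations.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.activations.shape[1]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class Hyperparameters:
    """Fixed prior settings for the TFA generative model.

    ``voxel_noise`` defaults to 0.1 and is interpreted according to
    ``voxel_noise_is`` ("std" | "variance" | "precision"); the standard
    deviation reading is the default.  The weight prior is zero-mean; the
    log-width prior mean of 1 puts the typical squared length scale at
    ``e`` coordinate units.  The center prior is meant to cover the brain:
    use :meth:`from_dataset` to center it on the voxel-cloud centroid with
    per-dimension variances equal to the coordinate variances.  The scalar
    log precisions default to broad priors (prior sd of 2 on weights and log
    widths).
    """

    voxel_noise: float = 0.1
    voxel_noise_is: str = "std"
    weight_mean: float = 0.0
    weight_log_precision: float = -math.log(4.0)
    center_mean: np.ndarray = None
    center_log_precision_diag: np.ndarray = None
    width_mean: float = 1.0
    width_log_precision: float = -math.log(4.0)

    def __post_init__(self):
        if self.voxel_noise_is not in ("std", "variance", "precision"):
            raise ValueError("voxel_noise_is must be 'std', 'variance' or 'precision'")
        if self.voxel_noise <= 0:
            raise ValueError("voxel_noise must be positive")
        if self.center_mean is not None:
            self.center_mean = np.atleast_1d(np.asarray(self.center_mean, dtype=float))
        if self.center_log_precision_diag is not None:
            self.center_log_precision_diag = np.atleast_1d(
                np.asarray(self.center_log_precision_diag, dtype=float)
            )

    @property
    def noise_variance(self) -> float:
        v = float(self.voxel_noise)
        if self.voxel_noise_is == "std":
            return v * v
        if self.voxel_noise_is == "variance":
            return v
        return 1.0 / v

    @property
    def noise_log_precision(self) -> float:
        return -math.log(self.noise_variance)

    @classmethod
    def from_dataset(cls, coords: np.ndarray, **overrides) -> "Hyperparameters":
        """Data-derived center prior: centroid mean, coordinate-variance scale."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        center_mean = coords.mean(axis=0)
        var = coords.var(axis=0, ddof=0)
        var = np.where(var > 0, var, 1.0)  # degenerate axis: fall back to unit scale
        return cls(
            center_mean=center_mean,
            center_log_precision_diag=-np.log(var),
            **overrides,
        )

    def require_center_prior(self, n_dims: int) -> "Hyperparameters":
        if self.center_mean is None or self.center_log_precision_diag is None:
            raise ValueError(
                "center prior not set; build Hyperparameters.from_dataset(coords)"
            )
        if self.center_mean.shape != (n_dims,):
            raise ValueError("center_mean dimension mismatch")
        if self.center_log_precision_diag.shape != (n_dims,):
            raise ValueError("center_log_precision_diag dimension mismatch")
        return self


# ---------------------------------------------------------------------------
# RBF sources and the basis matrix
# ---------------------------------------------------------------------------

def rbf_evaluate(center, log_width, location) -> float:
    """Evaluate a spherical Gaussian RBF source at one location.

    Returns ``exp(-||location - center||^2 / exp(log_width))``, which lies in
    (0, 1] and equals 1 exactly at the center.
    """
    center = np.asarray(center, dtype=float)
    location = np.asarray(location, dtype=float)
    if not (np.all(np.isfinite(center)) and np.all(np.isfinite(location))
            and np.isfinite(log_width)):
        raise ValueError("rbf_evaluate requires finite inputs")
    d2 = float(np.sum((location - center) ** 2))
    return math.exp(-d2 / math.exp(log_width))


def build_basis_matrix(sources: SourceSet, coords: np.ndarray) -> np.ndarray:
    """K x V matrix of every source evaluated at every voxel coordinate."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != sources.n_dims:
        raise ValueError(
            f"coords are {coords.shape[1]}-D but sources are {sources.n_dims}-D"
        )
    return _basis(sources.centers, sources.log_widths, coords)


def _basis(centers: np.ndarray, log_widths: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Unchecked basis computation; centers (..., K, D), coords (V, D)."""
    diff = centers[..., :, None, :] - coords  # (..., K, V, D)
    d2 = np.einsum("...kvd,...kvd->...kv", diff, diff)
    return np.exp(-d2 / np.exp(log_widths)[..., :, None])


def reconstruct(sources: SourceSet, weights: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Model-implied images ``W F``: one weighted source sum per image row."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != sources.n_sources:
        raise ValueError(
            f"weights have {weights.shape[1]} columns but there are "
            f"{sources.n_sources} sources"
        )
    return weights @ build_basis_matrix(sources, coords)


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------

def sample_generative(
    K: int,
    hyper: Hyperparameters,
    coords: np.ndarray,
    N: int,
    seed,
) -> tuple[SourceSet, np.ndarray, ImageDataset]:
    """Draw one dataset from the TFA generative process.

    Centers, log widths and weights are drawn from their Gaussian priors and
    each voxel activation from a Gaussian centered on ``(W F)[n, v]`` with the
    hyperparameter noise variance.  Deterministic given ``seed``.
    """
    if K < 1 or N < 1:
        raise ValueError("K and N must be >= 1")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = coords.shape[1]
    hyper = hyper.require_center_prior(d)
    rng = np.random.default_rng(seed)

    center_sd = np.exp(-0.5 * hyper.center_log_precision_diag)
    centers = hyper.center_mean + center_sd * rng.standard_normal((K, d))
    width_sd = math.exp(-0.5 * hyper.width_log_precision)
    log_widths = hyper.width_mean + width_sd * rng.standard_normal(K)
    weight_sd = math.exp(-0.5 * hyper.weight_log_precision)
    weights = hyper.weight_mean + weight_sd * rng.standard_normal((N, K))

    sources = SourceSet(centers, log_widths)
    mean = weights @ build_basis_matrix(sources, coords)
    noise_sd = math.sqrt(hyper.noise_variance)
    activations = mean + noise_sd * rng.standard_normal(mean.shape)
    data = ImageDataset(activations=activations, coords=coords)
    return sources, weights, data


# ---------------------------------------------------------------------------
# Log joint density
# ---------------------------------------------------------------------------

def _resolve_subset(subset, n, name) -> np.ndarray:
    if subset is None:
        return np.arange(n)
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError(f"{name} subset must be non-empty")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"{name} subset indices out of range")
    return idx


def log_joint(
    sources: SourceSet,
    weights: np.ndarray,
    data: ImageDataset,
    hyper: Hyperparameters,
    image_subset=None,
    voxel_subset=None,
) -> float:
    """Log of the joint density of latents and data, optionally subsampled.

    With image/voxel subsets the weight-prior and likelihood sums are scaled
    by ``N/N'`` and ``V/V'`` so the result is an unbiased estimate of the
    full-data log joint under uniform subset draws.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    hyper = hyper.require_center_prior(sources.n_dims)
    img = _resolve_subset(image_subset, data.n_images, "image")
    vox = _resolve_subset(voxel_subset, data.n_voxels, "voxel")
    n_scale = data.n_images / img.size
    v_scale = data.n_voxels / vox.size

    lp_centers = float(
        np.sum(
            gaussian_logpdf(
                sources.centers, hyper.center_mean, hyper.center_log_precision_diag
            )
        )
    )
    lp_widths = float(
        np.sum(
            gaussian_logpdf(sources.log_widths, hyper.width_mean, hyper.width_log_precision)
        )
    )
    lp_weights = n_scale * float(
        np.sum(
            gaussian_logpdf(weights[img], hyper.weight_mean, hyper.weight_log_precision)
        )
    )

    coords_sub = data.coords[vox]
    f_sub = _basis(sources.centers, sources.log_widths, coords_sub)
    mean = weights[img] @ f_sub
    y = data.activations[np.ix_(img, vox)]
    lik = float(
        np.sum(gaussian_logpdf(y, mean, hyper.noise_log_precision))
    )
    return lp_centers + lp_widths + lp_weights + n_scale * v_scale * lik
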