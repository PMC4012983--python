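"""Initialization of the variational parameters.

Two schemes are provided.  *Hotspot* initialization works on the mean image:
after centering by the scalar mean activation and folding (absolute value),
areas of very high and very low activation both show up as peaks.  Sources
are placed greedily at successive peaks of the residual image, each width is
fit by bounded scalar least squares, and the fitted (amplitude-scaled)
source image is subtracted before placing the next source.  Per-image
weights are then solved by ordinary least squares against the resulting
basis.  *Random* initialization draws the variational means from the prior
by running the generative process once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial import cKDTree

from .model import (
    Hyperparameters,
    ImageDataset,
    SourceSet,
    _resolve_subset,
    build_basis_matrix,
    sample_generative,
)
from .variational import VariationalState, _solve_weight_rows

__all__ = [
    "FoldedImage",
    "fold_mean_image",
    "fit_width_scalar",
    "hotspot_initialize",
    "solve_weights",
    "initialize_state",
    "voxel_spacing",
]


@dataclass
class FoldedImage:
    """Centered, folded mean image: |mean image - its scalar mean|."""

    values: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.values.shape != (self.coords.shape[0],):
            raise ValueError("values and coords must have matching voxel counts")
        if np.any(self.values < 0):
            raise ValueError("folded image values must be non-negative")


def fold_mean_image(data: ImageDataset) -> FoldedImage:
    """Mean across images, centered by its own scalar mean, absolute value."""
    mean_image = data.activations.mean(axis=0)
    folded = np.abs(mean_image - mean_image.mean())
    return FoldedImage(values=folded, coords=data.coords)


def voxel_spacing(coords: np.ndarray) -> float:
    """Smallest nearest-neighbor distance in the voxel cloud."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 2:
        return 1.0
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    return float(dist[:, 1].min())


def _width_bounds(coords: np.ndarray) -> tuple[float, float]:
    """Log-width search range from voxel spacing to bounding-box diagonal."""
    s = voxel_spacing(coords)
    span = float(np.linalg.norm(coords.max(axis=0) - coords.min(axis=0)))
    span = max(span, s)
    return float(np.log(0.25 * s * s)), float(np.log(4.0 * span * span))


def fit_width_scalar(
    folded: FoldedImage,
    center: np.ndarray,
    amplitude: float = None,
) -> float:
    """Least-squares log width of one amplitude-scaled RBF at a fixed center.

    Minimizes ``sum_v (folded_v - a * f_v(center, log_width))^2`` over the
    log width by bounded scalar optimization.  The amplitude ``a`` is held
    fixed at the folded value of the voxel nearest the center (or the given
    value) while the width is optimized.
    """
    values = folded.values
    if np.all(values == 0):
        raise RuntimeError("folded image is identically zero: no hotspot to fit")
    return _fit_width(values, folded.coords, center, amplitude)


def _fit_width(values, coords, center, amplitude=None) -> float:
    """Width fit on a raw (possibly signed) residual image."""
    center = np.atleast_1d(np.asarray(center, dtype=float))
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    if amplitude is None:
        peak = int(np.argmin(np.sum((coords - center) ** 2, axis=1)))
        amplitude = float(values[peak])
    d2 = np.sum((coords - center) ** 2, axis=1)
    lo, hi = _width_bounds(coords)

    def objective(log_width):
        pred = amplitude * np.exp(-d2 / np.exp(log_width))
        resid = values - pred
        return float(resid @ resid)

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _refine_source(values, coords, center, log_width, amplitude, spacing):
    """Local continuous polish of one placed source.

    Peak picking snaps the center to a voxel; a sub-voxel misalignment
    leaves a dipole artifact after subtraction that can dwarf fainter
    hotspots, so (center, log width, amplitude) are jointly re-fit by
    bounded least squares in a small neighborhood of the peak.
    """
    d = coords.shape[1]
    lo, hi = _width_bounds(coords)

    def objective(p):
        pred = p[d + 1] * np.exp(
            -np.sum((coords - p[:d]) ** 2, axis=1) / np.exp(p[d])
        )
        resid = values - pred
        return float(resid @ resid)

    bounds = [(center[j] - 2 * spacing, center[j] + 2 * spacing) for j in range(d)]
    bounds += [(lo, hi), (0.2 * amplitude, 2.0 * amplitude)]
    res = minimize(
        objective, np.concatenate([center, [log_width, amplitude]]),
        method="L-BFGS-B", bounds=bounds,
    )
    return res.x[:d], float(res.x[d]), float(res.x[d + 1])


def hotspot_initialize(
    data: ImageDataset,
    K: int,
    refine: bool = True,
    full_output: bool = False,
):
    """Greedy placement of K sources at peaks of the folded mean image.

    The image is folded exactly once at the start; residuals after each
    amplitude-scaled source subtraction are used as-is (they may go
    negative, leaving a "hole" where a source was removed).  Peaks are the
    maxima of the current residual, with ties broken by the lowest voxel
    index.  With ``refine`` (the default) each placed source is polished by
    a local continuous least-squares fit before subtraction, which prevents
    sub-voxel misalignment artifacts from masquerading as new hotspots;
    ``refine=False`` keeps centers exactly on peak voxels.  Deterministic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    folded = fold_mean_image(data)
    residual = folded.values.copy()
    coords = folded.coords
    spacing = voxel_spacing(coords)
    centers = np.empty((K, coords.shape[1]))
    log_widths = np.empty(K)
    amplitudes = np.empty(K)
    exhausted = False
    for k in range(K):
        peak = int(np.argmax(residual))
        amplitude = float(residual[peak])
        if amplitude <= 0:
            if not exhausted:
                warnings.warn(
                    f"residual exhausted after {k} sources; placing the rest "
                    "at the largest residual magnitudes",
                    RuntimeWarning,
                )
                exhausted = True
            peak = int(np.argmax(np.abs(residual)))
            amplitude = float(np.abs(residual[peak]))
        center = coords[peak].copy()
        log_width = _fit_width(residual, coords, center, amplitude)
        if refine:
            center, log_width, amplitude = _refine_source(
                residual, coords, center, log_width, amplitude, spacing
            )
        centers[k] = center
        log_widths[k] = log_width
        amplitudes[k] = amplitude
        d2 = np.sum((coords - center) ** 2, axis=1)
        residual = residual - amplitude * np.exp(-d2 / np.exp(log_width))
    sources = SourceSet(centers, log_widths)
    if full_output:
        return sources, amplitudes, residual
    return sources


def solve_weights(
    data: ImageDataset,
    basis: np.ndarray,
    image_subset=None,
) -> np.ndarray:
    """Per-image ordinary least squares weights: W = Y F' (F F')^-1.

    Falls back to the pseudoinverse (with a warning) when the basis Gram
    matrix is rank deficient, e.g. two coincident sources.
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if basis.shape[1] != data.n_voxels:
        raise ValueError(
            f"basis has {basis.shape[1]} columns but dataset has "
            f"{data.n_voxels} voxels"
        )
    img = _resolve_subset(image_subset, data.n_images, "image")
    y = data.activations[img]
    gram = basis @ basis.T
    k = basis.shape[0]
    if np.linalg.matrix_rank(gram) < k:
        warnings.warn(
            "basis Gram matrix is rank deficient; using pseudoinverse",
            RuntimeWarning,
        )
        return (np.linalg.pinv(gram) @ (basis @ y.T)).T
    return _solve_weight_rows(y, basis)


def _hotspot_candidates(data, K, n_restarts, rng):
    """Hotspot source sets from the full data and from random image subsets.

    A source whose weights average to zero across all images leaves no
    trace in the full mean image, but the mean over a random image subset
    fluctuates away from zero and can expose it; subset fractions cycle
    through 1/2, 1/4 and 1/10 of the images.
    """
    yield hotspot_initialize(data, K)
    fractions = (0.5, 0.25, 0.1)
    n = data.n_images
    for r in range(n_restarts - 1):
        frac = fractions[r % len(fractions)]
        size = max(2, int(round(frac * n)))
        sub = rng.choice(n, size=size, replace=False)
        subset = ImageDataset(activations=data.activations[sub], coords=data.coords)
        yield hotspot_initialize(subset, K)


def initialize_state(
    data: ImageDataset,
    K: int,
    mode: str = "hotspot",
    hyper: Hyperparameters = None,
    seed=0,
    restarts: int = 1,
    weight_log_precision: float = None,
    center_log_precision: float = None,
    width_log_precision: float = 2.3,
) -> VariationalState:
    """Build the initial variational state.

    ``mode="hotspot"`` derives center/width means from the folded mean image
    and weight means by regression; ``mode="random"`` draws the means from
    the prior by one pass of the generative process.  With ``restarts > 1``
    (hotspot mode) additional candidate source sets are computed from
    hotspots of random image subsets and the candidate with the smallest
    full-data reconstruction error — equivalently the best likelihood, the
    dominant ELBO term at initialization — is kept.  Initial log precisions
    are configurable; weight factors default to their conditional posterior
    precision given the initial sources.
    """
    if hyper is None:
        hyper = Hyperparameters.from_dataset(data.coords)
    hyper = hyper.require_center_prior(data.n_dims)
    if mode == "hotspot":
        rng = np.random.default_rng(seed)
        best = None
        for sources in _hotspot_candidates(data, K, max(1, restarts), rng):
            basis = build_basis_matrix(sources, data.coords)
            weights = solve_weights(data, basis)
            sse = float(np.sum((data.activations - weights @ basis) ** 2))
            if best is None or sse < best[0]:
                best = (sse, sources, basis, weights)
        _, sources, basis, weights = best
    elif mode == "random":
        sources, weights, _ = sample_generative(K, hyper, data.coords, data.n_images, seed)
        basis = build_basis_matrix(sources, data.coords)
    else:
        raise ValueError(f"unknown initialization mode: {mode!r}")

    spacing = voxel_spacing(data.coords)
    n = data.n_images
    if weight_log_precision is None:
        # conditional (conjugate) posterior precision of each weight given
        # the initial sources: prior precision + sum_v F_kv^2 / noise var
        prec = np.exp(hyper.weight_log_precision) + np.sum(basis ** 2, axis=1) / hyper.noise_variance
        weight_lp = np.broadcast_to(np.log(prec), (n, K)).copy()
    else:
        weight_lp = np.full((n, K), float(weight_log_precision))
    if center_log_precision is None:
        center_log_precision = float(np.log(1.0 / spacing ** 2))
    d = data.n_dims
    return VariationalState(
        weight_mean=np.asarray(weights, dtype=float),
        weight_log_precision=weight_lp,
        center_mean=sources.centers.copy(),
        center_log_precision=np.full((K, d), center_log_precision),
        width_mean=sources.log_widths.copy(),
        width_log_precision=np.full(K, width_log_precision),
    )
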