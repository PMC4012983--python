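"""Synthetic datasets with the exact statistical structure TFA assumes.

Every generator runs the model's own generative process (Gaussian centers,
log widths and weights; i.i.d. Gaussian voxel noise) so fitted parameters
can be compared against stored ground truth.  A signal-to-noise knob sets
the noise variance relative to the noiseless image variance, a separation
option rejects center draws that land closer than twice the mean source
width, and a condition-structured variant adds per-condition low-rank
perturbations to the weight covariance for testing the network-reliability
statistics (its covariance construction is test scaffolding, not part of
the model).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    Hyperparameters,
    ImageDataset,
    SourceSet,
    build_basis_matrix,
)

__all__ = [
    "GroundTruthBundle",
    "make_grid",
    "generate_tfa_dataset",
    "generate_condition_dataset",
    "generate_fig4_demo",
]


@dataclass
class GroundTruthBundle:
    """A synthetic dataset together with the latents that produced it."""

    sources: SourceSet
    weights: np.ndarray
    data: ImageDataset
    hyper: Hyperparameters
    noise_variance: float
    snr: Optional[float] = None
    condition_covariances: Optional[dict] = None
    seed: Optional[int] = None


def make_grid(shape: Sequence[int], spacing: float = 1.0) -> np.ndarray:
    """Row-major enumeration of a regular grid: V x D coordinate table."""
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("grid dimensions must be positive")
    pts = np.array(list(itertools.product(*(range(s) for s in shape))), dtype=float)
    return pts * float(spacing)


def _draw_sources(
    K: int,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    separated: bool,
    bounds: Optional[tuple] = None,
    max_attempts: int = 10_000,
) -> SourceSet:
    d = hyper.center_mean.size
    center_sd = np.exp(-0.5 * hyper.center_log_precision_diag)
    width_sd = math.exp(-0.5 * hyper.width_log_precision)
    log_widths = hyper.width_mean + width_sd * rng.standard_normal(K)
    if not separated:
        centers = hyper.center_mean + center_sd * rng.standard_normal((K, d))
        return SourceSet(centers, log_widths)
    # "well separated": pairwise gaps of twice the mean source width, and
    # every center inside the imaged volume so it is actually recoverable.
    # Centers are placed sequentially, each redrawn until it clears the
    # constraints (joint redraws would almost never pack K centers).
    min_sep = 2.0 * float(np.mean(np.exp(0.5 * log_widths)))
    draws = 0
    while draws < max_attempts:
        placed = []
        tries = 0
        while len(placed) < K and tries < 100 and draws < max_attempts:
            c = hyper.center_mean + center_sd * rng.standard_normal(d)
            draws += 1
            tries += 1
            if bounds is not None:
                lo, hi = bounds
                if np.any(c < lo) or np.any(c > hi):
                    continue
            if placed and min(
                float(np.linalg.norm(c - p)) for p in placed
            ) < min_sep:
                continue
            placed.append(c)
            tries = 0  # fresh budget for the next center
        if len(placed) == K:
            return SourceSet(np.array(placed), log_widths)
    raise RuntimeError(
        f"could not draw {K} in-volume centers at least {min_sep:.3g} apart "
        f"within {max_attempts} attempts; widen the center prior or lower K"
    )


def generate_tfa_dataset(
    K: int,
    N: int,
    grid: np.ndarray,
    hyper: Optional[Hyperparameters] = None,
    snr: float = 5.0,
    seed=0,
    separated: bool = False,
) -> GroundTruthBundle:
    """One draw of the generative process with SNR-controlled voxel noise.

    The noise variance is set so that var(W F) / noise variance equals
    ``snr``.  With ``separated=True`` center draws are rejected until every
    pair is at least twice the mean source width apart.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if hyper is None:
        # generator default: realistic spread of source sizes (log-width
        # sd 0.5 about the prior mean) rather than the deliberately broad
        # inference prior
        hyper = Hyperparameters.from_dataset(grid, width_log_precision=math.log(4.0))
    hyper = hyper.require_center_prior(grid.shape[1])
    rng = np.random.default_rng(seed)

    bounds = (grid.min(axis=0), grid.max(axis=0))
    sources = _draw_sources(K, hyper, rng, separated, bounds=bounds)
    weight_sd = math.exp(-0.5 * hyper.weight_log_precision)
    weights = hyper.weight_mean + weight_sd * rng.standard_normal((N, K))
    signal = weights @ build_basis_matrix(sources, grid)
    signal_var = float(signal.var())
    if signal_var == 0:
        signal_var = 1.0
    noise_variance = signal_var / snr
    activations = signal + math.sqrt(noise_variance) * rng.standard_normal(signal.shape)
    data = ImageDataset(activations=activations, coords=grid)
    # carry the realized noise level so downstream likelihoods are calibrated
    bundle_hyper = Hyperparameters(
        voxel_noise=noise_variance,
        voxel_noise_is="variance",
        weight_mean=hyper.weight_mean,
        weight_log_precision=hyper.weight_log_precision,
        center_mean=hyper.center_mean,
        center_log_precision_diag=hyper.center_log_precision_diag,
        width_mean=hyper.width_mean,
        width_log_precision=hyper.width_log_precision,
    )
    return GroundTruthBundle(
        sources=sources,
        weights=weights,
        data=data,
        hyper=bundle_hyper,
        noise_variance=noise_variance,
        snr=snr,
        seed=seed,
    )


def generate_condition_dataset(
    K: int,
    N_per_condition: int,
    C: int,
    grid: np.ndarray,
    effect_size: float = 1.0,
    seed=0,
    n_epochs: int = 6,
    base_variance: float = 1.0,
    snr: float = 5.0,
    hyper: Optional[Hyperparameters] = None,
) -> GroundTruthBundle:
    """Condition-labelled dataset with covariance-structured weights.

    Condition ``c`` draws its weights from N(0, Sigma_c) with
    ``Sigma_c = base_variance * I + effect_size * u_c u_c^T`` for a random
    unit vector ``u_c`` (positive definite by construction).  With
    ``effect_size = 0`` conditions are exchangeable — the null of the
    split-half permutation test.  Epochs are assigned round-robin within
    each condition.
    """
    if C < 2:
        raise ValueError("need at least 2 conditions")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if hyper is None:
        hyper = Hyperparameters.from_dataset(grid, width_log_precision=math.log(4.0))
    hyper = hyper.require_center_prior(grid.shape[1])
    rng = np.random.default_rng(seed)

    bounds = (grid.min(axis=0), grid.max(axis=0))
    sources = _draw_sources(K, hyper, rng, separated=True, bounds=bounds)
    cov_by_condition = {}
    weights = np.empty((C * N_per_condition, K))
    condition_labels = np.empty(C * N_per_condition, dtype=object)
    epoch_labels = np.empty(C * N_per_condition, dtype=int)
    for c in range(C):
        u = rng.standard_normal(K)
        u /= np.linalg.norm(u)
        sigma = base_variance * np.eye(K) + effect_size * np.outer(u, u)
        chol = np.linalg.cholesky(sigma)
        block = slice(c * N_per_condition, (c + 1) * N_per_condition)
        weights[block] = rng.standard_normal((N_per_condition, K)) @ chol.T
        cov_by_condition[f"cond{c}"] = sigma
        condition_labels[block] = f"cond{c}"
        epoch_labels[block] = 1 + np.arange(N_per_condition) % n_epochs

    signal = weights @ build_basis_matrix(sources, grid)
    signal_var = float(signal.var()) or 1.0
    noise_variance = signal_var / snr
    activations = signal + math.sqrt(noise_variance) * rng.standard_normal(signal.shape)
    data = ImageDataset(
        activations=activations,
        coords=grid,
        condition_labels=condition_labels,
        epoch_labels=epoch_labels,
    )
    return GroundTruthBundle(
        sources=sources,
        weights=weights,
        data=data,
        hyper=hyper,
        noise_variance=noise_variance,
        snr=snr,
        condition_covariances=cov_by_condition,
        seed=seed,
    )


def generate_fig4_demo(seed=0, N: int = 30, noise_sd: float = 0.05) -> GroundTruthBundle:
    """2-D demo image set built from 25 well-separated RBF sources.

    Sources sit on a jittered 5 x 5 lattice in a 40 x 40 grid, with weight
    means alternating in sign so both high- and low-activation hotspots
    appear in the folded mean image.  Used by the documentation and the
    hotspot-initialization tests.
    """
    rng = np.random.default_rng(seed)
    grid = make_grid((40, 40), spacing=1.0)
    lattice = np.array(
        [[4.0 + 8.0 * i, 4.0 + 8.0 * j] for i in range(5) for j in range(5)]
    )
    centers = lattice + rng.uniform(-1.0, 1.0, size=lattice.shape)
    log_widths = np.log(9.0) + rng.uniform(-0.2, 0.2, size=25)
    sources = SourceSet(centers, log_widths)
    signs = np.where(np.arange(25) % 2 == 0, 1.0, -1.0)
    weight_means = signs * rng.uniform(0.8, 1.2, size=25)
    weights = weight_means + 0.3 * rng.standard_normal((N, 25))
    signal = weights @ build_basis_matrix(sources, grid)
    activations = signal + noise_sd * rng.standard_normal(signal.shape)
    data = ImageDataset(activations=activations, coords=grid)
    hyper = Hyperparameters.from_dataset(grid, voxel_noise=noise_sd)
    return GroundTruthBundle(
        sources=sources,
        weights=weights,
        data=data,
        hyper=hyper,
        noise_variance=noise_sd ** 2,
        seed=seed,
    )
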