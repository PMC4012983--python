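"""Reconstruction diagnostics and model selection for the number of sources.

Because each fitted source is a spatial function, it can be evaluated at
voxel locations that were never used during fitting.  The cross-validation
scheme here exploits that: source centers and widths are estimated on
out-of-fold images, per-image weights are then fit on one random half of
the voxels, and the model predicts the *other* half's activations for the
held-out (in-fold) images.  Agreement is scored as the correlation between
the observed and predicted across-image covariance matrices of the held-out
voxels, giving 12 scores per candidate K (6 image folds x 2 voxel groups).
The K maximizing the median score is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Hyperparameters, ImageDataset, SourceSet, build_basis_matrix
from .initialization import initialize_state
from .variational import FitConfig, fit

__all__ = [
    "image_covariance",
    "predict_held_out",
    "covariance_agreement",
    "CrossValidationResult",
    "cross_validate",
    "select_K",
    "make_folds",
]


def image_covariance(images: np.ndarray) -> np.ndarray:
    """N x N sample covariance across images (voxels are the observations)."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if images.shape[1] < 2:
        raise ValueError("need at least 2 voxels to form an image covariance")
    return np.atleast_2d(np.cov(images, rowvar=True, ddof=1))


def covariance_agreement(
    observed: np.ndarray,
    estimated: np.ndarray,
    offdiag_only: bool = False,
) -> float:
    """Pearson correlation between two covariance matrices' entries.

    By default every entry is compared; ``offdiag_only`` restricts the
    comparison to the strict upper triangle.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    estimated = np.atleast_2d(np.asarray(estimated, dtype=float))
    if observed.shape != estimated.shape:
        raise ValueError("covariance matrices must have the same shape")
    if offdiag_only:
        iu = np.triu_indices(observed.shape[0], 1)
        a, b = observed[iu], estimated[iu]
    else:
        a, b = observed.ravel(), estimated.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("covariance agreement undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def make_folds(
    n_images: int,
    n_folds: int,
    rng: np.random.Generator,
    stratify_labels=None,
) -> np.ndarray:
    """Balanced fold assignment, stratified within label groups when given."""
    folds = np.empty(n_images, dtype=int)
    if stratify_labels is None:
        perm = rng.permutation(n_images)
        folds[perm] = np.arange(n_images) % n_folds
    else:
        labels = np.asarray(stratify_labels)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            perm = rng.permutation(idx)
            folds[perm] = np.arange(idx.size) % n_folds
    return folds


@dataclass
class CrossValidationResult:
    """Fold-level scores plus per-K medians with bootstrap 95% CIs."""

    scores: pd.DataFrame  # columns: K, fold, voxel_group, correlation
    summary: pd.DataFrame  # columns: K, median, ci_low, ci_high, n_scores

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)


def _bootstrap_ci(values: np.ndarray, rng, n_boot: int = 10_000) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return float(lo), float(hi)


def _fit_sources(train: ImageDataset, k: int, config: FitConfig, hyper,
                 init_restarts: int = 1) -> SourceSet:
    state = initialize_state(
        train, k, mode="hotspot", hyper=hyper, seed=config.seed,
        restarts=init_restarts,
    )
    if config.max_iters > 0:
        result = fit(
            train, replace(config, n_sources=k), state, hyper=hyper,
            run_final_update=False,
        )
        state = result.state
    return state.point_sources()


def predict_held_out(basis, y_fit, fit_vox, held_vox) -> np.ndarray:
    """Predict held-out voxel activations from in-group activations only.

    Per-image weights are solved by plain regression of ``y_fit`` against
    the basis columns of the fitting voxels, then the sources are evaluated
    at the held-out voxel coordinates (their basis columns).  Held-out
    activations never enter the computation, by construction.  Plain least
    squares is deliberate: redundant sources inflate the weight variance,
    which is exactly the overfitting cost cross-validation must expose
    (lstsq keeps exactly rank-deficient bases finite).
    """
    f_fit = basis[:, fit_vox]
    w = np.linalg.lstsq(f_fit.T, y_fit.T, rcond=None)[0].T
    return w @ basis[:, held_vox]


def cross_validate(
    data: ImageDataset,
    K_grid: Sequence[int],
    config: Optional[FitConfig] = None,
    seed=0,
    n_folds: int = 6,
    hyper: Optional[Hyperparameters] = None,
    n_bootstrap: int = 10_000,
    init_restarts: int = 4,
    offdiag_only: bool = False,
) -> CrossValidationResult:
    """Held-out covariance prediction over a grid of source counts.

    For each fold: sources are fit to the out-of-fold images; voxels are
    split into two random halves; weights for the in-fold images are solved
    on one half and the other half's activations are predicted from the
    fitted sources at the held-out coordinates.  The score is the Pearson
    agreement between observed and predicted across-image covariance of the
    held-out voxels.  Candidate K values too large for the fold data are
    skipped with a warning.
    """
    if len(K_grid) < 1:
        raise ValueError("K_grid must contain at least one value")
    if config is None:
        config = FitConfig()
    if hyper is None:
        hyper = Hyperparameters.from_dataset(data.coords)
    rng = np.random.default_rng(seed)
    n, v = data.n_images, data.n_voxels
    folds = make_folds(n, n_folds, rng, stratify_labels=data.condition_labels)

    # one voxel split per (fold, repetition); fresh random balanced halves
    rows = []
    for k in K_grid:
        if k > v // 2 or k >= n:
            warnings.warn(f"skipping K={k}: too large for {n} images / {v} voxels")
            continue
        for fold in range(n_folds):
            in_fold = np.flatnonzero(folds == fold)
            out_fold = np.flatnonzero(folds != fold)
            train = ImageDataset(
                activations=data.activations[out_fold], coords=data.coords
            )
            sources = _fit_sources(
                train, k, replace(config, seed=int(rng.integers(2**31))), hyper,
                init_restarts=init_restarts,
            )
            basis = build_basis_matrix(sources, data.coords)
            perm = rng.permutation(v)
            half = v // 2
            groups = (perm[:half], perm[half:])
            for g, fit_vox in enumerate(groups):
                held_vox = groups[1 - g]
                y_pred = predict_held_out(
                    basis, data.activations[np.ix_(in_fold, fit_vox)],
                    fit_vox, held_vox,
                )
                y_obs = data.activations[np.ix_(in_fold, held_vox)]
                corr = covariance_agreement(
                    image_covariance(y_obs), image_covariance(y_pred),
                    offdiag_only=offdiag_only,
                )
                rows.append(
                    {"K": k, "fold": fold, "voxel_group": g, "correlation": corr}
                )

    scores = pd.DataFrame(rows)
    if scores.empty:
        raise ValueError("no feasible K values in K_grid")
    summary_rows = []
    for k, grp in scores.groupby("K"):
        vals = grp["correlation"].to_numpy()
        lo, hi = _bootstrap_ci(vals, rng, n_boot=n_bootstrap)
        summary_rows.append(
            {
                "K": k,
                "median": float(np.median(vals)),
                "ci_low": lo,
                "ci_high": hi,
                "n_scores": vals.size,
            }
        )
    summary = pd.DataFrame(summary_rows).sort_values("K", ignore_index=True)
    return CrossValidationResult(scores=scores, summary=summary)


def select_K(cv_result: CrossValidationResult) -> int:
    """argmax-median choice of the number of sources (ties -> smallest K).

    Warns when the curve is still rising at the top of the grid, since the
    preferred K may then lie beyond the candidates examined.
    """
    summary = cv_result.summary
    if len(summary) < 2:
        raise ValueError("need at least 2 K values to select one")
    medians = summary["median"].to_numpy()
    ks = summary["K"].to_numpy()
    if np.all(np.isnan(medians)):
        raise ValueError("all candidate K values produced undefined scores")
    best = int(ks[int(np.nanargmax(medians))])
    finite = medians[~np.isnan(medians)]
    if np.all(np.diff(finite) > 0):
        warnings.warn(
            "median correlation is still increasing at the largest K in the "
            "grid; the selected value may underestimate the optimum",
            RuntimeWarning,
        )
    return best
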