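"""Source-interaction networks from the covariance of the weight matrix.

The K x K covariance of per-image source weights, taken across a set of
images, summarizes how similarly each pair of sources behaves from image to
image: positive entries are read as excitatory interactions, negative as
inhibitory.  Per-condition networks, a split-half (odd vs even epoch)
reliability analysis with a row-shuffle permutation test, and an
across-participant aggregate are provided.  Percentile thresholding is for
visualization only and is never applied before the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import _resolve_subset

__all__ = [
    "NetworkResult",
    "ReliabilityReport",
    "weight_covariance",
    "threshold_network",
    "split_half_reliability",
    "aggregate_across_participants",
]


@dataclass
class NetworkResult:
    """K x K symmetric source-interaction matrix for one image set."""

    interaction: np.ndarray
    condition: Optional[str] = None
    n_images: int = 0

    def __post_init__(self):
        self.interaction = np.atleast_2d(np.asarray(self.interaction, dtype=float))
        k1, k2 = self.interaction.shape
        if k1 != k2:
            raise ValueError("interaction matrix must be square")
        if not np.allclose(self.interaction, self.interaction.T, atol=1e-10):
            raise ValueError("interaction matrix must be symmetric")

    @property
    def n_sources(self) -> int:
        return self.interaction.shape[0]


@dataclass
class ReliabilityReport:
    """Split-half confusion matrix with its permutation test result."""

    confusion: np.ndarray
    conditions: np.ndarray
    t_statistic: float
    permutation_p: float
    n_permutations: int


def weight_covariance(weights: np.ndarray, image_subset=None, condition=None) -> NetworkResult:
    """Sample covariance (denominator n-1) of the K weight columns."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    img = _resolve_subset(image_subset, weights.shape[0], "image")
    if img.size < 2:
        raise ValueError("need at least 2 images to form a covariance")
    sub = weights[img]
    cov = np.cov(sub, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return NetworkResult(interaction=cov, condition=condition, n_images=img.size)


def threshold_network(
    net: NetworkResult,
    percentile: float,
    reference: Optional[NetworkResult] = None,
) -> pd.DataFrame:
    """Edges at or above a percentile of the reference's absolute strengths.

    The cutoff is the given percentile of the absolute off-diagonal values
    of the reference network (the network itself by default).  Returns a
    tidy edge list (source_i < source_j, strength).  Intended for display;
    statistical tests operate on the unthresholded matrices.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    if reference is None:
        reference = net
    k = net.n_sources
    iu = np.triu_indices(k, 1)
    ref_iu = np.triu_indices(reference.n_sources, 1)
    ref_strengths = np.abs(reference.interaction[ref_iu])
    cutoff = np.percentile(ref_strengths, percentile) if ref_strengths.size else 0.0
    strengths = net.interaction[iu]
    keep = np.abs(strengths) >= cutoff
    return pd.DataFrame(
        {
            "source_i": iu[0][keep],
            "source_j": iu[1][keep],
            "strength": strengths[keep],
        }
    )


def _offdiag_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def _welch_t(diag: np.ndarray, off: np.ndarray) -> float:
    nd, no = diag.size, off.size
    vd = diag.var(ddof=1) / nd
    vo = off.var(ddof=1) / no
    denom = np.sqrt(vd + vo)
    if denom == 0:
        return 0.0
    return float((diag.mean() - off.mean()) / denom)


def _confusion_t(confusion: np.ndarray) -> float:
    c = confusion.shape[0]
    diag = np.diag(confusion)
    off = confusion[~np.eye(c, dtype=bool)]
    return _welch_t(diag, off)


def _row_shuffle_p(confusion: np.ndarray, n_permutations: int, rng) -> tuple[float, float]:
    """One-sided permutation p for diagonal > off-diagonal under row shuffles.

    Rows of the confusion matrix are permuted uniformly (columns fixed) and
    the Welch t recomputed for each shuffle; p uses the +1 smoothing
    (1 + #{t_perm >= t_obs}) / (1 + n_permutations).
    """
    c = confusion.shape[0]
    t_obs = _confusion_t(confusion)
    total_sum = confusion.sum()
    total_sumsq = (confusion ** 2).sum()
    n_off = c * c - c

    perms = np.stack([rng.permutation(c) for _ in range(n_permutations)])
    diag = confusion[perms, np.arange(c)]  # (P, C)
    d_sum = diag.sum(axis=1)
    d_sumsq = (diag ** 2).sum(axis=1)
    d_mean = d_sum / c
    d_var = (d_sumsq - c * d_mean ** 2) / (c - 1)
    o_sum = total_sum - d_sum
    o_sumsq = total_sumsq - d_sumsq
    o_mean = o_sum / n_off
    o_var = (o_sumsq - n_off * o_mean ** 2) / (n_off - 1)
    denom = np.sqrt(np.maximum(d_var / c + o_var / n_off, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(denom > 0, (d_mean - o_mean) / denom, 0.0)
    p = (1.0 + np.sum(t_perm >= t_obs)) / (1.0 + n_permutations)
    return t_obs, float(p)


def _condition_split_networks(weights, condition_labels, epoch_labels):
    """Per-condition covariance networks from odd and from even epochs."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    condition_labels = np.asarray(condition_labels)
    epoch_labels = np.asarray(epoch_labels, dtype=int)
    conditions = np.unique(condition_labels)
    odd = epoch_labels % 2 == 1
    even = ~odd
    nets = {}
    for half, sel in (("odd", odd), ("even", even)):
        for cond in conditions:
            idx = np.flatnonzero((condition_labels == cond) & sel)
            if idx.size < 2:
                raise ValueError(
                    f"condition {cond!r} has fewer than 2 images in the "
                    f"{half}-epoch half"
                )
            nets[(half, cond)] = weight_covariance(
                weights, image_subset=idx, condition=str(cond)
            )
    return conditions, nets


def confusion_matrix(weights, condition_labels, epoch_labels) -> tuple[np.ndarray, np.ndarray]:
    """Odd-vs-even correlation of condition networks' off-diagonal entries.

    Entry (i, j) is the Pearson correlation between the vectorized strict
    upper triangle of condition i's odd-epoch network and condition j's
    even-epoch network.
    """
    conditions, nets = _condition_split_networks(weights, condition_labels, epoch_labels)
    c = conditions.size
    odd_vecs = [_offdiag_upper(nets[("odd", cond)].interaction) for cond in conditions]
    even_vecs = [_offdiag_upper(nets[("even", cond)].interaction) for cond in conditions]
    conf = np.empty((c, c))
    for i in range(c):
        for j in range(c):
            conf[i, j] = np.corrcoef(odd_vecs[i], even_vecs[j])[0, 1]
    return conf, conditions


def split_half_reliability(
    weights: np.ndarray,
    condition_labels,
    epoch_labels,
    n_permutations: int = 1000,
    seed=0,
) -> ReliabilityReport:
    """Reliability of per-condition networks across odd and even epochs.

    Same-condition (diagonal) confusion correlations are compared with
    different-condition (off-diagonal) ones by a Welch two-sample t, and
    significance is assessed by uniformly shuffling the confusion matrix's
    rows ``n_permutations`` times (one-sided, +1-smoothed p).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    conf, conditions = confusion_matrix(weights, condition_labels, epoch_labels)
    rng = np.random.default_rng(seed)
    t_obs, p = _row_shuffle_p(conf, n_permutations, rng)
    return ReliabilityReport(
        confusion=conf,
        conditions=conditions,
        t_statistic=t_obs,
        permutation_p=p,
        n_permutations=n_permutations,
    )


def aggregate_across_participants(
    confusions: Sequence[np.ndarray],
    n_permutations: int = 1000,
    seed=0,
    conditions=None,
) -> ReliabilityReport:
    """Mean confusion matrix across participants, then the same test."""
    mats = [
        np.atleast_2d(
            np.asarray(c.confusion if isinstance(c, ReliabilityReport) else c, dtype=float)
        )
        for c in confusions
    ]
    if not mats:
        raise ValueError("need at least one confusion matrix")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("confusion matrices must share a shape")
    mean_conf = np.mean(mats, axis=0)
    rng = np.random.default_rng(seed)
    t_obs, p = _row_shuffle_p(mean_conf, n_permutations, rng)
    if conditions is None:
        conditions = np.arange(shape[0])
    return ReliabilityReport(
        confusion=mean_conf,
        conditions=np.asarray(conditions),
        t_statistic=t_obs,
        permutation_p=p,
        n_permutations=n_permutations,
    )
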