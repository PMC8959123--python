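"""Evaluation statistics: landmark mean distance error, reliability
coefficients (Cronbach's alpha, optional ICC), chance-corrected agreement
(Cohen's and linear weighted kappa), and confusion-matrix metrics.

Conventions that matter numerically: all variances are sample variances
(denominator n−1), which Cronbach's alpha depends on; missing landmark
predictions are excluded from the MDE mean and reported separately as a
miss count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import LandmarkSet

__all__ = [
    "RaterMatrix",
    "ConfusionMatrix",
    "mean_distance_error",
    "cronbach_alpha",
    "icc2_1",
    "cohen_kappa",
    "weighted_linear_kappa",
    "binary_metrics",
    "interpret_kappa",
    "alpha_satisfactory",
    "StatisticUndefined",
]

LANDMARK_NAMES = ("E", "Y", "C", "H")
ALPHA_SATISFACTORY_CUTOFF = 0.75


class StatisticUndefined(ValueError):
    """The requested coefficient is undefined for this input (e.g. zero
    total variance, or a single-category confusion matrix)."""


@dataclass(frozen=True)
class RaterMatrix:
    """Subjects × raters grid of measurements or grades."""

    values: np.ndarray
    rater_ids: Optional[Sequence[str]] = None
    subject_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("rater matrix needs >= 2 subjects and >= 2 raters")
        if not np.isfinite(v).all():
            raise ValueError("rater matrix has missing or non-finite cells")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k agreement counts over (ordered) category labels."""

    counts: np.ndarray
    labels: Optional[Sequence] = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("confusion matrix must have positive total")
        object.__setattr__(self, "counts", c.astype(float))

    @staticmethod
    def from_labels(a: Sequence, b: Sequence, labels: Sequence) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        k = len(labels)
        m = np.zeros((k, k))
        for x, y in zip(a, b, strict=True):
            m[idx[x], idx[y]] += 1
        return ConfusionMatrix(m, labels=list(labels))


def mean_distance_error(
    truth: List[LandmarkSet], pred: List[LandmarkSet]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-landmark, per-side mean Euclidean distance error (pixels).

    Returns ``(mde, misses)``: two 4×2 DataFrames (landmarks E/Y/C/H ×
    sides left/right).  A landmark present in truth but absent in the
    prediction counts as a miss and is excluded from the mean.
    """
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lists must be aligned")
    dists: Dict[Tuple[str, str], list] = {
        (n, s): [] for n in LANDMARK_NAMES for s in ("left", "right")
    }
    misses = {k: 0 for k in dists}
    for t, p in zip(truth, pred):
        if t.image_id is not None and p.image_id is not None and t.image_id != p.image_id:
            raise ValueError(f"mismatched case ids: {t.image_id} vs {p.image_id}")
        for side in ("left", "right"):
            th, ph = t.hip(side), p.hip(side)
            for name in LANDMARK_NAMES:
                tp, pp = getattr(th, name), getattr(ph, name)
                if tp is None:
                    continue
                if pp is None:
                    misses[(name, side)] += 1
                    continue
                dists[(name, side)].append(math.hypot(tp.x - pp.x, tp.y - pp.y))
    mde = pd.DataFrame(
        {
            side: [
                float(np.mean(dists[(n, side)])) if dists[(n, side)] else np.nan
                for n in LANDMARK_NAMES
            ]
            for side in ("left", "right")
        },
        index=list(LANDMARK_NAMES),
    )
    miss_df = pd.DataFrame(
        {side: [misses[(n, side)] for n in LANDMARK_NAMES] for side in ("left", "right")},
        index=list(LANDMARK_NAMES),
    )
    return mde, miss_df


def cronbach_alpha(m: RaterMatrix) -> float:
    """Cronbach's alpha over raters (columns).

    alpha = k/(k−1) · (1 − Σ_i s_i² / s_total²), with s_i² the sample
    variance of rater i across subjects and s_total² the sample variance of
    per-subject rater sums.  Computed from the rater covariance matrix S
    (sample, n−1): Σ_i s_i² = tr(S) and s_total² = ΣΣ S, which is exact
    when raters are bit-identical (alpha = 1.0 without rounding residue).
    """
    v = m.values
    k = v.shape[1]
    S = np.cov(v, rowvar=False, ddof=1)
    total_var = S.sum()
    if total_var == 0:
        raise StatisticUndefined("all subjects identical; alpha undefined")
    return (k / (k - 1)) * (1.0 - np.trace(S) / total_var)


def alpha_satisfactory(alpha: float) -> bool:
    """Reliability convention: alpha >= 0.75 is considered satisfactory."""
    return alpha >= ALPHA_SATISFACTORY_CUTOFF


def icc2_1(m: RaterMatrix) -> float:
    """ICC(2,1), two-way random effects, absolute agreement, single rater.

    Provided for comparison; the package's default reliability coefficient
    is :func:`cronbach_alpha`.
    """
    v = m.values
    n, k = v.shape
    grand = v.mean()
    subj_means = v.mean(axis=1)
    rater_means = v.mean(axis=0)
    ms_r = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((rater_means - grand) ** 2).sum() / (k - 1)
    resid = v - subj_means[:, None] - rater_means[None, :] + grand
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise StatisticUndefined("zero denominator in ICC(2,1)")
    return (ms_r - ms_e) / denom


def _kappa(cm: ConfusionMatrix, weights: Optional[np.ndarray]) -> float:
    c = cm.counts
    n = c.sum()
    p = c / n
    row, col = p.sum(axis=1), p.sum(axis=0)
    expected = np.outer(row, col)
    if weights is None:
        k = c.shape[0]
        weights = np.eye(k)
    po = (weights * p).sum()
    pe = (weights * expected).sum()
    if pe == 1.0:
        raise StatisticUndefined("degenerate single-category table; kappa undefined")
    return (po - pe) / (1.0 - pe)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa: (p_o − p_e) / (1 − p_e)."""
    return _kappa(cm, None)


def weighted_linear_kappa(cm: ConfusionMatrix) -> float:
    """Linear weighted kappa for ordered categories: agreement weight
    w_ij = 1 − |i−j|/(k−1) on both observed and expected proportions."""
    k = cm.counts.shape[0]
    if k == 1:
        raise StatisticUndefined("single-category table")
    i = np.arange(k)
    w = 1.0 - np.abs(i[:, None] - i[None, :]) / (k - 1)
    return _kappa(cm, w)


def interpret_kappa(value: float) -> str:
    """Agreement band: <=0.40 poor-to-slight, (0.40, 0.75] moderate,
    >0.75 perfect."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {value}")
    if value <= 0.40:
        return "poor_to_slight"
    if value <= 0.75:
        return "moderate"
    return "perfect"


def binary_metrics(cm: ConfusionMatrix, positive_index: int = 0) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity and missed-diagnosis rate of a
    2×2 table; convention: rows = truth, columns = prediction."""
    c = cm.counts
    if c.shape != (2, 2):
        raise ValueError("binary metrics need a 2x2 confusion matrix")
    p, q = positive_index, 1 - positive_index
    tp, fn = c[p, p], c[p, q]
    fp, tn = c[q, p], c[q, q]
    n = c.sum()
    out: Dict[str, float] = {"accuracy": (tp + tn) / n}
    if tp + fn == 0:
        raise StatisticUndefined("empty positive margin; sensitivity undefined")
    if tn + fp == 0:
        raise StatisticUndefined("empty negative margin; specificity undefined")
    out["sensitivity"] = tp / (tp + fn)
    out["specificity"] = tn / (tn + fp)
    out["missed_diagnosis_rate"] = 1.0 - out["sensitivity"]
    return out
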