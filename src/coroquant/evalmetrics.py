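"""Evaluation statistics for masks, detections and continuous agreement.

Covers the full evaluation suite used for segmentation and quantification
studies: Dice/sensitivity/specificity/PPV/NPV on masks, confusion-matrix
metrics with Wilson 95% CIs on binary detections, mean absolute error and
Bland-Altman limits of agreement for continuous measures, ICC(2,1)
(two-way random effects, absolute agreement, single rater) with F-based
confidence bounds, and unweighted Cohen's kappa.

Metrics with a zero denominator are reported as ``None`` (explicitly
undefined), never silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "overlap_metrics",
    "wilson_interval",
    "confusion_from_labels",
    "mae",
    "bland_altman",
    "icc",
    "cohen_kappa",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def overlap_metrics(
    pred_mask: np.ndarray, truth_mask: np.ndarray, label: int = 1
) -> Dict[str, Optional[float]]:
    """Pixel-overlap metrics of a predicted vs reference mask for one label.

    Returns ``dsc``, ``sensitivity``, ``specificity``, ``ppv``, ``npv``;
    entries with an empty denominator are ``None``.
    """
    pred = np.asarray(pred_mask) == label
    truth = np.asarray(truth_mask) == label
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return {
        "dsc": _ratio(2 * tp, 2 * tp + fp + fn),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Wilson score 95% (by default) confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def confusion_from_labels(
    pred: Sequence[bool], truth: Sequence[bool]
) -> Tuple[ConfusionCounts, Dict[str, Optional[dict]]]:
    """Confusion counts and derived metrics (with Wilson 95% CIs).

    Works at any detection granularity (slice, vessel or patient level).
    Each defined metric maps to ``{"value", "ci_low", "ci_high"}``.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1D boolean lists")
    if pred.size == 0:
        raise ValueError("empty detection lists")
    counts = ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
        "accuracy": (counts.tp + counts.tn, counts.n),
    }
    metrics: Dict[str, Optional[dict]] = {}
    for name, (k, n) in pairs.items():
        if n == 0:
            metrics[name] = None
            continue
        lo, hi = wilson_interval(k, n)
        metrics[name] = {"value": k / n, "ci_low": lo, "ci_high": hi}
    return counts, metrics


def mae(pred: Sequence[float], ref: Sequence[float]) -> float:
    """Mean absolute error between paired measurements."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be equal-length 1D vectors")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(pred - ref)))


def bland_altman(
    pred: Sequence[float], ref: Sequence[float]
) -> Tuple[float, float, float]:
    """Bland-Altman agreement: (bias, loa_low, loa_high).

    Bias is the mean difference pred - ref; the 95% limits of agreement are
    bias +- 1.96 x sample SD of the differences (n-1 denominator).
    """
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("bland_altman needs equal-length vectors of size >= 2")
    diff = pred - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc(
    ratings: np.ndarray, alpha: float = 0.05
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects x raters matrix without missing cells. Point
    estimate from the standard mean-squares decomposition; confidence
    bounds via the F-distribution (McGraw & Wong). Returns
    ``(None, None, None)`` when the decomposition is degenerate (no
    variance anywhere).
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix, both >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        return None, None, None
    value = (msr - mse) / denom

    # F-based bounds (two-way random, absolute agreement, single measure)
    if mse <= 0 and msc <= 0:
        return float(value), None, None
    a = k * value / (n * (1.0 - value)) if value != 1.0 else np.inf
    if not np.isfinite(a):
        return float(value), float(value), float(value)
    b = 1.0 + k * value * (n - 1) / (n * (1.0 - value))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(value), float(lower), float(upper)


def cohen_kappa(a: Sequence[bool], b: Sequence[bool]) -> Optional[float]:
    """Unweighted Cohen's kappa between two binary raters.

    ``None`` when the expected agreement is 1 (kappa undefined).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("raters must give equal-length nonempty 1D lists")
    n = a.size
    po = np.count_nonzero(a == b) / n
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return None
    return float((po - pe) / (1.0 - pe))
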