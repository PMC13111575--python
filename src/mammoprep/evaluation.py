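"""Classification and segmentation metrics with case-level aggregation.

Metrics follow the standard confusion-matrix definitions; segmentation
overlap uses Dice and IoU (Jaccard).  Per-image scores are averaged across
the views of each case before any population statistic, so cases with more
views carry no extra weight, and uncertainty is reported as a percentile
bootstrap confidence interval over test cases (non-parametric, 1,000
resamples by default).  Paired comparisons use the classic paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask

__all__ = [
    "ConfusionCounts", "MetricSummary", "classification_metrics",
    "dice", "iou", "masks_both_empty", "aggregate_case_level",
    "bootstrap_ci", "paired_t_test", "threshold_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSummary:
    """Mean/SD/median of per-case scores plus a bootstrap CI on the mean."""

    mean: float
    sd: float
    median: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_resamples: int
    ci_level: float

    def __post_init__(self):
        if self.ci_low > self.ci_high + 1e-12:
            raise ValueError("ci_low must not exceed ci_high")


def classification_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero; nothing to score")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    accuracy = (c.TP + c.TN) / c.total
    sensitivity = ratio(c.TP, c.TP + c.FN)
    specificity = ratio(c.TN, c.TN + c.FP)
    precision = ratio(c.TP, c.TP + c.FP)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }


def _check_shapes(P: BinaryMask, G: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    if P.shape != G.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {G.shape}")
    return P.pixels.astype(bool), G.pixels.astype(bool)


def dice(P: BinaryMask, G: BinaryMask) -> float:
    """Dice overlap 2|P∩G|/(|P|+|G|); two empty masks score 1 (agreement on
    absence) so lesion-free cases remain scoreable."""
    p, g = _check_shapes(P, G)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def iou(P: BinaryMask, G: BinaryMask) -> float:
    """Jaccard overlap |P∩G|/|P∪G|; two empty masks score 1."""
    p, g = _check_shapes(P, G)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def masks_both_empty(P: BinaryMask, G: BinaryMask) -> bool:
    """Flag for the degenerate both-empty case where overlap scores are 1 by
    convention rather than by measured agreement."""
    p, g = _check_shapes(P, G)
    return not p.any() and not g.any()


def aggregate_case_level(per_image_scores: Sequence[tuple[str, str, float]]
                         ) -> list[tuple[str, float]]:
    """Average per-image scores across the views of each case.

    Input rows are (case_id, view, score); output is one (case_id, mean)
    row per case, views weighted equally.
    """
    df = pd.DataFrame(per_image_scores, columns=["case_id", "view", "score"])
    if not np.isfinite(df["score"]).all():
        raise ValueError("scores must be finite")
    agg = df.groupby("case_id", sort=True)["score"].mean()
    return list(agg.items())


def bootstrap_ci(case_scores: Sequence[float], n_resamples: int = 1000,
                 level: float = 0.95, seed: int = 0) -> MetricSummary:
    """Percentile bootstrap CI for the mean of per-case scores.

    Cases are resampled with replacement; the CI is the percentile interval
    of the resampled means with linear-interpolation quantiles.  Mean, SD
    (sample, n-1) and median describe the original scores.
    """
    scores = np.asarray(case_scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("bootstrap needs at least 2 case scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(n_resamples, scores.size))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return MetricSummary(
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)),
        median=float(np.median(scores)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_cases=int(scores.size),
        n_resamples=int(n_resamples),
        ci_level=float(level),
    )


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Two-sided paired t-test on the differences a - b.

    Identical sequences give t = 0, p = 1; constant nonzero differences make
    t undefined and raise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D sequences of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return {"t": 0.0, "df": n - 1, "p": 1.0}
        raise ValueError(
            "all paired differences are identical and nonzero: the paired "
            "t statistic is undefined (zero variance)"
        )
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p)}


def threshold_sweep(scores: Sequence[float], labels: Sequence[int],
                    thresholds: Sequence[float] | None = None) -> pd.DataFrame:
    """Confusion metrics across score thresholds (curve utility).

    ``labels`` are 1 = positive.  Returns one row per threshold with the
    five confusion metrics (None where undefined).  The default threshold
    for a single operating point elsewhere in the package is 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0, 0.5, 1.0], scores]))
    rows = []
    for th in thresholds:
        pred = scores >= th
        pos = labels == 1
        c = ConfusionCounts(
            TP=int((pred & pos).sum()), TN=int((~pred & ~pos).sum()),
            FP=int((pred & ~pos).sum()), FN=int((~pred & pos).sum()),
        )
        row = {"threshold": float(th)}
        row.update(classification_metrics(c))
        rows.append(row)
    return pd.DataFrame(rows)
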