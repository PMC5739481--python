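"""Diagnostic-accuracy measures for scored cohorts.

Implements the five challenge measures — average precision (area under the
precision–recall curve), AUC of the ROC, and specificity at 95/98/99%
sensitivity — together with the partial AUC over the high-sensitivity band
[0.95, 1], where the area integrates specificity over sensitivity so that a
perfect classifier attains the maximum.

Conventions (applied consistently everywhere):

* a lesion is called malignant iff ``score >= threshold``;
* tied scores move between confusion cells together, giving one ROC step
  per distinct score value;
* average precision is the uninterpolated step-sum over ranks, tie groups
  processed as blocks with the block-end precision;
* specificity at a sensitivity target is the best empirical specificity over
  the operating points whose empirical sensitivity meets the target (a
  linearly interpolated variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from dermeval.cohort import PANEL_MEASURES, MeasurePanel, ScoredCohort


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at one operating point; 'malignant' is positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        """Recall: TP / (TP + FN)."""
        return self.tp / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        """TN / (TN + FP)."""
        return self.tn / self.n_neg if self.n_neg else float("nan")

    @property
    def precision(self) -> float:
        """TP / (TP + FP); NaN when nothing is called malignant."""
        called = self.tp + self.fp
        return self.tp / called if called else float("nan")


@dataclass(frozen=True)
class OperatingCurve:
    """Empirical ROC polyline: (fpr, tpr) points with score thresholds.

    Points are ordered by decreasing threshold, one point per distinct score
    value plus the endpoints (0,0) (threshold +inf) and, when not already
    reached, (1,1). fpr and tpr are non-decreasing along the curve.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.fpr, self.tpr, self.thresholds):
            if arr.shape != self.fpr.shape or arr.ndim != 1:
                raise ValueError("curve arrays must be 1-D and aligned")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing along the curve")

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


class SpecAtSens(NamedTuple):
    """Specificity at a sensitivity target, with the achieved operating point."""

    specificity: float
    sensitivity: float
    threshold: float


def confusion_at_threshold(cohort: ScoredCohort, t: float) -> ConfusionCounts:
    """Confusion counts when calling malignant iff ``score >= t``."""
    pred = cohort.scores >= t
    pos = cohort.labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    return ConfusionCounts(
        tp=tp, fp=fp, tn=cohort.n_neg - fp, fn=cohort.n_pos - tp
    )


def roc_curve_from_scores(
    scores: np.ndarray | Sequence[float], labels: np.ndarray | Sequence[int]
) -> OperatingCurve:
    """Empirical ROC from arbitrary real-valued scores (higher = more malignant).

    Thresholds sweep the distinct score values in descending order; tied
    scores form a single step. The (0,0) endpoint carries threshold +inf;
    (1,1) is reached at the minimum score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("ROC requires at least one lesion of each class")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tie group in descending order
    distinct = np.nonzero(np.diff(s))[0]
    block_end = np.r_[distinct, s.size - 1]
    cum_tp = np.cumsum(y)[block_end]
    cum_fp = (block_end + 1) - cum_tp
    fpr = np.r_[0.0, cum_fp / n_neg]
    tpr = np.r_[0.0, cum_tp / n_pos]
    thresholds = np.r_[np.inf, s[block_end]]
    return OperatingCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def roc_curve(cohort: ScoredCohort) -> OperatingCurve:
    """Empirical ROC of a scored cohort."""
    cohort.require_both_classes()
    return roc_curve_from_scores(cohort.scores, cohort.labels)


def auc_roc(curve: OperatingCurve | ScoredCohort) -> float:
    """Trapezoidal area under the empirical ROC.

    Equals the Mann–Whitney probability that a random malignant lesion
    outscores a random benign one, with ties counting one half.
    """
    if isinstance(curve, ScoredCohort):
        curve = roc_curve(curve)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pr_curve(cohort: ScoredCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision–recall points (recall, precision, threshold), one per distinct score.

    Recall is non-decreasing along the returned arrays; precision is the
    block-end precision of each tie group.
    """
    if cohort.n_pos < 1:
        raise ValueError("PR curve requires at least one malignant lesion")
    order = np.argsort(-cohort.scores, kind="stable")
    s = cohort.scores[order]
    y = cohort.labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    block_end = np.r_[distinct, s.size - 1]
    cum_tp = np.cumsum(y)[block_end]
    depth = block_end + 1.0
    recall = cum_tp / cohort.n_pos
    precision = cum_tp / depth
    return recall, precision, s[block_end]


def average_precision(cohort: ScoredCohort) -> float:
    """Uninterpolated step-sum area under the precision–recall curve.

    AP = sum_k (R_k - R_{k-1}) * P_k over the distinct-score blocks in
    descending score order, with P_k the block-end precision.
    """
    if cohort.n_pos < 1:
        raise ValueError("average precision requires at least one malignant lesion")
    recall, precision, _ = pr_curve(cohort)
    dr = np.diff(np.r_[0.0, recall])
    return float(np.sum(dr * precision))


def specificity_at_sensitivity(
    cohort: ScoredCohort,
    target_se: float,
    interpolation: str = "none",
) -> SpecAtSens:
    """Best specificity subject to sensitivity >= ``target_se``.

    With ``interpolation='none'`` (default) only empirical operating points
    are considered, so the reported (specificity, sensitivity, threshold) is
    exactly attainable by thresholding. ``interpolation='linear'`` instead
    evaluates specificity at sensitivity exactly ``target_se`` by linear
    interpolation along the ROC polyline (the threshold is then the one of
    the first empirical point meeting the target).

    An answer always exists: the threshold at the minimum score gives
    sensitivity 1.
    """
    if not 0.0 < target_se <= 1.0:
        raise ValueError("target_se must lie in (0, 1]")
    if interpolation not in ("none", "linear"):
        raise ValueError("interpolation must be 'none' or 'linear'")
    curve = roc_curve(cohort)
    spec = curve.specificity
    ok = curve.tpr >= target_se - 1e-12
    i = int(np.argmax(ok))  # first point meeting the target: max specificity
    if interpolation == "none":
        # ties in specificity: report the highest sensitivity at that specificity
        tied = ok & np.isclose(spec, spec[i], rtol=0, atol=1e-12)
        j = int(np.nonzero(tied)[0][-1])
        return SpecAtSens(float(spec[i]), float(curve.tpr[j]), float(curve.thresholds[j]))
    if curve.tpr[i] <= target_se or i == 0:
        return SpecAtSens(float(spec[i]), float(curve.tpr[i]), float(curve.thresholds[i]))
    t0, t1 = curve.tpr[i - 1], curve.tpr[i]
    w = (target_se - t0) / (t1 - t0)
    interp = spec[i - 1] + w * (spec[i] - spec[i - 1])
    return SpecAtSens(float(interp), float(target_se), float(curve.thresholds[i]))


def partial_auc_roc(
    curve: OperatingCurve | ScoredCohort, se_lo: float = 0.95
) -> tuple[float, float]:
    """Area under the ROC restricted to the sensitivity band [se_lo, 1].

    Integrates specificity (1 - fpr) over sensitivity along the ROC
    polyline, linearly interpolating the curve at ``se_lo``. Returns
    ``(raw, normalized)`` with raw in [0, 1 - se_lo] and
    normalized = raw / (1 - se_lo), so a perfect classifier scores 1.
    """
    if not 0.0 < se_lo < 1.0:
        raise ValueError("se_lo must lie in (0, 1)")
    if isinstance(curve, ScoredCohort):
        curve = roc_curve(curve)
    tpr, fpr = curve.tpr, curve.fpr
    i = int(np.searchsorted(tpr, se_lo, side="left"))
    if tpr[i] > se_lo and i > 0:
        w = (se_lo - tpr[i - 1]) / (tpr[i] - tpr[i - 1])
        f0 = fpr[i - 1] + w * (fpr[i] - fpr[i - 1])
        t = np.r_[se_lo, tpr[i:]]
        f = np.r_[f0, fpr[i:]]
    else:
        t = tpr[i:]
        f = fpr[i:]
    raw = float(np.trapezoid(1.0 - f, t))
    return raw, raw / (1.0 - se_lo)


def measure_panel(
    cohort: ScoredCohort,
    se_targets: Sequence[float] = (0.95, 0.98, 0.99),
    pauc_lo: float = 0.95,
    interpolation: str = "none",
) -> MeasurePanel:
    """All seven measures of one cohort with consistent tie conventions."""
    if len(se_targets) != 3:
        raise ValueError("se_targets must give the three sensitivity targets")
    curve = roc_curve(cohort)
    specs = [
        specificity_at_sensitivity(cohort, t, interpolation).specificity
        for t in se_targets
    ]
    raw, norm = partial_auc_roc(curve, pauc_lo)
    return MeasurePanel(
        average_precision=average_precision(cohort),
        auc_roc=auc_roc(curve),
        spec_at_se95=specs[0],
        spec_at_se98=specs[1],
        spec_at_se99=specs[2],
        pauc_se95_100_raw=raw,
        pauc_se95_100_norm=norm,
    )


__all__ = [
    "ConfusionCounts",
    "OperatingCurve",
    "SpecAtSens",
    "confusion_at_threshold",
    "roc_curve",
    "roc_curve_from_scores",
    "pr_curve",
    "auc_roc",
    "average_precision",
    "specificity_at_sensitivity",
    "partial_auc_roc",
    "measure_panel",
    "PANEL_MEASURES",
]
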