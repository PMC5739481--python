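"""Cross-validated and bootstrap estimation of the measure panel.

High-sensitivity measures on cohorts with few melanomas hinge on the scores
of one or two lesions, so single-split estimates are unstable. This module
provides stratified k-fold cross-validation (scoring held-out folds and, by
default, pooling all out-of-fold scores into one cohort before computing the
panel) and a stratified bootstrap over an already-scored cohort with
percentile intervals.

Randomness contract: every scheme takes a single integer seed; per-resample
streams are derived as ``default_rng([seed, counter])`` so results are
bit-identical across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dermeval.cohort import PANEL_MEASURES, FeatureTable, MeasurePanel, ScoredCohort
from dermeval.gda import fit_gda, posterior
from dermeval.metrics import measure_panel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampledPanel:
    """Per-resample measure panels plus point estimates and spread.

    ``panels`` holds one row per fold/bootstrap replicate (columns = the
    seven measures). ``pooled`` is the panel of the pooled out-of-fold
    scores (CV) or of the original cohort (bootstrap); it is the default
    point estimate for CV.
    """

    scheme: str
    seed: int
    panels: pd.DataFrame
    pooled: MeasurePanel | None = None

    def __post_init__(self) -> None:
        if list(self.panels.columns) != list(PANEL_MEASURES):
            raise ValueError("panels must have the seven canonical measure columns")
        bad = (self.panels.lt(-1e-12) | self.panels.gt(1 + 1e-12)).any().any()
        if bad:
            raise ValueError("per-resample measures must lie in [0, 1]")

    @property
    def n_resamples(self) -> int:
        return len(self.panels)

    def point_estimate(self) -> pd.Series:
        """Mean of each measure over resamples."""
        return self.panels.mean(axis=0)

    def std_error(self) -> pd.Series:
        """Standard deviation over resamples (0 for a single resample)."""
        if len(self.panels) < 2:
            return pd.Series(0.0, index=self.panels.columns)
        return self.panels.std(axis=0, ddof=1)

    def percentile_interval(self, level: float = 0.95) -> pd.DataFrame:
        """Equal-tailed percentile interval per measure (rows: lo, hi)."""
        alpha = (1.0 - level) / 2.0
        qs = self.panels.quantile([alpha, 1.0 - alpha], axis=0)
        qs.index = ["lo", "hi"]
        return qs

    def summary_frame(self) -> pd.DataFrame:
        ci = self.percentile_interval()
        out = pd.DataFrame(
            {
                "mean": self.point_estimate(),
                "std_error": self.std_error(),
                "ci_lo": ci.loc["lo"],
                "ci_hi": ci.loc["hi"],
            }
        )
        if self.pooled is not None:
            out.insert(0, "pooled", pd.Series(self.pooled.as_dict()))
        return out


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold partition of row indices.

    Each class is shuffled with its own counter-derived stream and dealt
    round-robin to the folds, so every fold contains both classes whenever
    each class count is at least k.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be at least 2")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls, counter in ((0, 0), (1, 1)):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} rows, fewer than k={k} folds"
            )
        rng = np.random.default_rng([seed, counter])
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cv_panel(
    features: FeatureTable,
    variant: str = "qda",
    k: int = 5,
    seed: int = 0,
    ridge: float | None = None,
    aggregate: str = "pooled",
    se_targets=(0.95, 0.98, 0.99),
    pauc_lo: float = 0.95,
) -> ResampledPanel:
    """Stratified k-fold cross-validated measure panel for a GDA variant.

    The model is fitted on k-1 folds and scores the held-out fold. With
    ``aggregate='pooled'`` (default) all out-of-fold scores form a single
    cohort whose panel is the ``pooled`` point estimate; per-fold panels are
    returned as well. ``aggregate='per_fold'`` reports only the per-fold
    panels (folds too small to carry both classes at high sensitivity can
    make these erratic — the motivation for pooling).
    """
    if aggregate not in ("pooled", "per_fold"):
        raise ValueError("aggregate must be 'pooled' or 'per_fold'")
    folds = stratified_folds(features.labels, k, seed)
    n = features.n
    oof_scores = np.full(n, np.nan)
    rows = []
    for held_out in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[held_out] = False
        model = fit_gda(
            features.subset(np.nonzero(train_mask)[0]), variant=variant, ridge=ridge
        )
        post, _ = posterior(model, features.X[held_out])
        oof_scores[held_out] = post
        fold_cohort = ScoredCohort(post, features.labels[held_out])
        rows.append(
            measure_panel(fold_cohort, se_targets=se_targets, pauc_lo=pauc_lo).as_dict()
        )
    panels = pd.DataFrame(rows, columns=list(PANEL_MEASURES))
    pooled_cohort = ScoredCohort(oof_scores, features.labels, features.lesion_ids)
    pooled = measure_panel(pooled_cohort, se_targets=se_targets, pauc_lo=pauc_lo)
    return ResampledPanel(
        scheme=f"cv(k={k}, variant={variant}, aggregate={aggregate})",
        seed=seed,
        panels=panels,
        pooled=pooled,
    )


def loocv_pooled_scores(
    features: FeatureTable, variant: str = "qda", ridge: float | None = None
) -> ScoredCohort:
    """Leave-one-out out-of-fold scores pooled into one cohort (deterministic)."""
    n = features.n
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_gda(features.subset(np.nonzero(mask)[0]), variant=variant, ridge=ridge)
        post, _ = posterior(model, features.X[i : i + 1])
        scores[i] = post[0]
    return ScoredCohort(scores, features.labels, features.lesion_ids)


def bootstrap_panel(
    cohort: ScoredCohort,
    B: int = 1000,
    seed: int = 0,
    stratified: bool = True,
    se_targets=(0.95, 0.98, 0.99),
    pauc_lo: float = 0.95,
) -> ResampledPanel:
    """Bootstrap the measure panel of an already-scored cohort.

    Stratified resampling (default) draws with replacement within each class,
    preserving n_pos and n_neg exactly. Unstratified resamples that end up
    single-class are dropped with a log message; if every replicate is
    dropped an error is raised.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    cohort.require_both_classes()
    pos_idx = np.nonzero(cohort.labels == 1)[0]
    neg_idx = np.nonzero(cohort.labels == 0)[0]
    rows = []
    dropped = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        if stratified:
            take = np.r_[
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        else:
            take = rng.choice(len(cohort), size=len(cohort), replace=True)
            if len(set(cohort.labels[take])) < 2:
                dropped += 1
                continue
        boot = ScoredCohort(cohort.scores[take], cohort.labels[take])
        rows.append(measure_panel(boot, se_targets=se_targets, pauc_lo=pauc_lo).as_dict())
    if dropped:
        logger.info("dropped %d/%d single-class bootstrap replicate(s)", dropped, B)
    if not rows:
        raise ValueError("all bootstrap replicates were single-class; nothing to report")
    panels = pd.DataFrame(rows, columns=list(PANEL_MEASURES))
    return ResampledPanel(
        scheme=f"bootstrap(B={B}, stratified={stratified})",
        seed=seed,
        panels=panels,
        pooled=measure_panel(cohort, se_targets=se_targets, pauc_lo=pauc_lo),
    )


__all__ = [
    "ResampledPanel",
    "stratified_folds",
    "cv_panel",
    "loocv_pooled_scores",
    "bootstrap_panel",
]
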