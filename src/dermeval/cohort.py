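"""Core data containers: lesion records, scored cohorts, feature tables, measure panels.

The evaluation unit throughout the package is the :class:`ScoredCohort` — a
set of lesions, each carrying a continuous malignancy score in [0, 1]
(typically a classifier's posterior probability of melanoma) and a binary
truth label, with 'malignant' as the positive class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical label encoding: benign = 0 (negative), malignant = 1 (positive)
BENIGN, MALIGNANT = 0, 1

_LABEL_ALIASES = {
    "benign": BENIGN,
    "malignant": MALIGNANT,
    "0": BENIGN,
    "1": MALIGNANT,
}

#: the seven panel measures, in canonical display order
PANEL_MEASURES = (
    "average_precision",
    "auc_roc",
    "spec_at_se95",
    "spec_at_se98",
    "spec_at_se99",
    "pauc_se95_100_raw",
    "pauc_se95_100_norm",
)


def parse_label(raw: str | int | float) -> int:
    """Parse a ground-truth label to the canonical {0, 1} encoding.

    Accepts 'benign'/'malignant' (case-insensitive) and 0/1.
    """
    token = str(raw).strip().lower()
    try:
        return _LABEL_ALIASES[token]
    except KeyError:
        raise ValueError(
            f"unrecognised label {raw!r}: expected benign/malignant or 0/1"
        ) from None


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: identifier, malignancy score, and (optionally) truth label."""

    lesion_id: str
    score: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.lesion_id:
            raise ValueError("lesion_id must be a non-empty string")
        if self.score is not None:
            if not math.isfinite(self.score):
                raise ValueError(f"{self.lesion_id}: score must be finite")
            if not 0.0 <= self.score <= 1.0:
                raise ValueError(
                    f"{self.lesion_id}: score {self.score} outside [0, 1]"
                )
            if self.score in (0.0, 1.0):
                logger.debug("%s: saturated score %s", self.lesion_id, self.score)
        if self.label is not None and self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"{self.lesion_id}: label must be 0 or 1")


class ScoredCohort:
    """Joined per-lesion records: id, score and truth label for every lesion.

    Parameters
    ----------
    scores
        Malignancy scores, one per lesion.
    labels
        Binary truth labels (1 = malignant).
    lesion_ids
        Optional identifiers; generated as ``REC_000001`` ... when absent.
    """

    def __init__(
        self,
        scores: Sequence[float] | np.ndarray,
        labels: Sequence[int] | np.ndarray,
        lesion_ids: Sequence[str] | None = None,
    ) -> None:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if scores.ndim != 1 or labels.shape != scores.shape:
            raise ValueError("scores and labels must be 1-D and equal length")
        if scores.size == 0:
            raise ValueError("cohort must contain at least one record")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if not np.isin(labels, (BENIGN, MALIGNANT)).all():
            raise ValueError("labels must be 0 (benign) or 1 (malignant)")
        if lesion_ids is None:
            lesion_ids = [f"REC_{i + 1:06d}" for i in range(scores.size)]
        lesion_ids = list(map(str, lesion_ids))
        if len(lesion_ids) != scores.size:
            raise ValueError("lesion_ids length mismatch")
        if len(set(lesion_ids)) != len(lesion_ids):
            raise ValueError("lesion_ids must be unique")
        n_sat = int(np.sum((scores == 0.0) | (scores == 1.0)))
        if n_sat:
            logger.info("cohort contains %d saturated score(s) (exactly 0 or 1)", n_sat)
        self.scores = scores
        self.labels = labels
        self.lesion_ids = lesion_ids

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[LesionRecord]) -> "ScoredCohort":
        records = list(records)
        missing = [r.lesion_id for r in records if r.score is None or r.label is None]
        if missing:
            raise ValueError(f"records missing score or label: {missing[:5]}")
        return cls(
            [r.score for r in records],
            [r.label for r in records],
            [r.lesion_id for r in records],
        )

    # -- basic properties -------------------------------------------------

    def __len__(self) -> int:
        return self.scores.size

    @property
    def n_pos(self) -> int:
        """Number of malignant lesions."""
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        """Number of benign lesions."""
        return len(self) - self.n_pos

    def require_both_classes(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError(
                f"cohort must contain both classes (n_pos={self.n_pos}, "
                f"n_neg={self.n_neg})"
            )

    def to_records(self) -> list[LesionRecord]:
        return [
            LesionRecord(i, float(s), int(l))
            for i, s, l in zip(self.lesion_ids, self.scores, self.labels)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lesion_id": self.lesion_ids,
                "score": self.scores,
                "label": self.labels,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScoredCohort(n={len(self)}, n_pos={self.n_pos}, n_neg={self.n_neg})"
        )


class FeatureTable:
    """Numeric feature matrix with a binary label per row.

    Wraps an ``(n, d)`` float matrix, a label vector, feature names and
    optional lesion identifiers. No missing values are allowed and both
    classes must be present.
    """

    def __init__(
        self,
        X: np.ndarray | pd.DataFrame,
        labels: Sequence[int] | np.ndarray,
        feature_names: Sequence[str] | None = None,
        lesion_ids: Sequence[str] | None = None,
    ) -> None:
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be a 2-D matrix with at least one feature")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains missing or non-finite values")
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (X.shape[0],):
            raise ValueError("labels must align with the rows of X")
        if not np.isin(labels, (BENIGN, MALIGNANT)).all():
            raise ValueError("labels must be 0 (benign) or 1 (malignant)")
        if labels.min() == labels.max():
            raise ValueError("feature table must contain both classes")
        if feature_names is None:
            feature_names = [f"f{j + 1}" for j in range(X.shape[1])]
        feature_names = list(map(str, feature_names))
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        if lesion_ids is not None:
            lesion_ids = list(map(str, lesion_ids))
            if len(lesion_ids) != X.shape[0]:
                raise ValueError("lesion_ids length mismatch")
        self.X = X
        self.labels = labels
        self.feature_names = feature_names
        self.lesion_ids = lesion_ids

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return self.n - self.n_pos

    def class_matrix(self, label: int) -> np.ndarray:
        """Rows of ``X`` belonging to one class."""
        return self.X[self.labels == label]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset (used by resampling); may raise if single-class."""
        ids = None if self.lesion_ids is None else [self.lesion_ids[i] for i in idx]
        return FeatureTable(self.X[idx], self.labels[idx], self.feature_names, ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "lesion_id", self.lesion_ids or [f"REC_{i+1:06d}" for i in range(self.n)])
        df["label"] = self.labels
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable(n={self.n}, d={self.d}, n_pos={self.n_pos})"


@dataclass(frozen=True)
class MeasurePanel:
    """The five challenge measures plus the high-sensitivity partial AUC.

    ``spec_at_seXX`` is the best empirical specificity attainable subject to
    sensitivity >= 0.XX. ``pauc_se95_100_raw`` is the area under the ROC
    restricted to the sensitivity band [0.95, 1] (integrating specificity
    over sensitivity, so it lies in [0, 0.05]); the ``_norm`` field divides
    by the band width 0.05.
    """

    average_precision: float
    auc_roc: float
    spec_at_se95: float
    spec_at_se98: float
    spec_at_se99: float
    pauc_se95_100_raw: float
    pauc_se95_100_norm: float

    def __post_init__(self) -> None:
        for name in PANEL_MEASURES:
            v = getattr(self, name)
            hi = 0.05 if name == "pauc_se95_100_raw" else 1.0
            if not (-1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"{name}={v} outside [0, {hi}]")
        if not (
            self.spec_at_se95 >= self.spec_at_se98 - 1e-12
            and self.spec_at_se98 >= self.spec_at_se99 - 1e-12
        ):
            raise ValueError("specificity must be non-increasing in the target")
        if abs(self.pauc_se95_100_norm - self.pauc_se95_100_raw / 0.05) > 1e-9:
            raise ValueError("normalised partial AUC inconsistent with raw value")

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in PANEL_MEASURES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MeasurePanel":
        return cls(**{m: float(d[m]) for m in PANEL_MEASURES})
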