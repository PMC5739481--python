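"""Readers and writers for submissions, ground truth, feature tables and rank tables.

All formats are comma-separated UTF-8 text with a decimal point. A header
row is auto-detected: if the second field of the first row does not parse as
a number (or, for truth files, as a label), the row is treated as a header.
Scores are written with 10 decimals so that files round-trip bit-identically
across platforms.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dermeval.cohort import (
    FeatureTable,
    LesionRecord,
    ScoredCohort,
    parse_label,
)

logger = logging.getLogger(__name__)

SCORE_DECIMALS = 10


class SubmissionFormatError(ValueError):
    """Malformed or invalid submission/truth file."""


def _read_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = [
            (lineno, [c.strip() for c in row])
            for lineno, row in enumerate(csv.reader(fh), start=1)
            if row and any(c.strip() for c in row)
        ]
    if not rows:
        raise SubmissionFormatError(f"{path}: file is empty")
    return rows


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _check_unique(ids: list[str], path: Path) -> None:
    seen: set[str] = set()
    for lid in ids:
        if lid in seen:
            raise SubmissionFormatError(f"{path}: duplicate lesion_id {lid!r}")
        seen.add(lid)


def read_submission(path: str | Path) -> list[LesionRecord]:
    """Read a two-column submission file: ``lesion_id,score``.

    Scores must be real numbers in [0, 1]. Raises
    :class:`SubmissionFormatError` naming the offending line on malformed
    rows, out-of-range scores, or duplicated identifiers.
    """
    path = Path(path)
    rows = _read_rows(path)
    if not _is_number(rows[0][1][1] if len(rows[0][1]) > 1 else ""):
        rows = rows[1:]  # header
        if not rows:
            raise SubmissionFormatError(f"{path}: no data rows after header")
    records = []
    for lineno, row in rows:
        if len(row) != 2:
            raise SubmissionFormatError(
                f"{path}:{lineno}: expected 2 fields (lesion_id,score), got {len(row)}"
            )
        lid, raw = row
        if not _is_number(raw):
            raise SubmissionFormatError(f"{path}:{lineno}: score {raw!r} is not a number")
        try:
            records.append(LesionRecord(lid, float(raw)))
        except ValueError as exc:
            raise SubmissionFormatError(f"{path}:{lineno}: {exc}") from None
    _check_unique([r.lesion_id for r in records], path)
    n_sat = sum(1 for r in records if r.score in (0.0, 1.0))
    if n_sat:
        logger.info("%s: %d saturated score(s) (exactly 0 or 1)", path, n_sat)
    return records


def read_truth(path: str | Path) -> list[LesionRecord]:
    """Read a two-column ground-truth file: ``lesion_id,label``.

    Labels are 'benign'/'malignant' (case-insensitive) or 0/1.
    """
    path = Path(path)
    rows = _read_rows(path)

    def _is_label(token: str) -> bool:
        try:
            parse_label(token)
        except ValueError:
            return False
        return True

    if len(rows[0][1]) > 1 and not _is_label(rows[0][1][1]):
        rows = rows[1:]
        if not rows:
            raise SubmissionFormatError(f"{path}: no data rows after header")
    records = []
    for lineno, row in rows:
        if len(row) != 2:
            raise SubmissionFormatError(
                f"{path}:{lineno}: expected 2 fields (lesion_id,label), got {len(row)}"
            )
        lid, raw = row
        try:
            records.append(LesionRecord(lid, label=parse_label(raw)))
        except ValueError as exc:
            raise SubmissionFormatError(f"{path}:{lineno}: {exc}") from None
    _check_unique([r.lesion_id for r in records], path)
    return records


def write_submission(records: Iterable[LesionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lesion_id", "score"])
        for r in records:
            writer.writerow([r.lesion_id, f"{r.score:.{SCORE_DECIMALS}f}"])


def write_truth(records: Iterable[LesionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lesion_id", "label"])
        for r in records:
            writer.writerow([r.lesion_id, "malignant" if r.label else "benign"])


def join_cohort(
    submission: Sequence[LesionRecord], truth: Sequence[LesionRecord]
) -> ScoredCohort:
    """Inner-join submission scores with truth labels on ``lesion_id``.

    The join must be a perfect 1:1 match: every truth id present exactly
    once in the submission and vice versa. Record order follows the truth
    file; class counts are taken from the truth labels.
    """
    if not submission or not truth:
        raise ValueError("submission and truth must both be non-empty")
    scores = {r.lesion_id: r.score for r in submission}
    labels = {r.lesion_id: r.label for r in truth}
    missing_in_sub = sorted(set(labels) - set(scores))
    extra_in_sub = sorted(set(scores) - set(labels))
    if missing_in_sub or extra_in_sub:
        parts = []
        if missing_in_sub:
            parts.append(f"ids in truth missing from submission: {missing_in_sub[:10]}")
        if extra_in_sub:
            parts.append(f"ids in submission missing from truth: {extra_in_sub[:10]}")
        raise ValueError("; ".join(parts))
    ids = [r.lesion_id for r in truth]
    return ScoredCohort([scores[i] for i in ids], [labels[i] for i in ids], ids)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature CSV: ``lesion_id, f1..fd, label`` (header required)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise SubmissionFormatError(
            f"{path}: need lesion_id, at least one feature, and label columns"
        )
    if df.isna().any().any():
        raise SubmissionFormatError(f"{path}: missing values are not allowed")
    ids = df.iloc[:, 0].astype(str).tolist()
    labels = [parse_label(v) for v in df.iloc[:, -1]]
    feats = df.iloc[:, 1:-1]
    return FeatureTable(feats, labels, list(feats.columns), ids)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_frame()
    df["label"] = np.where(df["label"] == 1, "malignant", "benign")
    df.to_csv(path, index=False, float_format=f"%.{SCORE_DECIMALS}g")


def write_rank_table(table, path: str | Path) -> None:
    """Write a rank table: one row per measure, one integer column per system."""
    df = table.ranks
    if df.empty:
        raise ValueError("rank table is empty")
    out = df.copy()
    out.insert(0, "measure", df.index)
    out.to_csv(path, index=False)


def read_rank_table(path: str | Path):
    """Read a rank table written by :func:`write_rank_table`.

    Returns a bare :class:`~dermeval.ranking.RankTable` (integer ranks only;
    the underlying scores are not stored in the file).
    """
    from dermeval.ranking import RankTable

    df = pd.read_csv(path)
    if "measure" not in df.columns:
        raise SubmissionFormatError(f"{path}: missing 'measure' column")
    ranks = df.set_index("measure")
    ranks.index.name = None
    ranks.columns.name = None
    return RankTable(ranks=ranks.astype(int), scores=None)
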