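"""End-to-end challenge re-enactment: simulate -> evaluate -> rank -> report.

Every run writes a ``manifest.json`` echoing the fully resolved configuration
and the package version. Output files contain no timestamps, so a rerun with
the same configuration and seed is byte-identical; timestamps are confined to
log messages. While a run is in progress all files live in a ``_incomplete``
staging subdirectory; on success they are moved up, on failure they stay
quarantined there and the failing stage is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from pathlib import Path

import pandas as pd

import dermeval
from dermeval.cohort import PANEL_MEASURES, ScoredCohort
from dermeval.io import write_rank_table, write_submission, write_truth
from dermeval.metrics import measure_panel, pr_curve, roc_curve
from dermeval.ranking import SystemEntry, rank_instability, rank_systems
from dermeval.simulate import DEFAULT_SUITE_SEED, make_rank_reversal_suite

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    seed: int = DEFAULT_SUITE_SEED
    se_targets: tuple[float, float, float] = (0.95, 0.98, 0.99)
    pauc_lo: float = 0.95
    interpolation: str = "none"
    measures: tuple[str, ...] = PANEL_MEASURES
    bootstrap: int = 0
    write_curves: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = dermeval.__version__
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_curves(cohort: ScoredCohort, stem: Path) -> None:
    c = roc_curve(cohort)
    pd.DataFrame(
        {"fpr": c.fpr, "tpr": c.tpr, "threshold": c.thresholds}
    ).to_csv(f"{stem}_roc.csv", index=False, float_format="%.10g")
    r, p, t = pr_curve(cohort)
    pd.DataFrame(
        {"recall": r, "precision": p, "threshold": t}
    ).to_csv(f"{stem}_pr.csv", index=False, float_format="%.10g")


def evaluate_cohorts(
    cohorts: dict[str, ScoredCohort], config: RunConfig
) -> tuple[pd.DataFrame, list[SystemEntry]]:
    """Measure panels for a set of scored systems sharing one truth."""
    entries = [
        SystemEntry(
            sid,
            measure_panel(
                c,
                se_targets=config.se_targets,
                pauc_lo=config.pauc_lo,
                interpolation=config.interpolation,
            ),
        )
        for sid, c in sorted(cohorts.items())
    ]
    panels = pd.DataFrame(
        {e.system_id: e.panel.as_dict() for e in entries}
    ).T.loc[:, list(PANEL_MEASURES)]
    panels.index.name = "system_id"
    return panels, entries


def run_pipeline(config: RunConfig) -> Path:
    """Full re-enactment on the rank-reversal preset; returns the bundle dir.

    The bundle contains the simulated truth and per-system submissions, a
    systems-by-measures panel CSV, the rank table, the instability JSON,
    per-system ROC/PR curve CSVs and a plain-text summary naming the top
    system per measure.
    """
    out_dir = Path(config.out_dir)
    staging = out_dir / "_incomplete"
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    stage = "simulate"
    try:
        suite = make_rank_reversal_suite(config.seed)
        sub_dir = staging / "submissions"
        sub_dir.mkdir()
        write_truth(suite.truth, staging / "truth.csv")
        for sid, sub in sorted(suite.submissions.items()):
            write_submission(sub, sub_dir / f"{sid}.csv")

        stage = "evaluate"
        panels, entries = evaluate_cohorts(suite.cohorts, config)
        panels.to_csv(staging / "panels.csv", float_format="%.10g")
        if config.write_curves:
            curve_dir = staging / "curves"
            curve_dir.mkdir()
            for sid, cohort in sorted(suite.cohorts.items()):
                _write_curves(cohort, curve_dir / sid)
        if config.bootstrap:
            from dermeval.resampling import bootstrap_panel

            rows = {}
            for sid, cohort in sorted(suite.cohorts.items()):
                rp = bootstrap_panel(cohort, B=config.bootstrap, seed=config.seed)
                s = rp.summary_frame()
                rows[sid] = {
                    f"{m}_{col}": s.loc[m, col]
                    for m in s.index
                    for col in ("mean", "ci_lo", "ci_hi")
                }
            pd.DataFrame(rows).T.rename_axis("system_id").to_csv(
                staging / "bootstrap_summary.csv", float_format="%.10g"
            )

        stage = "rank"
        table = rank_systems(entries, config.measures)
        write_rank_table(table, staging / "rank_table.csv")
        report = rank_instability(table)
        _write_json(report.to_dict(), staging / "instability.json")

        stage = "report"
        lines = ["Top system per measure", "======================"]
        for m in table.measures:
            row = table.ranks.loc[m]
            best = sorted(row.index[row == 1])
            score = table.scores.loc[m, best[0]]
            lines.append(f"{m}: {', '.join(best)} (value {score:.4f})")
        (staging / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        _write_json(config.to_dict(), staging / "manifest.json")
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    for item in staging.iterdir():
        dest = out_dir / item.name
        if dest.exists():
            shutil.rmtree(dest) if dest.is_dir() else dest.unlink()
        shutil.move(str(item), dest)
    staging.rmdir()
    logger.info("pipeline bundle written to %s", out_dir)
    return out_dir


__all__ = ["RunConfig", "StageError", "run_pipeline", "evaluate_cohorts"]
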