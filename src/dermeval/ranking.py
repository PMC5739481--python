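"""Multi-system, multi-measure leaderboards and rank-instability statistics.

A leaderboard that looks decisive under one accuracy measure can reorder
drastically under another: a system tuned for global separability may top
the average-precision ranking yet fall to mid-field when systems are ranked
by specificity at 98% sensitivity. This module builds the measures-by-systems
rank table and quantifies that instability (per-system rank shifts and
Kendall tau-b between measure rankings).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from dermeval.cohort import PANEL_MEASURES, MeasurePanel


@dataclass(frozen=True)
class SystemEntry:
    """One system on the leaderboard: identifier plus its measure panel."""

    system_id: str
    panel: MeasurePanel

    def __post_init__(self) -> None:
        if not self.system_id:
            raise ValueError("system_id must be non-empty")


@dataclass(frozen=True)
class RankTable:
    """Measures-by-systems integer ranks (competition ranking, best = 1).

    ``scores`` holds the underlying measure values on the same grid; it is
    ``None`` for tables read back from disk, which store ranks only.
    """

    ranks: pd.DataFrame
    scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ranks.empty:
            raise ValueError("rank table must not be empty")
        vals = self.ranks.to_numpy()
        if (vals < 1).any() or (vals > self.ranks.shape[1]).any():
            raise ValueError("ranks must lie in 1..n_systems")
        for _, row in self.ranks.iterrows():
            if not _is_competition_ranking(row.to_numpy()):
                raise ValueError(f"row {row.name!r} is not a competition ranking")

    @property
    def measures(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def systems(self) -> list[str]:
        return list(self.ranks.columns)


def _is_competition_ranking(r: np.ndarray) -> bool:
    """'1224'-style ranking: rank of x = 1 + number of strictly better systems."""
    counts: dict[int, int] = {}
    for v in r:
        counts[int(v)] = counts.get(int(v), 0) + 1
    expected = 1
    for v in sorted(counts):
        if v != expected:
            return False
        expected += counts[v]
    return True


def competition_ranks(values: np.ndarray) -> np.ndarray:
    """Competition ranking with larger values better; ties share the best rank."""
    return rankdata(-np.asarray(values, dtype=float), method="min").astype(int)


def rank_systems(
    entries: Sequence[SystemEntry],
    measures: Sequence[str] | None = None,
) -> RankTable:
    """Rank systems per measure; higher measure value gives a smaller rank.

    Columns are ordered by system_id for a deterministic display; the ranks
    themselves depend only on the measure values.
    """
    if len(entries) < 2:
        raise ValueError("ranking requires at least 2 systems")
    ids = [e.system_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate system_id in ranking input")
    measures = list(measures) if measures is not None else list(PANEL_MEASURES)
    for m in measures:
        if m not in PANEL_MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    order = np.argsort(ids)
    entries = [entries[i] for i in order]
    ids = [ids[i] for i in order]
    scores = pd.DataFrame(
        {e.system_id: [getattr(e.panel, m) for m in measures] for e in entries},
        index=measures,
        dtype=float,
    )
    ranks = pd.DataFrame(
        {
            m: competition_ranks(scores.loc[m].to_numpy())
            for m in measures
        },
        index=ids,
    ).T
    return RankTable(ranks=ranks, scores=scores)


@dataclass(frozen=True)
class InstabilityReport:
    """How much the leaderboard depends on the choice of measure.

    * ``max_shift_per_system``: for each system, the largest absolute rank
      difference between any two measures.
    * ``tau_per_measure_pair``: Kendall tau-b between the rank vectors of
      every measure pair (ties handled by the b-correction).
    * ``mean_shift`` / ``max_shift``: mean and max of the per-system shifts.
    """

    max_shift_per_system: pd.Series
    tau_per_measure_pair: pd.DataFrame
    mean_shift: float
    max_shift: int

    def to_dict(self) -> dict:
        return {
            "max_shift_per_system": {
                k: int(v) for k, v in self.max_shift_per_system.items()
            },
            "tau_per_measure_pair": {
                m: {k: float(v) for k, v in row.items()}
                for m, row in self.tau_per_measure_pair.iterrows()
            },
            "mean_shift": float(self.mean_shift),
            "max_shift": int(self.max_shift),
        }


def kendall_tau_b(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Kendall tau-b between two rank vectors (scipy implementation)."""
    tau = kendalltau(r1, r2, variant="b").statistic
    return float(tau)


def rank_instability(table: RankTable) -> InstabilityReport:
    """Rank-shift and rank-correlation summary of a rank table."""
    if len(table.measures) < 2:
        raise ValueError("instability analysis needs at least 2 measures")
    ranks = table.ranks
    shifts = (ranks.max(axis=0) - ranks.min(axis=0)).astype(int)
    taus = pd.DataFrame(
        np.eye(len(table.measures)), index=table.measures, columns=table.measures
    )
    for i, mi in enumerate(table.measures):
        for mj in table.measures[i + 1 :]:
            t = kendall_tau_b(ranks.loc[mi].to_numpy(), ranks.loc[mj].to_numpy())
            taus.loc[mi, mj] = t
            taus.loc[mj, mi] = t
    return InstabilityReport(
        max_shift_per_system=shifts,
        tau_per_measure_pair=taus,
        mean_shift=float(shifts.mean()),
        max_shift=int(shifts.max()),
    )


__all__ = [
    "SystemEntry",
    "RankTable",
    "InstabilityReport",
    "competition_ranks",
    "rank_systems",
    "rank_instability",
    "kendall_tau_b",
]
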