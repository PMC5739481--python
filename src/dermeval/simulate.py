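"""Seeded generators for challenge-scale synthetic submissions and feature tables.

The generators emulate the 2016 skin-lesion classification challenge cohort:
a fixed test set of 379 lesions of which exactly 75 are melanomas, a training
set of 900 lesions, and 25 participating systems. Class counts are fixed by
construction (no binomial sampling of prevalence), mirroring a fixed
challenge test set.

Per-system scores are drawn class-conditionally from Beta mixtures: Beta
distributions live on [0, 1] like posterior probabilities, and mixture
components let the two tails be shaped independently — which is exactly what
is needed to build systems whose global and high-sensitivity performance
disagree. The shipped 25-system suite contains two engineered archetypes:

* ``global-optimiser`` — most melanomas score very high (top average
  precision) but a small melanoma fraction scores low, so reaching 98%
  sensitivity forces a low threshold and poor specificity;
* ``high-sensitivity-optimiser`` — melanoma scores are bounded away from the
  benign bulk (excellent specificity at 98-99% sensitivity) while extra
  benign/melanoma overlap in the mid-range keeps its average precision
  unremarkable.

All outputs are deterministic functions of a single integer seed; emitted
scores are rounded to 10 decimals so written files are bit-identical across
platforms.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from dermeval.cohort import FeatureTable, LesionRecord, ScoredCohort

logger = logging.getLogger(__name__)

#: cohort defaults: 379 test lesions (75 melanomas), 900 training lesions
DEFAULT_N_TEST = 379
DEFAULT_N_MELANOMA = 75
DEFAULT_N_TRAIN = 900
#: automatic-segmentation participation count
DEFAULT_N_SYSTEMS = 25

#: shipped default seed for the rank-reversal suite
DEFAULT_SUITE_SEED = 20160379

SCORE_DECIMALS = 10


def _substream(seed: int, *counters: int) -> np.random.Generator:
    """Counter-derived child stream of a single integer seed."""
    return np.random.default_rng([int(seed) % 2**31, *counters])


def _id_counter(system_id: str) -> int:
    """Stable 31-bit counter for a system identifier (platform-independent)."""
    return zlib.crc32(system_id.encode("utf-8")) % 2**31


@dataclass(frozen=True)
class BetaMixture:
    """Finite mixture of Beta distributions on [0, 1].

    ``components`` is a tuple of (weight, a, b); weights must be positive and
    sum to 1, shapes strictly positive.
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        for w, a, b in self.components:
            if w <= 0:
                raise ValueError("mixture weights must be positive")
            if a <= 0 or b <= 0:
                raise ValueError("Beta shape parameters must be positive")
        if abs(sum(w for w, _, _ in self.components) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @classmethod
    def single(cls, a: float, b: float) -> "BetaMixture":
        return cls(((1.0, a, b),))

    def mean(self) -> float:
        return sum(w * a / (a + b) for w, a, b in self.components)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([w for w, _, _ in self.components])
        comp = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for j, (_, a, b) in enumerate(self.components):
            m = comp == j
            out[m] = rng.beta(a, b, size=int(m.sum()))
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Size and seed of a synthetic challenge cohort."""

    n_test: int = DEFAULT_N_TEST
    n_melanoma: int = DEFAULT_N_MELANOMA
    n_train: int = DEFAULT_N_TRAIN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_melanoma < self.n_test:
            raise ValueError("need 0 < n_melanoma < n_test")
        if self.n_train < 1:
            raise ValueError("n_train must be positive")


@dataclass(frozen=True)
class SystemScoreSpec:
    """Class-conditional score distributions of one synthetic system."""

    system_id: str
    benign: BetaMixture
    melanoma: BetaMixture

    def __post_init__(self) -> None:
        if not self.system_id:
            raise ValueError("system_id must be non-empty")
        if self.melanoma.mean() < self.benign.mean():
            logger.warning(
                "%s: melanoma score distribution not stochastically above benign "
                "(means %.3f < %.3f)",
                self.system_id,
                self.melanoma.mean(),
                self.benign.mean(),
            )


@dataclass(frozen=True)
class SuiteSpec:
    """A cohort shared by a set of synthetic systems, with named archetypes."""

    cohort: CohortSpec
    systems: tuple[SystemScoreSpec, ...]
    archetypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.system_id for s in self.systems]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate system_id in suite")
        for role, sid in self.archetypes.items():
            if sid not in ids:
                raise ValueError(f"archetype {role!r} points at unknown system {sid!r}")

    @property
    def n_systems(self) -> int:
        return len(self.systems)


def simulate_cohort_scores(
    spec: SystemScoreSpec, cohort: CohortSpec
) -> tuple[list[LesionRecord], list[LesionRecord]]:
    """Synthetic (submission, ground truth) for one system on one cohort.

    The truth has exactly ``cohort.n_melanoma`` malignant labels; scores are
    drawn class-conditionally from the system's Beta mixtures, rounded to 10
    decimals. Lesion ids are ``SYN_000001``... The draw is a deterministic
    function of ``cohort.seed`` and the system id.
    """
    n_pos = cohort.n_melanoma
    n_neg = cohort.n_test - n_pos
    rng = _substream(cohort.seed, _id_counter(spec.system_id))
    scores = np.r_[spec.melanoma.sample(rng, n_pos), spec.benign.sample(rng, n_neg)]
    scores = np.round(scores, SCORE_DECIMALS)
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    ids = [f"SYN_{i + 1:06d}" for i in range(cohort.n_test)]
    submission = [LesionRecord(i, float(s)) for i, s in zip(ids, scores)]
    truth = [LesionRecord(i, label=int(l)) for i, l in zip(ids, labels)]
    return submission, truth


def simulate_scored_cohort(spec: SystemScoreSpec, cohort: CohortSpec) -> ScoredCohort:
    """Convenience wrapper: generate and join in one step."""
    from dermeval.io import join_cohort

    submission, truth = simulate_cohort_scores(spec, cohort)
    return join_cohort(submission, truth)


def simulate_feature_table(
    cohort: CohortSpec,
    d: int,
    mu0: np.ndarray,
    mu1: np.ndarray,
    cov0: np.ndarray,
    cov1: np.ndarray,
    seed: int | None = None,
    n: int | None = None,
) -> FeatureTable:
    """Class-conditional multivariate-Gaussian feature table.

    ``n`` defaults to ``cohort.n_test`` rows with the cohort's class balance
    (n_melanoma positives); covariances must be symmetric positive definite.
    The Gaussian draws use the Cholesky factor of each covariance for
    platform-stable determinism.
    """
    mu0 = np.asarray(mu0, dtype=float).reshape(-1)
    mu1 = np.asarray(mu1, dtype=float).reshape(-1)
    if mu0.size != d or mu1.size != d:
        raise ValueError("class means must have length d")
    chols = []
    for name, cov in (("cov0", cov0), ("cov1", cov1)):
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (d, d) or not np.allclose(cov, cov.T):
            raise ValueError(f"{name} must be a symmetric (d, d) matrix")
        try:
            chols.append(np.linalg.cholesky(cov))
        except np.linalg.LinAlgError:
            raise ValueError(f"{name} is not positive definite") from None
    if n is None:
        n = cohort.n_test
    n_pos = round(n * cohort.n_melanoma / cohort.n_test)
    n_pos = min(max(n_pos, 1), n - 1)
    n_neg = n - n_pos
    rng = _substream(cohort.seed if seed is None else seed, 2)
    X0 = rng.standard_normal((n_neg, d)) @ chols[0].T + mu0
    X1 = rng.standard_normal((n_pos, d)) @ chols[1].T + mu1
    X = np.vstack([X1, X0])
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    ids = [f"SYN_{i + 1:06d}" for i in range(n)]
    return FeatureTable(X, labels, [f"f{j + 1}" for j in range(d)], ids)


# ---------------------------------------------------------------------------
# Rank-reversal suite
# ---------------------------------------------------------------------------

#: archetype score distributions, found once by seeded search and frozen.
#: global-optimiser: tight high melanoma bulk + small low melanoma tail;
#: benign bulk low with a small high-score component.
GLOBAL_OPTIMISER_SPEC = dict(
    melanoma=BetaMixture(((0.90, 24.0, 5.0), (0.10, 2.0, 6.0))),
    benign=BetaMixture(((0.97, 2.0, 10.0), (0.03, 18.0, 4.0))),
)
#: high-sensitivity-optimiser: melanoma bounded away from the benign bulk,
#: with benign/melanoma overlap in the mid-range that suppresses AP.
HIGH_SENSITIVITY_SPEC = dict(
    melanoma=BetaMixture.single(22.0, 9.0),
    benign=BetaMixture(((0.80, 3.0, 9.0), (0.20, 8.0, 7.0))),
)

GLOBAL_OPTIMISER_ID = "SYS_A_global"
HIGH_SENSITIVITY_ID = "SYS_B_highsens"


def _mediocre_specs(n: int, seed: int) -> list[SystemScoreSpec]:
    """Deterministic family of unremarkable mid-field systems."""
    rng = _substream(seed, 3)
    specs = []
    for i in range(n):
        sep = rng.uniform(0.16, 0.34)  # mean separation between classes
        mean_b = rng.uniform(0.20, 0.32)
        mean_m = min(mean_b + sep, 0.85)
        conc_b = rng.uniform(6.0, 12.0)
        conc_m = rng.uniform(6.0, 12.0)
        specs.append(
            SystemScoreSpec(
                system_id=f"SYS_{i + 3:02d}",
                benign=BetaMixture.single(mean_b * conc_b, (1 - mean_b) * conc_b),
                melanoma=BetaMixture.single(mean_m * conc_m, (1 - mean_m) * conc_m),
            )
        )
    return specs


@dataclass(frozen=True)
class GeneratedSuite:
    """A suite spec together with its generated scores."""

    spec: SuiteSpec
    truth: list[LesionRecord]
    submissions: dict[str, list[LesionRecord]]
    cohorts: dict[str, ScoredCohort]


def make_rank_reversal_suite(seed: int = DEFAULT_SUITE_SEED) -> GeneratedSuite:
    """25 systems over one shared cohort, engineered for measure disagreement.

    The suite contains the two archetypes above plus 23 mid-field systems.
    With the shipped default seed the global-optimiser tops the
    average-precision ranking yet drops at least five positions under
    specificity at 98% sensitivity — the hallmark of measure-dependent
    leaderboards.
    """
    cohort = CohortSpec(seed=seed)
    systems = [
        SystemScoreSpec(GLOBAL_OPTIMISER_ID, **GLOBAL_OPTIMISER_SPEC),
        SystemScoreSpec(HIGH_SENSITIVITY_ID, **HIGH_SENSITIVITY_SPEC),
        *_mediocre_specs(DEFAULT_N_SYSTEMS - 2, seed),
    ]
    suite = SuiteSpec(
        cohort=cohort,
        systems=tuple(systems),
        archetypes={
            "global-optimiser": GLOBAL_OPTIMISER_ID,
            "high-sensitivity-optimiser": HIGH_SENSITIVITY_ID,
            "mediocre": "SYS_03",
        },
    )
    from dermeval.io import join_cohort

    truth: list[LesionRecord] | None = None
    submissions: dict[str, list[LesionRecord]] = {}
    cohorts: dict[str, ScoredCohort] = {}
    for sys_spec in suite.systems:
        sub, tr = simulate_cohort_scores(sys_spec, cohort)
        if truth is None:
            truth = tr
        submissions[sys_spec.system_id] = sub
        cohorts[sys_spec.system_id] = join_cohort(sub, truth)
    assert truth is not None
    return GeneratedSuite(spec=suite, truth=truth, submissions=submissions, cohorts=cohorts)


__all__ = [
    "BetaMixture",
    "CohortSpec",
    "SystemScoreSpec",
    "SuiteSpec",
    "GeneratedSuite",
    "simulate_cohort_scores",
    "simulate_scored_cohort",
    "simulate_feature_table",
    "make_rank_reversal_suite",
    "DEFAULT_N_TEST",
    "DEFAULT_N_MELANOMA",
    "DEFAULT_N_TRAIN",
    "DEFAULT_N_SYSTEMS",
    "DEFAULT_SUITE_SEED",
]
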