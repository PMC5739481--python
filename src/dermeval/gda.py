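"""Gaussian discriminant classifiers: LDA, QDA and their diagonal (naive Bayes) variants.

The classifier models each class k as a multivariate Gaussian
N(mu_k, Sigma_k) and outputs the Bayes posterior probability of malignancy

    P(malignant | x) = pi_1 f_1(x) / (pi_0 f_0(x) + pi_1 f_1(x)).

Variants differ only in the covariance structure:

* ``lda``  — pooled full covariance (within-class, denominator n - 2);
* ``qda``  — per-class full covariances (denominator n_k - 1);
* ``dlda`` — pooled covariance with off-diagonal entries zeroed;
* ``dqda`` — per-class diagonal covariances (Gaussian naive Bayes).

Two operating-curve constructions are provided. ``threshold_sweep`` sweeps a
threshold on the posterior from 0 to 1; ``prior_sweep`` instead varies the
class prior and classifies at posterior 0.5. Varying the prior adds a
constant to every lesion's log-odds, so the two sweeps visit the same
operating points — but the prior sweep reads off each point at a posterior
near 0.5, away from the saturated regime where many lesions share the
posterior 1.00 at working precision. All densities are evaluated in the log
domain; a posterior outside (1e-15, 1 - 1e-15) is flagged as saturated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

from dermeval.cohort import FeatureTable, ScoredCohort
from dermeval.metrics import OperatingCurve, roc_curve_from_scores

logger = logging.getLogger(__name__)

VARIANTS = ("lda", "qda", "dlda", "dqda")

#: posterior closer than this to 0 or 1 counts as saturated at working precision
SATURATION_EPS = 1e-15

#: default prior grid: 201 points uniform in prior log-odds over [-12, 12]
PRIOR_LOGODDS_RANGE = (-12.0, 12.0)
PRIOR_GRID_SIZE = 201


def _logdet_and_solve(cov: np.ndarray):
    """Cholesky log-determinant and solver; raises LinAlgError if not PD."""
    c, low = cho_factor(cov, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return logdet, (c, low)


@dataclass(frozen=True)
class GaussianClassModel:
    """Fitted Gaussian discriminant model.

    ``cov0``/``cov1`` are the class covariance matrices after the variant's
    structure (pooled/diagonal) and the ridge have been applied; for pooled
    variants the two are identical.
    """

    variant: str
    mu0: np.ndarray
    mu1: np.ndarray
    cov0: np.ndarray
    cov1: np.ndarray
    prior1: float
    ridge: float

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.prior1 < 1.0:
            raise ValueError("prior1 must lie strictly inside (0, 1)")
        for arr in (self.mu0, self.mu1):
            if not np.all(np.isfinite(arr)):
                raise ValueError("class means must be finite")

    @property
    def d(self) -> int:
        return self.mu0.size

    def log_density_diff(self, X: np.ndarray) -> np.ndarray:
        """Delta(x) = log f1(x) - log f0(x), the prior-free log-likelihood ratio."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature values must be finite")
        logdets, solvers = {}, {}
        for k, cov in ((0, self.cov0), (1, self.cov1)):
            try:
                logdets[k], solvers[k] = _logdet_and_solve(cov)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"{self.variant}: class-{k} covariance not positive definite"
                ) from None
        d0 = X - self.mu0
        d1 = X - self.mu1
        q0 = np.einsum("ij,ij->i", d0, cho_solve(solvers[0], d0.T).T)
        q1 = np.einsum("ij,ij->i", d1, cho_solve(solvers[1], d1.T).T)
        out = 0.5 * (q0 - q1) + 0.5 * (logdets[0] - logdets[1])
        return out


def fit_gda(
    features: FeatureTable,
    variant: str = "qda",
    ridge: float | None = None,
    prior: float | None = None,
) -> GaussianClassModel:
    """Fit a Gaussian discriminant model to a labelled feature table.

    Parameters
    ----------
    variant
        One of ``lda``, ``qda``, ``dlda``, ``dqda``.
    ridge
        Value added to every diagonal entry of the covariance estimate(s).
        ``None`` uses the default 1e-6 times the mean within-class variance;
        pass 0 for the raw estimator (raises if it is singular).
    prior
        Fixed training prior pi_1; ``None`` uses the empirical class fraction.

    The pooled covariance (LDA/dLDA) is the within-class estimator with
    denominator n - 2; per-class covariances (QDA/dQDA) use n_k - 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    X0 = features.class_matrix(0)
    X1 = features.class_matrix(1)
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 rows to estimate a covariance")
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    s0 = (X0 - mu0).T @ (X0 - mu0)
    s1 = (X1 - mu1).T @ (X1 - mu1)
    if variant in ("lda", "dlda"):
        pooled = (s0 + s1) / (features.n - 2)
        cov0 = cov1 = pooled
    else:
        cov0 = s0 / (len(X0) - 1)
        cov1 = s1 / (len(X1) - 1)
    if variant in ("dlda", "dqda"):
        cov0 = np.diag(np.diag(cov0))
        cov1 = np.diag(np.diag(cov1))
    if ridge is None:
        ridge = 1e-6 * float(np.mean(np.r_[np.diag(cov0), np.diag(cov1)]))
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    eye = np.eye(features.d)
    cov0 = cov0 + ridge * eye
    cov1 = cov1 + ridge * eye
    for k, cov in ((0, cov0), (1, cov1)):
        try:
            cho_factor(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"{variant}: singular class-{k} covariance (ridge={ridge}); "
                "increase the ridge"
            ) from None
    if prior is None:
        prior = features.n_pos / features.n
    return GaussianClassModel(
        variant=variant,
        mu0=mu0,
        mu1=mu1,
        cov0=cov0,
        cov1=cov1,
        prior1=float(prior),
        ridge=float(ridge),
    )


def posterior(
    model: GaussianClassModel,
    X: np.ndarray | Sequence[float],
    prior_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probability of malignancy for each row of ``X``.

    Computed as expit(Delta(x) + logit(pi_1)) with Delta the class
    log-density difference — numerically stable for extreme log-odds.
    Returns ``(posteriors, saturated)`` where ``saturated`` flags values that
    round to 0 or 1 at working precision.
    """
    pi1 = model.prior1 if prior_override is None else prior_override
    if not 0.0 < pi1 < 1.0:
        raise ValueError("prior must lie strictly inside (0, 1)")
    log_odds = model.log_density_diff(X) + logit(pi1)
    post = expit(log_odds)
    saturated = (post <= SATURATION_EPS) | (post >= 1.0 - SATURATION_EPS)
    if saturated.any():
        logger.info(
            "%d/%d posterior(s) saturated at working precision",
            int(saturated.sum()),
            post.size,
        )
    return post, saturated


def score_cohort(
    model: GaussianClassModel,
    features: FeatureTable,
    prior_override: float | None = None,
) -> ScoredCohort:
    """Score a labelled feature table with the model's posteriors."""
    post, _ = posterior(model, features.X, prior_override)
    return ScoredCohort(post, features.labels, features.lesion_ids)


def threshold_sweep(
    model: GaussianClassModel, features: FeatureTable
) -> OperatingCurve:
    """Operating curve from sweeping a posterior threshold from 0 to 1.

    Internally the sweep orders lesions by their log-odds rather than the
    posterior itself: the two orderings are identical in exact arithmetic,
    but the log-odds never collapse distinct lesions that merely share a
    saturated posterior of 1.00 at working precision. Posterior-value
    thresholds are attached to the returned points.
    """
    delta = model.log_density_diff(features.X)
    curve = roc_curve_from_scores(delta, features.labels)
    return OperatingCurve(
        fpr=curve.fpr,
        tpr=curve.tpr,
        thresholds=expit(curve.thresholds + logit(model.prior1)),
    )


def default_prior_grid() -> np.ndarray:
    """201 priors uniform in log-odds over [-12, 12]."""
    return expit(np.linspace(*PRIOR_LOGODDS_RANGE, PRIOR_GRID_SIZE))


def prior_sweep(
    model: GaussianClassModel,
    features: FeatureTable,
    grid: np.ndarray | Sequence[float] | None = None,
) -> OperatingCurve:
    """Operating curve from sweeping the class prior, classifying at posterior 0.5.

    For each prior pi in the grid a lesion is called malignant iff its
    posterior under pi is at least 0.5, i.e. iff Delta(x) + logit(pi) >= 0.
    The supplied grid (default: 201 priors uniform in log-odds over
    [-12, 12]) is always augmented with the exact breakpoints
    logit(pi) = -Delta(x), so every achievable operating point is visited
    and the curve coincides with :func:`threshold_sweep`'s.
    """
    if grid is None:
        grid_logodds = np.linspace(*PRIOR_LOGODDS_RANGE, PRIOR_GRID_SIZE)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("prior grid must be non-empty")
        if np.any((grid <= 0.0) | (grid >= 1.0)):
            raise ValueError("prior grid values must lie strictly inside (0, 1)")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("prior grid must be strictly increasing")
        grid_logodds = logit(grid)

    delta = model.log_density_diff(features.X)
    lam = np.unique(np.r_[grid_logodds, -delta])
    labels = features.labels
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("prior sweep requires both classes in the features")
    points = {}
    for lo in lam:
        pred = delta + lo >= 0.0
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        points[(fp / n_neg, tp / n_pos)] = lo
    points.setdefault((0.0, 0.0), -np.inf)
    points.setdefault((1.0, 1.0), np.inf)
    pts = sorted(points)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    # thresholds field carries the prior at which each point is attained;
    # larger priors call more lesions malignant, so priors increase along the curve
    priors = expit(np.array([points[p] for p in pts]))
    return OperatingCurve(fpr=fpr, tpr=tpr, thresholds=priors)


__all__ = [
    "VARIANTS",
    "SATURATION_EPS",
    "GaussianClassModel",
    "fit_gda",
    "posterior",
    "score_cohort",
    "threshold_sweep",
    "prior_sweep",
    "default_prior_grid",
]
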