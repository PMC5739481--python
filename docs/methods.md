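# Methods

This note records the statistical conventions, numerical choices and design
decisions behind `dermeval`, and what the synthetic-data generators do and
do not emulate.

## Evaluation unit and measures

The evaluation unit is a *scored cohort*: one record per lesion with a
malignancy score in [0, 1] and a binary truth label, positive = malignant.
All operating points use the prediction rule **score ≥ threshold**, so the
threshold equal to the lowest melanoma score always achieves sensitivity 1
exactly. Records sharing a score move between confusion cells together: the
empirical ROC has one step per distinct score value, with endpoints (0,0)
(threshold +∞) and (1,1).

* **AUC of the ROC** — trapezoidal area of that polyline; identical to the
  Mann–Whitney pair probability with ties counting ½ (asserted exactly
  against an exhaustive pair-count oracle in the tests).
* **Average precision** — the uninterpolated step-sum
  `Σ_k (R_k − R_{k−1}) P_k` over descending-score tie blocks, using the
  block-end precision. No 11-point or max-interpolated variants are
  provided.
* **Specificity at sensitivity s ∈ {0.95, 0.98, 0.99}** — the maximum
  empirical specificity over operating points with sensitivity ≥ s, i.e. an
  exactly attainable point, reported with its achieved sensitivity and
  threshold. The convention at the original challenge is not documented
  anywhere we could verify, and with 75 melanomas the ceiling rule
  ⌈0.99·75⌉ = 75 makes "99% sensitivity" equal "miss none"; we deliberately
  encode only the conservative ≥-rule. A linear-interpolation variant
  (specificity interpolated along the ROC at sensitivity exactly s) is
  available behind `interpolation="linear"`.
* **Partial AUC over [0.95, 1] sensitivity** — the integral of specificity
  over sensitivity along the ROC polyline, linearly interpolated at the
  band edge; raw range [0, 0.05], normalised by 0.05. Integrating over the
  sensitivity axis (not 1−specificity) makes the measure a direct
  high-sensitivity summary: a perfect classifier attains 1 after
  normalisation.

Every measure is invariant under strictly increasing transforms of the
scores (property-tested); consequently the panel depends only on the
ranking of scores and the tie pattern.

## Gaussian discriminant classifiers

Class-conditional Gaussians with shared or per-class, full or diagonal
covariance: LDA, QDA, dLDA, dQDA (the diagonal variants are Gaussian naive
Bayes). Estimators: class means are maximum likelihood; the pooled
covariance is the within-class estimator with denominator n − 2; per-class
covariances use n_k − 1. A ridge ε is added to every diagonal entry,
defaulting to 1e-6 times the mean within-class variance — enough to rescue
d ≥ n_k fits without visibly biasing well-conditioned ones; ε = 0 requests
the raw estimator and raises on singularity, naming the variant.

Posteriors are computed in the log domain: the lesion's class log-density
difference Δ(x) = log f₁(x) − log f₀(x) (via Cholesky solves) plus the
prior log-odds, mapped through the logistic function. A posterior outside
(1e-15, 1 − 1e-15) is flagged *saturated*: at 64-bit precision many lesions
can share the printed posterior 1.00, which destroys threshold resolution
exactly where high-sensitivity evaluation needs it.

Two operating-curve constructions:

* **Threshold sweep** — thresholds on the posterior from 0 to 1.
  Internally the curve is built on the Δ ordering, which is identical to the
  posterior ordering in exact arithmetic but never collapses distinct
  lesions that merely share a saturated posterior at float precision.
  Posterior-valued thresholds are attached to the returned points.
* **Prior sweep** — the class prior π is varied and each lesion is called
  malignant iff its posterior under π is ≥ 0.5, i.e. iff
  Δ(x) + logit(π) ≥ 0. The default grid is 201 points uniform in prior
  log-odds over [−12, 12], always augmented with the exact breakpoints
  logit(π) = −Δ(x). With the breakpoints the two sweeps visit identical
  operating-point sets (an exact, property-tested equivalence: varying the
  prior adds a constant to every lesion's log-odds, preserving the
  ordering); the prior sweep reads each point off near posterior 0.5, away
  from the saturated regime — which is its practical reason to exist.

Saturation counts are monotone one-sidedly: raising a tiny prior toward ½
monotonically raises every posterior (saturation at 0 shrinks), and
symmetrically from the high extreme. The two-sided count is *not* monotone:
a lesion with |Δ| beyond the saturation range re-saturates on the opposite
side once the prior crosses midrange.

## Resampling

With 75 positives, specificity at 99% sensitivity is decided by one lesion,
so single-split estimates are noisy. `cv_panel` runs stratified k-fold CV
(default k = 5): each class is shuffled by its own counter-derived stream
and dealt round-robin, guaranteeing both classes in every fold when each
class count is ≥ k (for that reason leave-one-out is a separate pooled-only
helper). The default aggregation pools all out-of-fold scores into one
cohort and computes a single panel — per-fold high-sensitivity measures on
~15 positives per fold are close to meaningless, which is exactly the
instability pooling addresses; per-fold panels are returned alongside.
`bootstrap_panel` resamples an already-scored cohort, by default within
class (preserving n_pos and n_neg exactly), and reports per-measure means,
standard errors and 2.5/97.5 percentile intervals. Percentile rather than
BCa intervals: simple, deterministic, and replaceable if bias correction is
ever needed. All randomness derives from one integer seed with per-resample
streams `default_rng([seed, counter])`; identical seeds give bit-identical
results.

## Ranking and instability

Leaderboards use competition ranking ("1224": tied systems share the best
applicable rank, the next rank is skipped), all measures oriented larger =
better. Display order of columns is alphabetical by system id; ranks depend
only on values. Instability is summarised by each system's maximum rank
difference across measure pairs and by Kendall τ-b between the rank vectors
of every measure pair (τ-b's tie correction matters because competition
ranks tie often); the implementation is scipy's, cross-checked in tests
against an exhaustive pair-enumeration oracle.

## Synthetic data

`CohortSpec` defaults encode the emulated challenge: 379 test lesions of
which exactly 75 melanomas, 900 training lesions; the suite default of 25
systems matches the automatic-segmentation participation. Class counts are
fixed, not binomially sampled, because the emulated test set is fixed.
Scores are drawn class-conditionally from Beta mixtures — supported on
[0, 1] like posteriors, with independently tunable tails; emitted scores are
rounded to 10 decimals so written files are platform-identical.

The shipped rank-reversal suite contains two engineered archetypes and 23
mid-field systems whose Beta parameters are drawn deterministically from
the suite seed (class-mean separation 0.16–0.34, concentrations 6–12 —
AUCs around 0.75–0.9, the plausible mid-field of a dermoscopy challenge):

* *global-optimiser*: melanoma scores 0.9·Beta(24, 5) + 0.1·Beta(2, 6),
  benign 0.97·Beta(2, 10) + 0.03·Beta(18, 4). The tight high melanoma bulk
  dominates the top ranks (top average precision); the 10% low-scoring
  melanoma tail forces the 98%-sensitivity threshold far down, collapsing
  specificity there.
* *high-sensitivity-optimiser*: melanoma Beta(22, 9), benign
  0.8·Beta(3, 9) + 0.2·Beta(8, 7). Melanomas are bounded away from the
  benign bulk (excellent specificity at 98–99% sensitivity) while the
  benign mid-range component suppresses average precision.

The archetype constants were calibrated once by a seeded search and frozen;
the engineered properties (archetype rank 1 by average precision, a drop of
at least 5 positions under specificity at 98% sensitivity, τ-b between the
average-precision and 99%-sensitivity rankings below 0.8) are asserted for
the shipped default seed 20160379 and are intentionally seed-specific.

What the generators do **not** emulate: real submission score
distributions of any challenge participant (so published leaderboard values
are not reproducible here), image content, segmentation or feature
extraction, inter-source heterogeneity, or label noise. A green suite
therefore establishes the correctness of the evaluation machinery and the
qualitative measure-dependence phenomenon, not any quantitative claim about
real systems.

## Degenerate inputs and tie-breaking

Single-class cohorts are rejected wherever a measure needs both classes;
scores exactly 0 or 1 are legal but logged as saturated; duplicate lesion
ids and submission/truth id mismatches are hard errors listing the
offenders. Unstratified bootstrap replicates that come out single-class are
dropped and logged (error only if all are dropped). In
`specificity_at_sensitivity`, among operating points tying on specificity
the reported achieved sensitivity is the largest.
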