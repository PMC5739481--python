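# dermeval

Evaluation and ranking toolkit for melanoma-classification challenges.

Computer systems for melanoma detection are compared by scoring each lesion
image with a posterior probability of malignancy and measuring diagnostic
accuracy against histopathology-backed ground truth. Which accuracy measure
is used matters enormously: global measures (average precision, AUC of the
ROC) weight a missed melanoma the same as an unnecessary excision, while the
clinically relevant regime is high sensitivity — missing a melanoma can be
fatal, a false alarm merely costs an excision. A system that tops a
leaderboard ranked by average precision can fall to the bottom half when
systems are ranked by specificity at 98% sensitivity instead.

`dermeval` packages everything needed to study and run such evaluations:

* **Measures** — for a scored cohort with `n_pos` melanomas and `n_neg`
  benign lesions (positive = malignant, prediction rule `score ≥ t`):
  precision `TP/(TP+FP)`, recall/sensitivity `SE = TP/(TP+FN)`, specificity
  `SP = TN/(TN+FP)`; average precision as the uninterpolated step-sum
  `AP = Σ_k (R_k − R_{k−1}) P_k` over descending-score tie blocks; AUC of the
  empirical ROC (trapezoidal, equal to the Mann–Whitney statistic with ties
  counting ½); specificity at sensitivity targets 95/98/99% (best empirical
  SP subject to `SE ≥ target`); and the partial AUC
  `pAUC = ∫_{0.95}^{1} SP(SE) dSE ∈ [0, 0.05]`, optionally normalised by the
  band width.
* **Classifiers** — Gaussian discriminant analysis: LDA (pooled covariance),
  QDA (per-class), and the diagonal naive-Bayes variants dLDA/dQDA, with
  numerically stable log-domain posteriors, posterior-threshold sweeps, and
  class-prior sweeps that trace the same operating points while avoiding
  saturated posteriors of 1.00.
* **Resampling** — stratified k-fold cross-validation with pooled
  out-of-fold scoring and a stratified bootstrap with percentile intervals,
  for stabilising the high-sensitivity measures (at 75 melanomas, 99%
  sensitivity hinges on a single lesion).
* **Ranking** — measures × systems leaderboards with competition ranking and
  instability statistics (per-system rank shifts, Kendall τ-b between
  measure rankings).
* **Synthetic data** — seeded generators at challenge scale (379 test
  lesions with exactly 75 melanomas, 900 training lesions, 25 systems) using
  Beta-mixture score distributions and Gaussian feature tables, including a
  shipped 25-system suite engineered to exhibit the rank-reversal
  phenomenon.

## Worked example

Score a four-lesion submission against ground truth:

```bash
printf 'L1,0.9\nL2,0.8\nL3,0.7\nL4,0.6\n' > sub.csv
printf 'L1,malignant\nL2,benign\nL3,malignant\nL4,benign\n' > truth.csv
dermeval --out-dir ev evaluate --submission sub.csv --truth truth.csv
```

prints

```
 average_precision  auc_roc  spec_at_se95  spec_at_se98  spec_at_se99  pauc_se95_100_raw  pauc_se95_100_norm
          0.833333     0.75           0.5           0.5           0.5              0.025                 0.5
```

AUC 0.75 is the fraction of (melanoma, benign) pairs ranked correctly: of
the four pairs, L1/L3 beat L4, L1 beats L2, and L3 loses to L2 → 3/4.
Average precision sums precision over the two recall steps:
(1 + 2/3)/2 ≈ 0.833. Reaching 95% sensitivity requires both melanomas, so
the threshold drops to 0.7 and one of the two benign lesions is a false
positive: specificity 0.5.

The full challenge re-enactment simulates the 25-system suite, evaluates
every system, and ranks them by all seven measures:

```bash
dermeval --out-dir rep report
```

```
Top system per measure
======================
average_precision: SYS_A_global (value 0.9112)
auc_roc: SYS_B_highsens (value 0.9687)
spec_at_se95: SYS_B_highsens (value 0.8849)
spec_at_se98: SYS_B_highsens (value 0.8618)
spec_at_se99: SYS_B_highsens (value 0.8553)
pauc_se95_100_raw: SYS_B_highsens (value 0.0433)
pauc_se95_100_norm: SYS_B_highsens (value 0.8664)
```

`SYS_A_global` tops the average-precision ranking (rank 1 of 25) but falls
to rank 23 under specificity at 98% sensitivity: most of its melanomas score
very high, but a small low-scoring melanoma fraction forces the operating
threshold down once 74 of 75 melanomas must be caught. `SYS_B_highsens`
shows the converse pattern. The bundle in `rep/` contains the simulated
submissions, per-system panels (`panels.csv`), the rank table, an
instability report (`instability.json`), ROC/PR curve points per system, and
a `manifest.json`; rerunning with the same seed reproduces it byte for byte.

Other subcommands: `simulate` (presets `challenge-cohort`,
`rank-reversal-suite`, `gaussian-features`), `sweep` (fit LDA/QDA/dLDA/dQDA,
threshold- or prior-mode operating curves, optional `--cv k`), `rank`
(leaderboard from several submission files), and `evaluate --bootstrap B`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch: the full simulate → evaluate →
rank pipeline on the challenge-scale suite, a pooled 5-fold cross-validated
panel on 1-D binormal features (population AUC Φ(1/√2) ≈ 0.76), and a
stratified bootstrap interval, then writes the results JSON to `--out`.

See `docs/methods.md` for the statistical conventions (tie handling,
operating-point rules, covariance estimators, saturation) and the design
rationale behind the synthetic-data generators.
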