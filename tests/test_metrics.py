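"""Measure correctness against hand enumerations and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermeval.cohort import ScoredCohort
from dermeval.metrics import (
    auc_roc,
    average_precision,
    confusion_at_threshold,
    measure_panel,
    partial_auc_roc,
    roc_curve,
    specificity_at_sensitivity,
)
from tests.conftest import ap_rank_cut_oracle, auc_pairwise_oracle, random_cohort


class TestConfusion:
    @pytest.mark.parametrize(
        "scores,labels,t,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5, (2, 0, 2, 0)),
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.0, (2, 2, 0, 0)),
            ([0.9, 0.7, 0.6, 0.3], [1, 0, 1, 0], 0.65, (1, 1, 1, 1)),
        ],
    )
    def test_counts_by_hand(self, scores, labels, t, expected):
        c = confusion_at_threshold(ScoredCohort(scores, labels), t)
        assert (c.tp, c.fp, c.tn, c.fn) == expected

    def test_counts_partition_cohort(self, five_record_cohort):
        c = confusion_at_threshold(five_record_cohort, 0.5)
        assert c.tp + c.fp + c.tn + c.fn == len(five_record_cohort)

    def test_threshold_at_min_score_gives_full_sensitivity(self, five_record_cohort):
        c = confusion_at_threshold(five_record_cohort, five_record_cohort.scores.min())
        assert c.sensitivity == 1.0


class TestRocCurve:
    def test_hand_enumerated_points(self, four_record_cohort):
        curve = roc_curve(four_record_cohort)
        assert curve.points() == [(0, 0), (0, 0.5), (0.5, 0.5), (0.5, 1), (1, 1)]

    def test_perfect_separation_passes_through_0_1(self, perfect_cohort):
        assert (0.0, 1.0) in roc_curve(perfect_cohort).points()

    def test_total_tie_gives_chance_diagonal(self):
        c = ScoredCohort([0.5] * 6, [1, 1, 0, 0, 0, 1])
        curve = roc_curve(c)
        assert curve.points() == [(0.0, 0.0), (1.0, 1.0)]
        assert auc_roc(curve) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(ScoredCohort([0.1, 0.2], [1, 1]))


class TestAuc:
    def test_hand_enumerated_value(self, four_record_cohort):
        assert auc_roc(four_record_cohort) == 0.75

    def test_perfect_is_one(self, perfect_cohort):
        assert auc_roc(perfect_cohort) == 1.0

    def test_label_swap_duality(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            c = random_cohort(rng, 60)
            swapped = ScoredCohort(c.scores, 1 - c.labels)
            assert auc_roc(swapped) == pytest.approx(1.0 - auc_roc(c), abs=1e-12)


class TestAveragePrecision:
    def test_all_melanomas_on_top(self, perfect_cohort):
        assert average_precision(perfect_cohort) == 1.0

    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_single_melanoma_ranked_last(self, n):
        scores = np.linspace(0.9, 0.1, n)
        labels = [0] * (n - 1) + [1]
        assert average_precision(ScoredCohort(scores, labels)) == pytest.approx(1 / n)

    def test_mbmb_hand_value(self):
        c = ScoredCohort([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert average_precision(c) == pytest.approx((1 + 2 / 3) / 2)


class TestSpecificityAtSensitivity:
    def test_hand_enumerated_five_records(self, five_record_cohort):
        res = specificity_at_sensitivity(five_record_cohort, 0.95)
        assert res.specificity == 0.5
        assert res.sensitivity == 1.0

    def test_perfect_cohort_any_target(self, perfect_cohort):
        for t in (0.5, 0.95, 0.98, 0.99, 1.0):
            assert specificity_at_sensitivity(perfect_cohort, t).specificity == 1.0

    def test_target_one_forces_lowest_melanoma_threshold(self, five_record_cohort):
        res = specificity_at_sensitivity(five_record_cohort, 1.0)
        assert res.threshold == 0.4
        assert res.specificity == 0.5

    def test_monotone_non_increasing_in_target(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            c = random_cohort(rng, 80)
            targets = np.sort(rng.uniform(0.05, 1.0, size=4))
            specs = [specificity_at_sensitivity(c, t).specificity for t in targets]
            assert all(a >= b - 1e-12 for a, b in zip(specs, specs[1:]))

    def test_interpolated_variant_between_neighbours(self, five_record_cohort):
        emp = specificity_at_sensitivity(five_record_cohort, 0.9).specificity
        lin = specificity_at_sensitivity(five_record_cohort, 0.9, "linear").specificity
        # interpolation at SE=0.9 sits between the SE=2/3 and SE=1 points
        assert emp <= lin <= 1.0


class TestPartialAuc:
    def test_perfect_classifier(self, perfect_cohort):
        raw, norm = partial_auc_roc(roc_curve(perfect_cohort), 0.95)
        assert raw == pytest.approx(0.05)
        assert norm == pytest.approx(1.0)

    def test_normalised_is_one_for_perfect_at_any_band(self, perfect_cohort):
        curve = roc_curve(perfect_cohort)
        for lo in (0.1, 0.5, 0.9, 0.99):
            assert partial_auc_roc(curve, lo)[1] == pytest.approx(1.0)

    def test_worst_classifier_zero(self):
        c = ScoredCohort([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        raw, norm = partial_auc_roc(roc_curve(c), 0.95)
        assert raw == 0.0 and norm == 0.0

    def test_four_record_band_half(self, four_record_cohort):
        raw, norm = partial_auc_roc(roc_curve(four_record_cohort), 0.5)
        assert raw == pytest.approx(0.25)
        assert norm == pytest.approx(0.5)


class TestMeasurePanel:
    def test_perfect_panel(self, perfect_cohort):
        panel = measure_panel(perfect_cohort)
        assert panel.average_precision == panel.auc_roc == 1.0
        assert panel.spec_at_se95 == panel.spec_at_se98 == panel.spec_at_se99 == 1.0
        assert panel.pauc_se95_100_raw == pytest.approx(0.05)

    def test_anti_perfect_panel(self):
        c = ScoredCohort([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        panel = measure_panel(c)
        assert panel.auc_roc == 0.0
        assert panel.spec_at_se95 == panel.spec_at_se99 == 0.0

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(777)
        c = ScoredCohort(rng.random(2000), rng.integers(0, 2, 2000))
        assert measure_panel(c).auc_roc == pytest.approx(0.5, abs=0.05)


class TestOracleProperties:
    """Exact agreement with independent brute-force oracles."""

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(60):
            c = random_cohort(rng, 120)
            assert auc_roc(c) == pytest.approx(
                auc_pairwise_oracle(c.scores.tolist(), c.labels.tolist()), abs=1e-12
            )

    def test_ap_matches_rank_cut_oracle(self):
        rng = np.random.default_rng(202)
        for _ in range(60):
            c = random_cohort(rng, 120)
            assert average_precision(c) == pytest.approx(
                ap_rank_cut_oracle(c.scores.tolist(), c.labels.tolist()), abs=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=40).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        ),
        data=st.data(),
    )
    def test_monotone_transform_invariance(self, labels, data):
        """A strictly increasing score map leaves the whole panel unchanged."""
        n = len(labels)
        grid = data.draw(st.integers(2, 8))
        scores = np.array(
            data.draw(st.lists(st.integers(0, grid), min_size=n, max_size=n))
        ) / grid
        c1 = ScoredCohort(scores, labels)
        c2 = ScoredCohort((np.tanh(3 * scores - 1) + 1) / 2, labels)  # strictly increasing
        p1, p2 = measure_panel(c1).as_dict(), measure_panel(c2).as_dict()
        for m in p1:
            assert p1[m] == pytest.approx(p2[m], abs=1e-9)
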