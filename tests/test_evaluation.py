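"""Evaluation statistics: AUC oracle, DeLong, kappa, ordinal scales, McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepanode.evaluation import (
    cnn_probability_to_ordinal,
    cohen_kappa_unweighted,
    compare_paired_auc,
    diagnostic_metrics,
    interpret_kappa,
    low_confidence_fraction,
    mcnemar_low_confidence,
    radiologist_to_ordinal,
    roc_auc,
)


def pair_counting_auc(scores, labels):
    """O(n^2) oracle: fraction of positive-negative pairs ranked correctly,
    ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_equals_oracle_property(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 50))
        labels = np.r_[0, 1, r.integers(0, 2, n - 2)]
        scores = r.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
        assert abs(roc_auc(scores, labels).auc - pair_counting_auc(scores, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestComparePairedAuc:
    def test_self_comparison_is_null(self, rng):
        scores = rng.random(40)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        diff, p = compare_paired_auc(scores, scores, labels)
        assert diff == 0.0 and p == 1.0

    def test_type_one_error_near_nominal(self):
        """Two noisy copies of one latent score: rejection rate ~ alpha."""
        r = np.random.default_rng(2024)
        rejections = 0
        reps = 500
        for _ in range(reps):
            n = 138
            y = np.r_[np.zeros(83, int), np.ones(55, int)]
            latent = y * 1.2 + r.normal(size=n)
            a = latent + r.normal(scale=0.8, size=n)
            b = latent + r.normal(scale=0.8, size=n)
            _, p = compare_paired_auc(a, b, y)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_power_against_random_scores(self):
        r = np.random.default_rng(7)
        y = np.r_[np.zeros(83, int), np.ones(55, int)]
        detected = 0
        for _ in range(40):
            perfect = y + r.normal(scale=0.05, size=y.size)
            noise = r.normal(size=y.size)
            _, p = compare_paired_auc(perfect, noise, y)
            detected += p < 0.01
        assert detected >= 38  # >= 95%

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_auc([0.1, 0.2], [0.3], [0, 1])


class TestDiagnosticMetrics:
    def test_perfect_classifier(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        perf = diagnostic_metrics(y.astype(float), y)
        assert perf.sensitivity == perf.specificity == perf.accuracy == 100.0

    def test_hand_computed_confusion_matrix(self):
        """TP=44 FN=10 TN=64 FP=20 -> sens 81.5, spec 76.2, acc 78.3."""
        y = np.r_[np.ones(54, int), np.zeros(84, int)]
        calls = np.r_[np.ones(44), np.zeros(10), np.zeros(64), np.ones(20)]
        perf = diagnostic_metrics(calls, y)
        assert round(perf.sensitivity, 1) == 81.5
        assert round(perf.specificity, 1) == 76.2
        assert round(perf.accuracy, 1) == 78.3
        lo, hi = perf.sensitivity_ci
        assert 0 <= lo < perf.sensitivity < hi <= 100

    def test_inverted_calls_swap_sens_spec_complements(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        calls = rng.integers(0, 2, 60).astype(float)
        perf = diagnostic_metrics(calls, y)
        inv = diagnostic_metrics(1 - calls, y)
        assert inv.sensitivity == pytest.approx(100 - perf.sensitivity)
        assert inv.specificity == pytest.approx(100 - perf.specificity)

    def test_accuracy_is_prevalence_weighted_combination(self, rng):
        for _ in range(20):
            y = np.r_[0, 1, rng.integers(0, 2, 40)]
            calls = rng.random(42)
            perf = diagnostic_metrics(calls, y)
            prev = y.mean()
            expected = prev * perf.sensitivity + (1 - prev) * perf.specificity
            assert perf.accuracy == pytest.approx(expected)

    def test_missing_class_flagged(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([0.6, 0.7], [1, 1])


class TestKappa:
    def test_identity_is_almost_perfect(self):
        calls = [0, 1, 0, 1, 1]
        result = cohen_kappa_unweighted(calls, calls)
        assert result.kappa == 1.0 and result.interpretation == "almost perfect"

    def test_hand_worked_contingency_table(self):
        """Table [[20,5],[10,15]]: p_o = 0.70, p_e = 0.50, kappa = 0.40."""
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        result = cohen_kappa_unweighted(a, b)
        assert result.kappa == pytest.approx(0.40)
        assert result.observed_agreement == pytest.approx(0.70)
        assert result.expected_agreement == pytest.approx(0.50)

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 2, 10000)
        b = rng.integers(0, 2, 10000)
        assert abs(cohen_kappa_unweighted(a, b).kappa) < 0.05

    def test_constant_equal_raters_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa_unweighted([1, 1, 1], [1, 1, 1])

    @pytest.mark.parametrize(
        "kappa,label",
        [(0.5, "moderate"), (0.7, "substantial"), (0.9, "almost perfect"),
         (0.3, "fair"), (0.1, "slight"), (-0.2, "poor")],
    )
    def test_interpretation_bands(self, kappa, label):
        assert interpret_kappa(kappa) == label


class TestOrdinalScales:
    def test_malignant_high_confidence_maps_to_ten(self):
        assert radiologist_to_ordinal("malignant", 5) == 10

    def test_benign_low_confidence_maps_to_five(self):
        assert radiologist_to_ordinal("benign", 1) == 5

    def test_bijection_onto_1_to_10(self):
        values = {
            radiologist_to_ordinal(call, c)
            for call in ("benign", "malignant")
            for c in range(1, 6)
        }
        assert values == set(range(1, 11))

    def test_probability_decile_bins(self):
        assert cnn_probability_to_ordinal(0.05) == 1
        assert cnn_probability_to_ordinal(0.10) == 1
        assert cnn_probability_to_ordinal(0.11) == 2
        assert cnn_probability_to_ordinal(1.0) == 10
        assert cnn_probability_to_ordinal(0.0) == 1

    def test_binning_monotone_on_grid(self):
        grid = np.arange(0, 1.0001, 0.001)
        ords = [cnn_probability_to_ordinal(p) for p in grid]
        assert all(a <= b for a, b in zip(ords, ords[1:]))
        assert set(ords) == set(range(1, 11))

    def test_scales_order_consistent(self):
        """Higher malignancy conviction never maps to a lower ordinal."""
        seq = [("benign", 5), ("benign", 4), ("benign", 3), ("benign", 2), ("benign", 1),
               ("malignant", 1), ("malignant", 2), ("malignant", 3), ("malignant", 4),
               ("malignant", 5)]
        ords = [radiologist_to_ordinal(c, k) for c, k in seq]
        assert ords == list(range(1, 11))

    @pytest.mark.parametrize("bad", [0, 6, 2.5])
    def test_bad_confidence_rejected(self, bad):
        with pytest.raises(ValueError):
            radiologist_to_ordinal("benign", bad)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cnn_probability_to_ordinal(1.2)


class TestLowConfidenceZone:
    def test_fully_confident_reader_has_empty_zone(self):
        dist = low_confidence_fraction([1] * 30)
        assert dist.zone_count == 0 and dist.zone_fraction == 0.0

    def test_published_style_fractions(self):
        """16/138 -> 11.6%, 27/138 -> 19.6% after rounding to one decimal."""
        ords = [5] * 16 + [1] * 122
        assert round(100 * low_confidence_fraction(ords).zone_fraction, 1) == 11.6
        ords = [6] * 27 + [10] * 111
        assert round(100 * low_confidence_fraction(ords).zone_fraction, 1) == 19.6

    def test_histogram_sums_to_n(self, rng):
        ords = rng.integers(1, 11, 200)
        dist = low_confidence_fraction(ords)
        assert sum(dist.histogram) == 200

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            low_confidence_fraction([])


class TestMcNemar:
    def test_identical_flags_give_p_one(self):
        flags = [0, 1, 0, 1, 1]
        assert mcnemar_low_confidence(flags, flags) == 1.0

    def test_extreme_discordance_exact_binomial(self):
        """2 vs 30 discordant pairs -> p < 1e-4 (chi-square branch, n=32)."""
        a = [1] * 30 + [0] * 2 + [0] * 50
        b = [0] * 30 + [1] * 2 + [0] * 50
        assert mcnemar_low_confidence(a, b) < 1e-4

    def test_small_discordance_uses_exact_binomial(self):
        from scipy.stats import binomtest

        a = [1] * 8 + [0] * 2 + [1] * 40
        b = [0] * 8 + [1] * 2 + [1] * 40
        expected = binomtest(8, 10, 0.5).pvalue
        assert mcnemar_low_confidence(a, b) == pytest.approx(expected)

    def test_type_one_error_near_nominal(self):
        r = np.random.default_rng(99)
        reps, rejections = 1000, 0
        for _ in range(reps):
            a = r.integers(0, 2, 200)
            flip = r.random(200) < 0.3  # symmetric disagreement
            b = np.where(flip, 1 - a, a)
            rejections += mcnemar_low_confidence(a, b) < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02
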