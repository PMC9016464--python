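"""Diagnostic-accuracy statistics: classification, metrics, ROC, inference."""

import numpy as np
import pytest

from fibroscreen.diagnostics import (ConfusionSummary, CutoffRule,
                                     PUBLISHED_CUTOFFS, auroc, classify_dual,
                                     classify_many, combined_dual_metrics,
                                     compare_paired_rates,
                                     compare_predictive_values,
                                     compare_unpaired_rates, confusion, delong,
                                     delong_ci, dual_cutoff_performance,
                                     metrics, obuchowski, percent,
                                     predictive_values_at_prevalence,
                                     roc_curve)
from fibroscreen.errors import (DegenerateDataError, DomainError,
                                ValidationError)

from _oracles import (auroc_pair_count, bootstrap_pv_difference_p,
                      delong_permutation_p, mcnemar_binomial_two_sided,
                      obuchowski_exhaustive)


class TestClassifyDual:
    FIB4 = PUBLISHED_CUTOFFS["FIB4"]

    @pytest.mark.parametrize("value,expect", [
        (1.0, "low"), (2.0, "indeterminate"), (3.0, "high"),
        (1.3, "indeterminate"), (2.67, "indeterminate"),  # boundary: gray zone closed
    ])
    def test_dual_cutoff_bands(self, value, expect):
        assert classify_dual(value, self.FIB4, age=50) == expect

    def test_age_adjusted_lower_replaces_lower(self):
        assert classify_dual(1.5, self.FIB4, age=70) == "low"
        assert classify_dual(1.5, self.FIB4, age=64) == "indeterminate"
        assert classify_dual(2.0, self.FIB4, age=65) == "indeterminate"

    def test_single_cutoff_is_inclusive(self):
        rule = CutoffRule("NFS_single", lower=-1.309)
        assert classify_dual(-1.309, rule) == "high"
        assert classify_dual(-1.310, rule) == "low"

    def test_monotone_in_score(self, rng):
        order = {"low": 0, "indeterminate": 1, "high": 2}
        for _ in range(200):
            a, b = sorted(rng.normal(1.8, 1.2, 2))
            assert order[classify_dual(a, self.FIB4, 50)] <= \
                order[classify_dual(b, self.FIB4, 50)]

    def test_rule_invariants(self):
        with pytest.raises(ValidationError):
            CutoffRule("x")
        with pytest.raises(ValidationError):
            CutoffRule("x", lower=2.0, upper=1.0)


class TestConfusion:
    def test_all_high_all_positive(self):
        cs = confusion(["high"] * 7, [True] * 7)
        assert cs.tp == 7 and cs.total == 7

    def test_printed_strata_counts_reproduce_tally(self):
        # three strata of a rule-out screen: 303 below (286 neg / 17 pos),
        # 236 between (175/61), 61 above (24/37); positive = at/above lower
        cls = (["low"] * 303 + ["high"] * 236 + ["high"] * 61)
        labels = ([False] * 286 + [True] * 17 + [False] * 175 + [True] * 61
                  + [False] * 24 + [True] * 37)
        cs = confusion(cls, labels)
        assert (cs.tp, cs.fn, cs.tn, cs.fp) == (98, 17, 286, 199)

    def test_random_vectors_match_exhaustive_tally(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            cls = rng.choice(["low", "indeterminate", "high"], n)
            y = rng.random(n) < 0.4
            cs = confusion(list(cls), list(y))
            assert cs.tp == sum((c == "high") and t for c, t in zip(cls, y))
            assert cs.indeterminate_neg == sum(
                (c == "indeterminate") and not t for c, t in zip(cls, y))
            assert cs.total == n

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion(["high"], [True, False])


class TestMetrics:
    def test_rule_out_screen_from_printed_counts(self):
        m = metrics(ConfusionSummary(tp=98, fn=17, tn=286, fp=199))
        assert percent(m.se) == 85
        assert percent(m.sp) == 59
        assert percent(m.ppv) == 33
        assert percent(m.npv) == 94

    def test_perfect_classifier(self):
        m = metrics(ConfusionSummary(tp=10, tn=10))
        assert m.se == m.sp == m.ppv == m.npv == 1.0
        assert m.nnd == pytest.approx(1.0)

    def test_nnd_from_integer_percent_convention(self):
        # Se 79% / Sp 87% -> Youden 0.66 -> NND 1.5 at one decimal
        cs = ConfusionSummary(tp=79, fn=21, tn=87, fp=13)
        m = metrics(cs, lr_rounding="integer_percent")
        assert round(m.nnd, 1) == 1.5
        assert round(m.lr_pos, 2) == 6.08
        assert round(m.lr_neg, 2) == 0.24

    def test_undefined_metrics_are_none(self):
        m = metrics(ConfusionSummary(tp=0, fn=0, tn=5, fp=5))
        assert m.se is None and m.npv is not None
        m = metrics(ConfusionSummary(tp=2, fn=8, tn=2, fp=8))  # Youden < 0
        assert m.nnd is None

    def test_clopper_pearson_interval_bounds(self):
        m = metrics(ConfusionSummary(tp=8, fn=2, tn=90, fp=10))
        lo, hi = m.se_ci
        assert 0 <= lo < m.se < hi <= 1
        # exact interval for 8/10 at 95%: (0.444, 0.975)
        assert lo == pytest.approx(0.4439, abs=5e-4)
        assert hi == pytest.approx(0.9748, abs=5e-4)

    def test_conservation_with_indeterminates(self, rng):
        for _ in range(20):
            cls = list(rng.choice(["low", "indeterminate", "high"], 40))
            y = list(rng.random(40) < 0.5)
            assert confusion(cls, y).total == 40


class TestDualCutoffPerformance:
    def test_perfect_separation_with_straddling_cutoffs(self):
        scores = [0, 0.1, 0.2, 0.8, 0.9, 1.0]
        labels = [False, False, False, True, True, True]
        rule = CutoffRule("s", lower=0.4, upper=0.6)
        perf = dual_cutoff_performance(scores, labels, None, rule)
        assert perf.lower.se == perf.lower.sp == 1.0
        assert perf.upper.se == perf.upper.sp == 1.0
        assert perf.indeterminate_fraction == 0.0

    def test_hand_traced_panel(self):
        # 20 subjects, rule (1.0, 2.0): 8 below, 7 between, 5 above
        scores = [0.2, 0.5, 0.7, 0.9, 0.95, 0.3, 0.6, 0.99,
                  1.0, 1.2, 1.5, 1.8, 2.0, 1.1, 1.9,
                  2.1, 2.5, 3.0, 2.2, 4.0]
        labels = [False] * 8 + [False, False, True, True, True, False, True] + \
                 [True, True, True, False, True]
        rule = CutoffRule("s", lower=1.0, upper=2.0)
        perf = dual_cutoff_performance(scores, labels, None, rule)
        # 8 positives, 12 negatives in total
        # lower screen: >=1.0 positive -> tp=8, fn=0, fp=4, tn=8
        assert perf.lower.se == pytest.approx(1.0)
        assert perf.lower.sp == pytest.approx(8 / 12)
        # upper screen: >2.0 positive -> tp=4, fn=4, fp=1, tn=11
        assert perf.upper.se == pytest.approx(4 / 8)
        assert perf.upper.sp == pytest.approx(11 / 12)
        assert perf.indeterminate_fraction == pytest.approx(7 / 20)

    def test_classified_fractions_conserve(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.3
        labels[:2] = [True, False]
        rule = CutoffRule("s", lower=-0.5, upper=0.5)
        cls = classify_many(list(scores), rule)
        frac = {c: cls.count(c) / 100 for c in ("low", "indeterminate", "high")}
        assert sum(frac.values()) == pytest.approx(1.0)
        perf = dual_cutoff_performance(scores, labels, None, rule)
        assert perf.indeterminate_fraction == pytest.approx(frac["indeterminate"])


class TestCombinedDualMetrics:
    RULE = CutoffRule("s", lower=-0.5, upper=0.5)

    def test_all_indeterminate_is_perfect_under_convention(self):
        m = combined_dual_metrics([0, 0, 0, 0], [True, True, False, False],
                                  None, self.RULE)
        assert m.se == 1.0 and m.sp == 1.0
        assert m.indeterminate_fraction == 1.0

    def test_no_indeterminates_reduces_to_binary(self):
        scores = [-2, -1, 1, 2]
        labels = [False, False, True, True]
        m = combined_dual_metrics(scores, labels, None, self.RULE)
        single = metrics(confusion(
            ["high" if s >= -0.5 else "low" for s in scores], labels))
        assert (m.se, m.sp, m.ppv, m.npv) == (single.se, single.sp, single.ppv, single.npv)

    def test_matches_brute_force_convention(self, rng):
        for _ in range(20):
            scores = rng.normal(size=50)
            labels = rng.random(50) < 0.4
            labels[:2] = [True, False]
            m = combined_dual_metrics(scores, labels, None, self.RULE)
            tp = fp = tn = fn = 0
            for s, t in zip(scores, labels):
                if -0.5 <= s <= 0.5:
                    tp, tn = tp + (1 if t else 0), tn + (0 if t else 1)
                elif s > 0.5:
                    tp, fp = tp + (1 if t else 0), fp + (0 if t else 1)
                else:
                    fn, tn = fn + (1 if t else 0), tn + (0 if t else 1)
            assert m.se == pytest.approx(tp / (tp + fn))
            assert m.sp == pytest.approx(tn / (tn + fp))


class TestRoc:
    def test_perfect_and_constant_scores(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 200))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.4
            labels[:2] = [True, False]
            assert auroc(scores, labels) == pytest.approx(
                auroc_pair_count(scores, labels), abs=1e-12)

    def test_curve_monotone_and_ci_brackets(self, rng):
        scores = rng.normal(size=120) + rng.random(120)
        labels = rng.random(120) < 0.35
        labels[:2] = [True, False]
        rc = roc_curve(scores, labels)
        assert np.all(np.diff(rc.se) >= -1e-12)      # se rises as threshold falls
        assert np.all(np.diff(rc.sp) <= 1e-12)
        assert 0 <= rc.auroc_ci[0] <= rc.auroc <= rc.auroc_ci[1] <= 1

    def test_single_class_is_error(self):
        with pytest.raises(DegenerateDataError):
            auroc([1, 2, 3], [True, True, True])


class TestDeLong:
    def test_self_comparison(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        labels[:2] = [True, False]
        res = delong(scores, scores, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=80)
        b = a + rng.normal(scale=0.7, size=80)
        labels = (a + b + rng.normal(scale=1.0, size=80)) > 0.5
        labels[:2] = [True, False]
        r1 = delong(a, b, labels)
        r2 = delong(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_against_permutation_oracle(self, rng):
        n = 40
        latent = rng.normal(size=n)
        labels = latent > 0.3
        labels[:2] = [True, False]
        a = latent + rng.normal(scale=1.0, size=n)
        b = latent + rng.normal(scale=1.6, size=n)
        res = delong(a, b, labels)
        p_perm = delong_permutation_p(a, b, labels, n_perm=4000, seed=9)
        # Monte-Carlo and asymptotic agreement: generous but informative band
        assert res.p == pytest.approx(p_perm, abs=0.08)

    def test_duplicating_data_halves_variance(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        _, ci1 = delong_ci(scores, labels)
        s2 = np.concatenate([scores, scores])
        y2 = np.concatenate([labels, labels])
        _, ci2 = delong_ci(s2, y2)
        w1 = ci1[1] - ci1[0]
        w2 = ci2[1] - ci2[0]
        assert w2 == pytest.approx(w1 / np.sqrt(2), rel=0.05)


class TestObuchowski:
    def test_perfectly_concordant_scores(self):
        stages = [0, 1, 2, 3, 4, 0, 2, 4]
        scores = [0.0, 1.0, 2.0, 3.0, 4.0, 0.1, 2.1, 4.1]
        theta, _ = obuchowski(scores, stages)
        assert theta == 1.0

    def test_constant_score_is_half(self):
        theta, _ = obuchowski([7] * 10, [0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        assert theta == pytest.approx(0.5)

    def test_exhaustive_pair_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 50))
            stages = rng.integers(0, 5, n)
            if np.unique(stages).size < 2:
                continue
            scores = np.round(stages + rng.normal(scale=1.5, size=n), 1)
            theta, ci = obuchowski(scores, stages)
            assert theta == pytest.approx(
                obuchowski_exhaustive(scores, stages), abs=1e-12)
            assert ci[0] <= theta <= ci[1]

    def test_two_stage_unit_weight_reduces_to_auroc(self, rng):
        stages = np.array([0] * 12 + [1] * 8)
        scores = rng.normal(size=20) + stages
        theta, _ = obuchowski(scores, stages, penalty_per_stage=1.0)
        assert theta == pytest.approx(auroc_pair_count(scores, stages == 1), abs=1e-12)

    def test_single_stage_is_error(self):
        with pytest.raises(DegenerateDataError):
            obuchowski([1, 2, 3], [2, 2, 2])


class TestRateComparisons:
    def test_symmetric_discordance_p_is_one(self):
        a = [True] * 5 + [False] * 5 + [True] * 10
        b = [False] * 5 + [True] * 5 + [True] * 10
        assert compare_paired_rates(a, b) == pytest.approx(1.0)

    def test_exact_binomial_tail_oracle(self):
        # discordant counts (9, 1)
        a = [True] * 9 + [False] * 1 + [True] * 20
        b = [False] * 9 + [True] * 1 + [True] * 20
        p = compare_paired_rates(a, b)
        assert p == pytest.approx(mcnemar_binomial_two_sided(9, 1), abs=1e-12)

    def test_identical_classifications(self):
        a = [True, False, True, False]
        assert compare_paired_rates(a, a) == 1.0

    def test_unpaired_chi_squared(self):
        # 2x2 with a clear difference
        p = compare_unpaired_rates(40, 50, 10, 50)
        assert p < 1e-6
        assert compare_unpaired_rates(25, 50, 25, 50) == pytest.approx(1.0)


class TestPredictiveValueComparison:
    def test_identical_tests_p_one(self):
        t = np.array([True, True, False, False, True, False] * 5)
        d = np.array([True, False, False, True, True, False] * 5)
        res = compare_predictive_values(t, t, d)
        assert res.p_ppv == 1.0 and res.p_npv == 1.0

    def test_dominating_test_small_p_and_sign(self, rng):
        # test A calls exactly the diseased; B adds many false positives
        n = 400
        d = rng.random(n) < 0.3
        a = d.copy()
        b = d | (rng.random(n) < 0.5)
        res = compare_predictive_values(a, b, d)
        assert res.ppv_a > res.ppv_b
        assert res.p_ppv < 0.001

    def test_against_bootstrap_oracle(self, rng):
        n = 250
        d = rng.random(n) < 0.3
        a = d ^ (rng.random(n) < 0.15)
        b = d ^ (rng.random(n) < 0.25)
        res = compare_predictive_values(a, b, d)
        p_boot = bootstrap_pv_difference_p(a, b, d, which="ppv",
                                           n_boot=4000, seed=5)
        assert res.p_ppv == pytest.approx(p_boot, abs=0.1)

    def test_undefined_pv_is_error(self):
        with pytest.raises(DegenerateDataError):
            compare_predictive_values([False] * 4, [True, False, True, False],
                                      [True, False, True, False])


class TestPrevalenceProjection:
    def test_planning_identity(self):
        out = predictive_values_at_prevalence(0.85, 0.95, 0.15)
        assert out["ppv"] == pytest.approx(0.750, abs=5e-4)
        assert out["npv"] == pytest.approx(0.973, abs=5e-4)
        assert out["accuracy"] == pytest.approx(0.935, abs=5e-4)

    def test_zero_prevalence_limits(self):
        out = predictive_values_at_prevalence(0.8, 0.9, 0.0)
        assert out["ppv"] == 0.0 and out["npv"] == 1.0

    def test_perfect_test(self):
        out = predictive_values_at_prevalence(1.0, 1.0, 0.3)
        assert out["ppv"] == out["npv"] == out["accuracy"] == 1.0

    def test_out_of_range_input(self):
        with pytest.raises(DomainError):
            predictive_values_at_prevalence(1.2, 0.9, 0.1)
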