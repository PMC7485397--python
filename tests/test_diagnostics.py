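"""Diagnostic statistics vs printed-table arithmetic and brute-force oracles."""

import itertools
import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from swe_radiomics.diagnostics import (ConfusionCounts, bonferroni_adjust,
                                       cohort_summary, confusion_metrics,
                                       evaluate_classifier, interpret_lr_band,
                                       likelihood_ratios, mcnemar_test,
                                       report_table, roc_auc_delong,
                                       round_half_up_percent)
from swe_radiomics.exceptions import DegenerateLabelError, UndefinedStatisticError


class TestConfusionMetrics:
    def test_point_estimates_and_rendering(self):
        sens, spec = confusion_metrics(ConfusionCounts(tp=48, fn=10, tn=123, fp=17))
        assert sens.value == pytest.approx(48 / 58)
        assert round_half_up_percent(sens.value) == 83
        assert round_half_up_percent(spec.value) == 88

    def test_clopper_pearson_against_beta_oracle(self):
        sens, _ = confusion_metrics(ConfusionCounts(tp=48, fn=10, tn=1, fp=0))
        lo = stats.beta.ppf(0.025, 48, 11)
        hi = stats.beta.ppf(0.975, 49, 10)
        assert sens.ci_low == pytest.approx(lo, abs=1e-10)
        assert sens.ci_high == pytest.approx(hi, abs=1e-10)

    def test_perfect_sensitivity_ci_below_one(self):
        sens, _ = confusion_metrics(ConfusionCounts(tp=58, fn=0, tn=10, fp=0))
        assert sens.value == 1.0 and sens.ci_low < 1.0 and sens.ci_high == 1.0

    def test_zero_denominator_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))

    @pytest.mark.parametrize("num,den,pct", [
        (48, 58, 83), (123, 140, 88), (57, 58, 98), (44, 58, 76),
        (131, 140, 94), (16, 19, 84), (41, 46, 89), (7, 10, 70),
        (76, 140, 54), (25, 46, 54), (7, 18, 39), (139, 140, 99),
    ])
    def test_percentages_reproduce_from_counts(self, num, den, pct):
        assert round_half_up_percent(num / den) == pct


class TestLikelihoodRatios:
    def test_moderate_plr_with_ci(self):
        lrs = likelihood_ratios(ConfusionCounts(tp=48, fn=10, tn=123, fp=17))
        assert round(lrs.plr.value, 2) == 6.82
        assert round(lrs.plr.ci_low, 2) == 4.30
        assert round(lrs.plr.ci_high, 2) == 10.80
        assert round(lrs.nlr.value, 2) == 0.20

    def test_perfect_sensitivity_large_plr(self):
        lrs = likelihood_ratios(ConfusionCounts(tp=58, fn=0, tn=139, fp=1))
        assert lrs.plr.value == pytest.approx(140.0)
        assert round(lrs.plr.ci_low, 2) == 19.86
        assert round(lrs.plr.ci_high, 2) == 986.92
        assert lrs.nlr.value == 0.0 and lrs.nlr.ci_low is None

    def test_perfect_specificity_infinite_plr(self):
        lrs = likelihood_ratios(ConfusionCounts(tp=57, fn=1, tn=140, fp=0))
        assert math.isinf(lrs.plr.value)
        assert round(lrs.nlr.value, 2) == 0.02
        assert round(lrs.nlr.ci_low, 4) == 0.0025
        assert round(lrs.nlr.ci_high, 2) == 0.12

    def test_identity_with_rates_holds_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fn, tn, fp = rng.integers(1, 60, size=4)
            c = ConfusionCounts(int(tp), int(fn), int(tn), int(fp))
            sens, spec = confusion_metrics(c)
            lrs = likelihood_ratios(c)
            assert lrs.plr.value * (1 - spec.value) == pytest.approx(sens.value, abs=1e-12)
            assert lrs.nlr.value * spec.value == pytest.approx(1 - sens.value, abs=1e-12)

    def test_degenerate_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            likelihood_ratios(ConfusionCounts(tp=0, fn=10, tn=10, fp=0))


class TestLRBands:
    @pytest.mark.parametrize("lr,direction,band", [
        (11.8, "positive", "large"), (6.82, "positive", "moderate"),
        (5.0, "positive", "moderate"), (10.0, "positive", "moderate"),
        (2.07, "positive", "small"),
        (0.05, "negative", "large"), (0.1, "negative", "moderate"),
        (0.2, "negative", "moderate"), (0.34, "negative", "small"),
    ])
    def test_bands(self, lr, direction, band):
        assert interpret_lr_band(lr, direction) == band

    def test_negative_value_invalid(self):
        with pytest.raises(ValueError):
            interpret_lr_band(-0.1, "positive")


def auc_pair_counting(scores, labels):
    """Brute-force AUC: fraction of (diseased, healthy) pairs ordered correctly."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestDeLong:
    def test_perfect_and_tied(self):
        assert roc_auc_delong([1, 2, 8, 9], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc_delong([5, 5, 5, 5], [0, 0, 1, 1]).auc == 0.5

    def test_six_case_toy_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert roc_auc_delong(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            scores = rng.normal(size=n).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc_delong(scores, labels).auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)

    def test_ci_coverage_on_binormal_cohorts(self):
        """~95% of DeLong CIs should cover the true binormal AUC (n=60)."""
        mu = 1.0
        true_auc = stats.norm.cdf(mu / math.sqrt(2))
        rng = np.random.default_rng(7)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            neg = rng.normal(0, 1, 30)
            pos = rng.normal(mu, 1, 30)
            res = roc_auc_delong(np.concatenate([neg, pos]),
                                 np.repeat([0, 1], 30))
            covered += res.ci_low <= true_auc <= res.ci_high
        assert abs(covered / n_sim - 0.95) <= 0.03

    def test_paired_test_detects_difference(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 40)
        good = y * 2.0 + rng.normal(0, 0.5, 80)
        bad = rng.normal(0, 1, 80)
        res = roc_auc_delong(good, y, bad)
        assert res.auc > res.auc_b
        assert res.p_value < 0.01

    def test_identical_scores_give_p_one(self):
        y = np.repeat([0, 1], 10)
        s = np.arange(20.0)
        assert roc_auc_delong(s, y, s).p_value == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            roc_auc_delong([1, 2, 3], [1, 1, 1])


def test_delong_matches_r_proc():
    """Independent oracle: CI and paired p from R's pROC on a fixed dataset."""
    pytest.importorskip("numpy")
    rng = np.random.default_rng(11)
    y = np.repeat([0, 1], 20)
    a = y * 1.2 + rng.normal(0, 1, 40)
    b = y * 0.4 + rng.normal(0, 1, 40)
    script = f"""
suppressMessages(library(pROC))
y <- c({",".join(map(str, y))})
a <- c({",".join(f"{v:.10f}" for v in a)})
b <- c({",".join(f"{v:.10f}" for v in b)})
ra <- roc(y, a, quiet=TRUE, direction="<")
ci <- ci.auc(ra, method="delong")
tt <- roc.test(ra, roc(y, b, quiet=TRUE, direction="<"), method="delong", paired=TRUE)
cat(sprintf("%.10f %.10f %.10f %.10f\\n", ci[1], ci[2], ci[3], tt$p.value))
"""
    try:
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
    except FileNotFoundError:
        pytest.skip("Rscript not available")
    assert out.returncode == 0, out.stderr
    lo, auc_r, hi, p_r = map(float, out.stdout.split())
    res = roc_auc_delong(a, y, b)
    assert res.auc == pytest.approx(auc_r, abs=1e-9)
    assert res.ci_low == pytest.approx(lo, abs=1e-6)
    assert res.ci_high == pytest.approx(hi, abs=1e-6)
    assert res.p_value == pytest.approx(p_r, abs=1e-6)


def mcnemar_exact_oracle(b, c):
    """Two-sided exact binomial tail for the discordant counts."""
    n = b + c
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2 ** n
    return min(1.0, 2 * tail)


class TestMcNemar:
    @staticmethod
    def vectors(b, c, both_right=5, both_wrong=2):
        a = [True] * both_right + [False] * both_wrong + [True] * b + [False] * c
        bb = [True] * both_right + [False] * both_wrong + [False] * b + [True] * c
        return a, bb

    def test_symmetric_discordance(self):
        p, b, c = mcnemar_test(*self.vectors(1, 1))
        assert (b, c) == (1, 1) and p == pytest.approx(1.0)

    def test_no_discordance(self):
        p, b, c = mcnemar_test(*self.vectors(0, 0))
        assert p == 1.0 and b == 0 and c == 0

    def test_exact_binomial_oracle(self):
        p, b, c = mcnemar_test(*self.vectors(10, 2))
        assert (b, c) == (10, 2)
        assert p == pytest.approx(mcnemar_exact_oracle(10, 2), abs=1e-12)

    def test_symmetry_in_b_c(self):
        assert mcnemar_test(*self.vectors(7, 2))[0] == pytest.approx(
            mcnemar_test(*self.vectors(2, 7))[0], abs=1e-12)

    def test_large_counts_use_corrected_chi_square(self):
        p, b, c = mcnemar_test(*self.vectors(20, 10))
        expected = stats.chi2.sf((abs(20 - 10) - 1) ** 2 / 30, 1)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 2, 30).astype(bool)
            b = rng.integers(0, 2, 30).astype(bool)
            p, *_ = mcnemar_test(a, b)
            assert 0.0 <= p <= 1.0


class TestBonferroni:
    def test_single_test_unchanged(self):
        res = bonferroni_adjust([0.03])
        assert res.adjusted_p == [0.03] and res.significant == [True]

    def test_four_tests(self):
        res = bonferroni_adjust([0.02, 0.5, 0.001, 0.4], alpha=0.05)
        assert res.adjusted_p[0] == pytest.approx(0.08)
        assert res.threshold == pytest.approx(0.0125)
        assert res.significant == [False, False, True, False]

    def test_cap_at_one(self):
        assert bonferroni_adjust([0.4, 0.2, 0.9]).adjusted_p[0] == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestCohortSummary:
    def test_identical_groups_p_one(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        vals = rng.normal(50, 5, 30)
        df = pd.DataFrame({
            "label": ["benign"] * 30 + ["malignant"] * 30,
            "age": np.concatenate([vals, vals]),
        })
        out = cohort_summary(df, continuous=["age"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "test"] == "t"

    def test_large_shift_detected(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "label": ["benign"] * 30 + ["malignant"] * 30,
            "size": np.concatenate([rng.normal(10, 1, 30), rng.normal(20, 1, 30)]),
        })
        out = cohort_summary(df, continuous=["size"])
        assert out.loc[0, "p_value"] < 0.001

    def test_independent_categorical_p_near_one(self):
        import pandas as pd

        df = pd.DataFrame({
            "label": (["benign"] * 20 + ["malignant"] * 20),
            "side": (["left"] * 10 + ["right"] * 10) * 2,
        })
        out = cohort_summary(df, categorical=["side"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)


class TestReportRendering:
    def test_infinite_plr_and_formats(self):
        rep = evaluate_classifier("SWE-RS", [0.1, 0.2, 0.9, 0.8, 0.3, 0.95],
                                  [0, 0, 1, 1, 0, 1], threshold=0.5)
        table = report_table([rep])
        row = table.iloc[0]
        assert row["positive_lr"] == "∞"
        assert row["sensitivity_pct"].endswith("[3/3]")
        assert row["auc"].startswith("1.00")
        assert row["plr_band"] == "large" and row["nlr_band"] == "large"
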