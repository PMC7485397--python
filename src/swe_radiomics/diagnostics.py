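"""Diagnostic-performance statistics for binary classifiers.

Everything needed for a per-cohort performance table: sensitivity and
specificity with exact Clopper-Pearson 95% CIs, positive/negative
likelihood ratios with Simel log-method CIs and Jaeschke interpretation
bands, AUC with DeLong variance (CI and paired two-sided test), the
McNemar test for paired sensitivities/specificities, Bonferroni
correction, and baseline-table group comparisons (Student's t or
Mann-Whitney U per normality, chi-square for categoricals).

Table rendering follows the clinical convention: percentages rounded half
up to integers with the raw counts in brackets, likelihood ratios to two
decimals (integers from 100 up), an infinite PLR shown as the infinity
sign, AUC to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DegenerateLabelError, UndefinedStatisticError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, predicted_positive, truth_positive) -> "ConfusionCounts":
        p = np.asarray(predicted_positive, dtype=bool)
        t = np.asarray(truth_positive, dtype=bool)
        if p.shape != t.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int((p & t).sum()), fn=int((~p & t).sum()),
            tn=int((~p & ~t).sum()), fp=int((p & ~t).sum()),
        )


@dataclass(frozen=True)
class Proportion:
    """Point estimate with exact 95% CI and the defining counts."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


def round_half_up_percent(fraction: float) -> int:
    """Percentage rounded half up (0.8276 -> 83)."""
    return int(math.floor(fraction * 100 + 0.5))


def confusion_metrics(counts: ConfusionCounts) -> tuple[Proportion, Proportion]:
    """(sensitivity, specificity) with exact Clopper-Pearson 95% CIs."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos < 1 or neg < 1:
        raise UndefinedStatisticError("both diseased and healthy cases are required")
    out = []
    for num, den in ((counts.tp, pos), (counts.tn, neg)):
        lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
        out.append(Proportion(num / den, float(lo), float(hi), num, den))
    return out[0], out[1]


@dataclass(frozen=True)
class LikelihoodRatio:
    value: float  # may be inf (PLR) or 0 (NLR)
    ci_low: float | None  # None when the point estimate is infinite/zero
    ci_high: float | None


@dataclass(frozen=True)
class LikelihoodRatios:
    plr: LikelihoodRatio
    nlr: LikelihoodRatio


def likelihood_ratios(counts: ConfusionCounts) -> LikelihoodRatios:
    """PLR = sens/(1-spec), NLR = (1-sens)/spec with Simel log-method CIs.

    A perfect specificity with non-zero sensitivity yields an infinite PLR;
    a perfect sensitivity yields NLR = 0.  CIs are omitted (None) at those
    boundary estimates.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    pos, neg = tp + fn, tn + fp
    if pos < 1 or neg < 1:
        raise UndefinedStatisticError("both diseased and healthy cases are required")
    sens, spec = tp / pos, tn / neg
    if sens == 0 and spec == 1:
        raise UndefinedStatisticError("PLR undefined at sensitivity 0, specificity 1")

    if spec == 1.0:
        plr = LikelihoodRatio(math.inf, None, None)
    elif tp == 0:
        plr = LikelihoodRatio(0.0, None, None)
    else:
        value = sens / (1 - spec)
        se = math.sqrt(1 / tp - 1 / pos + 1 / fp - 1 / neg)
        plr = LikelihoodRatio(
            value,
            math.exp(math.log(value) - 1.959963984540054 * se),
            math.exp(math.log(value) + 1.959963984540054 * se),
        )
    if sens == 1.0:
        nlr = LikelihoodRatio(0.0, None, None)
    elif spec == 0.0:
        nlr = LikelihoodRatio(math.inf, None, None)
    else:
        value = (1 - sens) / spec
        se = math.sqrt(1 / fn - 1 / pos + 1 / tn - 1 / neg)
        nlr = LikelihoodRatio(
            value,
            math.exp(math.log(value) - 1.959963984540054 * se),
            math.exp(math.log(value) + 1.959963984540054 * se),
        )
    return LikelihoodRatios(plr=plr, nlr=nlr)


def interpret_lr_band(lr: float, direction: str) -> str:
    """Jaeschke interpretation band of a likelihood ratio.

    Positive LRs: >10 large, 5-10 moderate, otherwise small.
    Negative LRs: <0.1 large, 0.1-0.2 moderate, otherwise small.
    """
    if lr < 0:
        raise ValueError("likelihood ratios are non-negative")
    if direction == "positive":
        if lr > 10:
            return "large"
        return "moderate" if lr >= 5 else "small"
    if direction == "negative":
        if lr < 0.1:
            return "large"
        return "moderate" if lr <= 0.2 else "small"
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# DeLong AUC machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of a 1-D array (ties share the average rank)."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=np.float64)
    out[order] = mid
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the DeLong structural components V10 (diseased) / V01 (healthy)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    auc_b: float | None = None
    delta: float | None = None
    z: float | None = None
    p_value: float | None = None


def roc_auc_delong(scores_a, labels, scores_b=None) -> DeLongResult:
    """AUC (Mann-Whitney, ties at 1/2) with DeLong 95% CI; paired test if ``scores_b``.

    ``labels`` is boolean/0-1 with True = diseased; higher scores must
    indicate disease (orient before calling).  With two score vectors on
    the same cases the two-sided paired z-test for the AUC difference is
    reported.
    """
    y = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=np.float64)
    if y.all() or not y.any():
        raise DegenerateLabelError("both classes required for ROC analysis")
    m, n = int(y.sum()), int((~y).sum())
    auc_a, v10_a, v01_a = _delong_components(a, y)
    var_a = (np.var(v10_a, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01_a, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * math.sqrt(max(var_a, 0.0))
    ci = (max(0.0, auc_a - half), min(1.0, auc_a + half))
    if scores_b is None:
        return DeLongResult(float(auc_a), ci[0], ci[1], float(var_a))
    b = np.asarray(scores_b, dtype=np.float64)
    if b.shape != a.shape:
        raise ValueError("paired score vectors must share the case set")
    auc_b, v10_b, v01_b = _delong_components(b, y)
    var_b = (np.var(v10_b, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01_b, ddof=1) / n if n > 1 else 0.0
    )
    cov = 0.0
    if m > 1:
        cov += np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    var_delta = var_a + var_b - 2 * cov
    delta = auc_a - auc_b
    if var_delta <= 0:
        z = math.inf if abs(delta) > 0 else 0.0
        p = 0.0 if abs(delta) > 0 else 1.0
    else:
        z = delta / math.sqrt(var_delta)
        p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(float(auc_a), ci[0], ci[1], float(var_a),
                        auc_b=float(auc_b), delta=float(delta),
                        z=float(z), p_value=float(p))


def mcnemar_test(correct_a, correct_b) -> tuple[float, int, int]:
    """Two-sided McNemar test on paired per-case correctness vectors.

    Returns (p, b, c) with b = cases only classifier A got right and
    c = cases only classifier B got right.  Exact binomial when b + c < 25,
    otherwise chi-square with continuity correction.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_vec = np.asarray(correct_b, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("paired vectors must share length")
    b = int((a & ~b_vec).sum())
    c = int((~a & b_vec).sum())
    if b + c == 0:
        return 1.0, b, c
    table = [[int((a & b_vec).sum()), b], [c, int((~a & ~b_vec).sum())]]
    res = _sm_mcnemar(table, exact=(b + c < 25), correction=True)
    return float(min(res.pvalue, 1.0)), b, c


@dataclass(frozen=True)
class BonferroniResult:
    adjusted_p: list[float]
    threshold: float
    significant: list[bool]


def bonferroni_adjust(p_values: Sequence[float], alpha: float = 0.05) -> BonferroniResult:
    """Adjusted p = min(1, m*p); significance at the alpha/m threshold."""
    p = list(map(float, p_values))
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    return BonferroniResult(
        adjusted_p=[min(1.0, m * v) for v in p],
        threshold=alpha / m if m else alpha,
        significant=[v < alpha / m for v in p] if m else [],
    )


def cohort_summary(
    table: pd.DataFrame,
    label_col: str = "label",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline-table group comparison.

    Continuous variables: Shapiro normality per group at alpha 0.05 decides
    Student's t (both normal) vs Mann-Whitney U.  Categorical variables:
    chi-square on the contingency table.  Returns one row per variable with
    per-group mean +/- SD (or level counts), the test used, and p.
    """
    groups = table[label_col].unique()
    if len(groups) != 2:
        raise DegenerateLabelError("exactly two groups required")
    g1 = table[table[label_col] == groups[0]]
    g2 = table[table[label_col] == groups[1]]
    rows = []
    for var in continuous:
        x1 = g1[var].astype(float).to_numpy()
        x2 = g2[var].astype(float).to_numpy()
        if np.ptp(x1) == 0 and np.ptp(x2) == 0:
            p = 1.0 if x1.mean() == x2.mean() else 0.0
            test = "degenerate"
        else:
            normal = all(
                np.ptp(x) > 0 and len(x) >= 3 and stats.shapiro(x).pvalue > 0.05
                for x in (x1, x2)
            )
            if normal:
                p = float(stats.ttest_ind(x1, x2, equal_var=True).pvalue)
                test = "t"
            else:
                p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
                test = "mann-whitney"
        rows.append({
            "variable": var,
            f"{groups[0]}": f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
            f"{groups[1]}": f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}",
            "test": test, "p_value": p,
        })
    for var in categorical:
        ct = pd.crosstab(table[var], table[label_col])
        chi2 = stats.chi2_contingency(ct.to_numpy())
        rows.append({
            "variable": var,
            f"{groups[0]}": "; ".join(f"{ix}:{v}" for ix, v in ct[groups[0]].items()),
            f"{groups[1]}": "; ".join(f"{ix}:{v}" for ix, v in ct[groups[1]].items()),
            "test": "chi-square", "p_value": float(chi2.pvalue),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class DiagnosticReport:
    """One performance-table row: a classifier evaluated on one cohort."""

    name: str
    threshold: float | str
    sensitivity: Proportion
    specificity: Proportion
    auc: DeLongResult
    lrs: LikelihoodRatios | None  # None when undefined (sens 0 at spec 1)
    counts: ConfusionCounts

    @property
    def plr_band(self) -> str:
        if self.lrs is None:
            return "n/a"
        return interpret_lr_band(self.lrs.plr.value, "positive")

    @property
    def nlr_band(self) -> str:
        if self.lrs is None:
            return "n/a"
        return interpret_lr_band(self.lrs.nlr.value, "negative")


def evaluate_classifier(
    name: str,
    scores,
    labels,
    threshold: float,
    positive_higher: bool = True,
) -> DiagnosticReport:
    """Apply a fixed threshold and assemble the full per-cohort report row."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    called = scores > threshold if positive_higher else scores < threshold
    counts = ConfusionCounts.from_predictions(called, y)
    sens, spec = confusion_metrics(counts)
    oriented = scores if positive_higher else -scores
    auc = roc_auc_delong(oriented, y)
    try:
        lrs = likelihood_ratios(counts)
    except UndefinedStatisticError:
        lrs = None
    return DiagnosticReport(
        name=name,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        lrs=lrs,
        counts=counts,
    )


def _fmt_lr(lr: LikelihoodRatio) -> str:
    if math.isinf(lr.value):
        return "∞"
    text = f"{lr.value:.0f}" if lr.value >= 100 else f"{lr.value:.2f}"
    if lr.ci_low is None:
        return text
    lo = f"{lr.ci_low:.0f}" if lr.ci_low >= 100 else f"{lr.ci_low:.2f}"
    hi = f"{lr.ci_high:.0f}" if lr.ci_high >= 100 else f"{lr.ci_high:.2f}"
    return f"{text} ({lo}-{hi})"


def _fmt_prop(p: Proportion) -> str:
    return (
        f"{round_half_up_percent(p.value)} "
        f"({round_half_up_percent(p.ci_low)}-{round_half_up_percent(p.ci_high)}) "
        f"[{p.numerator}/{p.denominator}]"
    )


def report_table(reports: Sequence[DiagnosticReport]) -> pd.DataFrame:
    """Render report rows in the standard table layout."""
    rows = []
    for r in reports:
        rows.append({
            "parameter": r.name,
            "threshold": r.threshold if isinstance(r.threshold, str)
            else f"{r.threshold:.2f}",
            "sensitivity_pct": _fmt_prop(r.sensitivity),
            "specificity_pct": _fmt_prop(r.specificity),
            "auc": f"{r.auc.auc:.2f} ({r.auc.ci_low:.2f}-{r.auc.ci_high:.2f})",
            "positive_lr": _fmt_lr(r.lrs.plr) if r.lrs else "n/a",
            "negative_lr": _fmt_lr(r.lrs.nlr) if r.lrs else "n/a",
            "plr_band": r.plr_band,
            "nlr_band": r.nlr_band,
        })
    return pd.DataFrame(rows)
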