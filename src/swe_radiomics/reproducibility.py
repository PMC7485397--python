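"""Intra-/inter-rater reproducibility screening of deep radiomic features.

The first of the three feature-selection steps: every feature is scored with
an intraclass correlation coefficient across repeated segmentations
(rater 1 twice for the intra-rater ICC; rater 1 vs rater 2 for the
inter-rater ICC) and retained only when both ICCs exceed a threshold
(0.6 by default, strictly greater).

The ICC form is the two-way random-effects, absolute-agreement,
single-measure ICC(2,1); the consistency form ICC(3,1) is available as an
option.  Both come from the standard two-way ANOVA decomposition and are
computed vectorized across features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import UndefinedStatisticError


@dataclass(frozen=True)
class ICCRecord:
    feature_index: int
    icc_intra: float
    icc_inter: float
    retained: bool


def _anova_mean_squares(x: np.ndarray):
    """MSR (rows/targets), MSC (columns/raters), MSE from a (n, k, ...) stack."""
    n, k = x.shape[0], x.shape[1]
    grand = x.mean(axis=(0, 1))
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((x - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, sst


def _icc_from_ms(msr, msc, mse, n: int, k: int, form: str):
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}; use 'icc2' or 'icc3'")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (msr - mse) / denom, np.nan)


def icc(ratings: np.ndarray, form: str = "icc2") -> float:
    """Single-measure ICC of a cases x raters matrix.

    ``form='icc2'`` (default) is the two-way random-effects absolute-agreement
    ICC(2,1); ``form='icc3'`` the two-way mixed consistency ICC(3,1).
    Estimates below zero are possible and returned as-is.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a (>=2 cases) x (>=2 raters) matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    msr, msc, mse, sst = _anova_mean_squares(x[:, :, None])
    if sst[0] == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    value = _icc_from_ms(msr, msc, mse, n, k, form)[0]
    if np.isnan(value):
        raise UndefinedStatisticError("degenerate ANOVA decomposition; ICC undefined")
    return float(value)


def icc_per_feature(x: np.ndarray, form: str = "icc2") -> np.ndarray:
    """Vectorized ICC over a (cases, raters, features) stack; NaN where undefined."""
    x = np.asarray(x, dtype=np.float64)
    n, k = x.shape[0], x.shape[1]
    msr, msc, mse, sst = _anova_mean_squares(x)
    vals = _icc_from_ms(msr, msc, mse, n, k, form)
    return np.where(sst > 0, vals, np.nan)


_ICC_BANDS = [
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
]


def classify_icc_band(v: float) -> str:
    """Agreement band of an ICC value (negative estimates read as weak/none)."""
    if v > 1:
        raise ValueError("ICC cannot exceed 1")
    for lo, name in _ICC_BANDS:
        if v >= lo:
            return name
    return "weak/none"


class ICCFeatureFilter(BaseEstimator, TransformerMixin):
    """Retain features whose intra- AND inter-rater ICC exceed ``threshold``.

    Parameters
    ----------
    threshold : float, default 0.6
        Retention requires strictly greater-than on both ICCs.
    form : {'icc2', 'icc3'}, default 'icc2'
        ANOVA form; absolute agreement by default since the question is
        measurement reproducibility across raters.

    Fitted attributes
    -----------------
    icc_intra_, icc_inter_ : per-feature ICC arrays (NaN where undefined)
    support_ : boolean retention mask
    selected_indices_ : retained feature indices, ascending
    records_ : list of :class:`ICCRecord`
    """

    def __init__(self, threshold: float = 0.6, form: str = "icc2"):
        self.threshold = threshold
        self.form = form

    def fit(self, X, y=None, *, X_retest=None, X_other_rater=None):
        X = np.asarray(X, dtype=np.float64)
        if X_retest is None or X_other_rater is None:
            raise ValueError("fit requires X_retest and X_other_rater matrices")
        X_retest = np.asarray(X_retest, dtype=np.float64)
        X_other_rater = np.asarray(X_other_rater, dtype=np.float64)
        if not (X.shape == X_retest.shape == X_other_rater.shape):
            raise ValueError("the three feature matrices must share one shape")
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a (>=2 cases) x features matrix")
        self.n_features_in_ = X.shape[1]
        self.icc_intra_ = icc_per_feature(np.stack([X, X_retest], axis=1), self.form)
        self.icc_inter_ = icc_per_feature(np.stack([X, X_other_rater], axis=1), self.form)
        with np.errstate(invalid="ignore"):
            self.support_ = (self.icc_intra_ > self.threshold) & (
                self.icc_inter_ > self.threshold
            )
        self.selected_indices_ = np.nonzero(self.support_)[0]
        self.records_ = [
            ICCRecord(int(i), float(self.icc_intra_[i]), float(self.icc_inter_[i]),
                      bool(self.support_[i]))
            for i in range(self.n_features_in_)
        ]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "records_")
        return pd.DataFrame([r.__dict__ for r in self.records_])


def filter_reproducible_features(
    features_r1s1: np.ndarray,
    features_r1s2: np.ndarray,
    features_r2: np.ndarray,
    threshold: float = 0.6,
    form: str = "icc2",
) -> list[ICCRecord]:
    """Functional wrapper over :class:`ICCFeatureFilter`; returns the records."""
    f = ICCFeatureFilter(threshold=threshold, form=form)
    f.fit(features_r1s1, X_retest=features_r1s2, X_other_rater=features_r2)
    return f.records_
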