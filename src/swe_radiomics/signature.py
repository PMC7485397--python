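"""Rad-score signatures: L1-penalized selection, scoring, Youden cutoff.

Steps two and three of the feature-selection procedure: the ICC-screened
deep features are reduced with LASSO (binomial-deviance logistic regression,
penalty chosen by stratified cross-validation), and the radiomics score
("rad-score") of a case is the intercept plus the sum of the selected
features weighted by their coefficients.  The operating threshold on the
rad-score is the Youden-optimal cutpoint on the training cohort.

Features are standardized (mean 0, SD 1) before the penalized fit;
coefficients are reported on the standardized scale and the standardization
constants travel with the serialized model, so scoring raw vectors remains
well-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateLabelError, NoSignalError


@dataclass
class SignatureModel:
    """A fitted rad-score signature (serializable as JSON)."""

    modality: str
    selected_indices: list[int]
    coefficients: list[float]
    intercept: float
    threshold: float | None = None
    lambda_: float | None = None
    orientation: str = "higher_is_malignant"
    standardized: bool = False
    feature_means: list[float] | None = None  # per selected index, when standardized
    feature_scales: list[float] | None = None
    seed: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.selected_indices) != len(self.coefficients):
            raise ValueError("one coefficient per selected feature required")
        if any(c == 0 for c in self.coefficients):
            raise ValueError("selected features must have non-zero coefficients")
        if self.orientation not in ("higher_is_malignant", "lower_is_malignant"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        return cls(**json.loads(Path(path).read_text()))


def rad_score(model: SignatureModel, feature_vector) -> float:
    """intercept + sum(coefficient * feature) over the selected indices."""
    x = np.asarray(feature_vector, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("feature vector must be 1-D")
    idx = np.asarray(model.selected_indices, dtype=int)
    if idx.size and x.shape[0] <= idx.max():
        raise ValueError(
            f"feature vector of length {x.shape[0]} is missing index {idx.max()}"
        )
    z = x[idx] if idx.size else np.empty(0)
    if model.standardized:
        z = (z - np.asarray(model.feature_means)) / np.asarray(model.feature_scales)
    return float(model.intercept + z @ np.asarray(model.coefficients))


def rad_scores(model: SignatureModel, feature_matrix) -> np.ndarray:
    X = np.asarray(feature_matrix, dtype=np.float64)
    return np.array([rad_score(model, row) for row in X])


class YoudenResult(NamedTuple):
    threshold: float
    sensitivity: float
    specificity: float
    j: float


def youden_threshold(scores, labels, positive_higher: bool = True) -> YoudenResult:
    """Cutpoint maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent sorted unique scores plus the
    two extreme cutpoints that call every case or no case (the unique score
    itself when there is only one).  A case is called positive
    when its score is strictly greater than the threshold (strictly lower
    when ``positive_higher=False``).  Ties on J break toward higher
    specificity, then toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise DegenerateLabelError("both classes required for a Youden threshold")
    uniq = np.unique(scores)
    if uniq.size > 1:
        candidates = np.concatenate(
            [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]]
        )
    else:
        candidates = uniq
    best: YoudenResult | None = None
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    for t in candidates:
        called = scores > t if positive_higher else scores < t
        sens = int((called & y).sum()) / n_pos
        spec = int((~called & ~y).sum()) / n_neg
        j = sens + spec - 1
        cand = YoudenResult(float(t), sens, spec, j)
        if (
            best is None
            or j > best.j + 1e-12
            or (abs(j - best.j) <= 1e-12 and spec > best.specificity + 1e-12)
        ):
            best = cand
    return best


class LassoSignature(BaseEstimator, ClassifierMixin):
    """LASSO-logistic rad-score signature with a Youden operating point.

    Parameters
    ----------
    cv_folds : int, default 10
        Stratified folds for the penalty search (binomial deviance).
    n_penalties : int, default 25
        Size of the logarithmic penalty grid.
    penalty_strength : float or None
        Fix the L1 penalty (lambda) instead of cross-validating; large
        values force full shrinkage and an intercept-only model.
    standardize : bool, default True
    modality : str, a tag carried into the serialized model.
    seed : int

    Fitted attributes: ``selected_indices_``, ``coefficients_``,
    ``intercept_``, ``threshold_``, ``orientation_``, ``lambda_``,
    ``signature_`` (a :class:`SignatureModel`).
    """

    def __init__(self, cv_folds: int = 10, n_penalties: int = 25,
                 penalty_strength: float | None = None, standardize: bool = True,
                 modality: str = "bmode", seed: int = 0):
        self.cv_folds = cv_folds
        self.n_penalties = n_penalties
        self.penalty_strength = penalty_strength
        self.standardize = standardize
        self.modality = modality
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_bin = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise DegenerateLabelError("binary labels required")
        if np.allclose(X.std(axis=0), 0):
            raise NoSignalError("constant feature matrix")
        counts = np.bincount(y_bin)
        if self.penalty_strength is None and counts.min() < self.cv_folds:
            raise ValueError(
                f"need >= cv_folds={self.cv_folds} cases per class, got {counts.min()}"
            )

        if self.standardize:
            self._scaler = StandardScaler().fit(X)
            Xs = self._scaler.transform(X)
        else:
            self._scaler = None
            Xs = X

        if self.penalty_strength is not None:
            lam = float(self.penalty_strength)
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
                random_state=self.seed, max_iter=2000,
            ).fit(Xs, y_bin)
        else:
            cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
            clf = LogisticRegressionCV(
                Cs=np.logspace(-4, 3, self.n_penalties), l1_ratios=(1.0,),
                solver="liblinear", scoring="neg_log_loss", cv=cv,
                random_state=self.seed, max_iter=2000, use_legacy_attributes=False,
            ).fit(Xs, y_bin)
            lam = float(1.0 / np.atleast_1d(clf.C_)[0])

        coef = clf.coef_[0]
        support = np.nonzero(coef)[0]
        self.selected_indices_ = support.astype(int)
        self.coefficients_ = coef[support]
        self.intercept_ = float(clf.intercept_[0])
        self.lambda_ = lam

        scores = self._raw_scores(X)
        if support.size and len(np.unique(scores)) > 1:
            auc = roc_auc_score(y_bin, scores)
        else:
            auc = 0.5
        self.orientation_ = "higher_is_malignant" if auc >= 0.5 else "lower_is_malignant"
        try:
            yr = youden_threshold(scores, y_bin,
                                  positive_higher=self.orientation_ == "higher_is_malignant")
            self.threshold_ = yr.threshold
        except DegenerateLabelError:  # pragma: no cover
            self.threshold_ = 0.0

        means = scales = None
        if self.standardize:
            means = self._scaler.mean_[support].tolist()
            scales = self._scaler.scale_[support].tolist()
        self.signature_ = SignatureModel(
            modality=self.modality,
            selected_indices=self.selected_indices_.tolist(),
            coefficients=self.coefficients_.tolist(),
            intercept=self.intercept_,
            threshold=self.threshold_,
            lambda_=self.lambda_,
            orientation=self.orientation_,
            standardized=self.standardize,
            feature_means=means,
            feature_scales=scales,
            seed=self.seed,
        )
        return self

    def _raw_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        Z = self._scaler.transform(X) if self._scaler is not None else X
        return Z[:, self.selected_indices_] @ self.coefficients_ + self.intercept_

    def decision_function(self, X) -> np.ndarray:
        """Rad-score of each row."""
        check_is_fitted(self, "signature_")
        return self._raw_scores(X)

    def predict(self, X):
        scores = self.decision_function(X)
        if self.orientation_ == "higher_is_malignant":
            positive = scores > self.threshold_
        else:
            positive = scores < self.threshold_
        return self.classes_[positive.astype(int)]


def fit_lasso_signature(features, labels, cv_folds: int = 10, seed: int = 0,
                        modality: str = "bmode") -> SignatureModel:
    """Functional wrapper: fit and return the serializable signature."""
    est = LassoSignature(cv_folds=cv_folds, seed=seed, modality=modality)
    est.fit(features, labels)
    return est.signature_


def load_reference_signature(modality: str) -> SignatureModel:
    """Frozen reference signatures shipped with the package.

    These are published formulas transcribed verbatim (7 B-mode features,
    4 SWE features, with their intercepts and operating thresholds); they
    validate rad-score arithmetic and report rendering, and are not
    produced by — nor comparable to — fits on synthetic cohorts.
    """
    name = {"bmode": "bus_reference_signature.json",
            "swe": "swe_reference_signature.json"}[modality]
    with resources.files("swe_radiomics.fixtures").joinpath(name).open() as fh:
        return SignatureModel(**json.load(fh))
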