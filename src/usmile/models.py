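"""Probabilistic classifier adapters and cross-validated prediction plumbing.

Any model usable with the rLR machinery only needs to emit an event
probability per observation; the two built-in families are a plain
maximum-likelihood logistic regression (parametric, p-values available) and
bootstrap-aggregated decision trees (non-parametric, effect-size selection
only).  Out-of-fold probabilities under a stratified K-fold plan are the
common currency: every metric downstream is computed on predictions for
observations the model never saw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import DEFAULT_EPS, PredictionSet, _as_binary_labels
from .exceptions import ValidationError

_SATURATION = 1e-10  # training probability this extreme flags separation


class PrevalenceModel(BaseEstimator):
    """Intercept-only model: predicts the training prevalence everywhere."""

    is_parametric = True

    def fit(self, X, y):
        y = _as_binary_labels(y)
        self.prevalence_ = float(y.mean())
        self.converged_ = True
        self.separation_ = False
        return self

    def predict_event_probability(self, X) -> np.ndarray:
        return np.full(len(X), self.prevalence_)


class LogisticModel(BaseEstimator):
    """Maximum-likelihood logistic regression (intercept always included).

    Thin wrapper around scikit-learn's unpenalized ``LogisticRegression``.
    Convergence is declared by the L-BFGS stopping rule at ``tol`` within
    ``max_iter`` iterations; non-convergence and (quasi-)separation set the
    ``converged_`` / ``separation_`` flags instead of raising.
    An empty feature set degrades gracefully to the prevalence model.
    """

    is_parametric = True

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError(f"feature matrix must be 2-D, got shape {X.shape}")
        y = _as_binary_labels(y)
        if y.sum() in (0, len(y)):
            raise ValidationError("cannot fit a classifier on single-class labels")
        self.n_features_in_ = X.shape[1]
        if X.shape[1] == 0:
            self._null = PrevalenceModel().fit(X, y)
            self.converged_ = True
            self.separation_ = False
            return self
        if np.any(X.std(axis=0) == 0.0):
            raise ValidationError("feature matrix contains a constant column")
        self._null = None
        est = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=self.tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        self._est = est
        self.coef_ = est.coef_[0]
        self.intercept_ = float(est.intercept_[0])
        self.converged_ = int(est.n_iter_[0]) < self.max_iter
        p_train = est.predict_proba(X)[:, 1]
        self.separation_ = bool(
            (p_train.min() < _SATURATION) or (p_train.max() > 1.0 - _SATURATION)
        )
        return self

    def predict_event_probability(self, X) -> np.ndarray:
        if self._null is not None:
            return self._null.predict_event_probability(X)
        return self._est.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]


class BaggedTreesModel(BaseEstimator):
    """Bootstrap-aggregated decision trees (random-forest family).

    Defaults: 500 trees, sqrt(p) candidate features per split, and leaves of
    at least ``min_samples_leaf`` observations.  Because the rLR machinery
    consumes *probabilities*, the trees are grown as probability estimators:
    larger leaves keep the vote proportions calibrated instead of saturating
    at 0/1, and the aggregated votes are additionally shrunk away from exact
    0/1 by a Laplace-style floor of ``1 / (2 * n_estimators)`` so that
    log-likelihood-based metrics stay bounded.
    """

    is_parametric = False

    def __init__(self, n_estimators: int = 500, random_state: int | None = None,
                 min_samples_leaf: int = 10):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = _as_binary_labels(y)
        if y.sum() in (0, len(y)):
            raise ValidationError("cannot fit a classifier on single-class labels")
        self.n_features_in_ = X.shape[1]
        if X.shape[1] == 0:
            self._null = PrevalenceModel().fit(X, y)
            return self
        self._null = None
        self._est = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            max_depth=None,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def predict_event_probability(self, X) -> np.ndarray:
        if self._null is not None:
            return self._null.predict_event_probability(X)
        p = self._est.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]
        floor = 1.0 / (2.0 * self.n_estimators)
        return np.clip(p, floor, 1.0 - floor)


_FAMILIES = {"logistic": LogisticModel, "forest": BaggedTreesModel}


def make_model(family: str, seed: int | None = None, **params) -> BaseEstimator:
    """Instantiate a built-in model family (``logistic`` or ``forest``)."""
    if family not in _FAMILIES:
        raise ValidationError(
            f"unknown model family {family!r}; choose from {sorted(_FAMILIES)}"
        )
    if family == "forest":
        params.setdefault("random_state", seed)
    return _FAMILIES[family](**params)


@dataclass
class CVPlan:
    """Stratified K-fold assignment, fully determined by (labels, n_folds, seed)."""

    n_folds: int = 10
    seed: int = 0

    def splits(self, y) -> list[tuple[np.ndarray, np.ndarray]]:
        y = _as_binary_labels(y)
        if min(int(y.sum()), int(len(y) - y.sum())) < self.n_folds:
            raise ValidationError(
                f"cannot stratify {self.n_folds} folds: minority class has "
                f"fewer than {self.n_folds} observations"
            )
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed
        )
        return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]

    def assignments(self, y) -> np.ndarray:
        fold = np.empty(len(y), dtype=np.int64)
        for i, (_, te) in enumerate(self.splits(y)):
            fold[te] = i
        return fold


def cv_probabilities(X, y, model: BaseEstimator, plan: CVPlan) -> np.ndarray:
    """Pooled out-of-fold event probabilities aligned to input order.

    For each fold the (cloned) model is fit on the other folds and predicts
    the held-out one; no observation is ever predicted by a model that saw
    it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _as_binary_labels(y)
    out = np.full(len(y), np.nan)
    for train, test in plan.splits(y):
        if y[train].sum() in (0, len(train)):
            raise ValidationError("a training fold lost one class entirely")
        est = clone(model).fit(X[train], y[train])
        out[test] = est.predict_event_probability(X[test])
    return out


def _select_columns(X: pd.DataFrame, variables) -> np.ndarray:
    missing = [v for v in variables if v not in X.columns]
    if missing:
        raise ValidationError(f"variables not in feature table: {missing}")
    return X[list(variables)].to_numpy(dtype=np.float64)


def paired_cv(
    X,
    y,
    ref_vars,
    new_vars,
    model: BaseEstimator | str = "logistic",
    plan: CVPlan | None = None,
    eps: float = DEFAULT_EPS,
) -> PredictionSet:
    """PredictionSet of a (reference, new) model pair under one shared CV plan.

    An empty ``ref_vars`` means the null (training-fold prevalence) model;
    otherwise ``ref_vars`` must be nested inside ``new_vars``.  Both models
    are trained and evaluated on identical folds.
    """
    X = pd.DataFrame(X)
    y = _as_binary_labels(np.asarray(y))
    ref_vars, new_vars = list(ref_vars), list(new_vars)
    if ref_vars and not set(ref_vars) <= set(new_vars):
        raise ValidationError(
            f"reference variables {ref_vars} are not nested in {new_vars}"
        )
    if isinstance(model, str):
        model = make_model(model)
    plan = plan or CVPlan()

    def _oof(variables) -> np.ndarray:
        proto = PrevalenceModel() if not variables else model
        return cv_probabilities(_select_columns(X, variables), y, proto, plan)

    return PredictionSet(y=y, p_ref=_oof(ref_vars), p_new=_oof(new_vars), eps=eps)
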