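"""Forward stepwise variable selection with removal, in four criterion variants.

The selector grows a variable set by repeatedly adding the candidate that
most improves the configured criterion -- out-of-fold AUC-ROC (``auc``) or
one of the rLR coefficients (``rlr_overall``, ``rlr_event``,
``rlr_nonevent``) -- and, under the p-value scheme, pruning variables whose
drop-one test is no longer significant.  Two gating schemes mirror the two
model worlds:

* ``pvalue`` (parametric models): a candidate may enter when its
  likelihood-ratio entry test against the current model has p < ``p_enter``
  (overall chi-squared test for ``auc``/``rlr_overall``; class-specific gamma
  test for the class variants) *and* it strictly improves the criterion;
  included variables are removed while their drop-one p >= ``p_remove``.
* ``effect_size`` (any model): a candidate enters while the best relative
  criterion gain is at least ``min_gain``; no removal.

All candidate evaluations use pooled out-of-fold predictions under one
shared stratified K-fold plan, so entry decisions are made on
out-of-sample behaviour.  Each step records the rLR coefficient sets in
both evaluation contexts: against the null model (Context A, absolute) and
against the immediate predecessor (Context B, incremental).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (
    DEFAULT_EPS,
    PairEvaluation,
    PredictionSet,
    RLRCoefficients,
    _as_binary_labels,
    evaluate_pair,
)
from .exceptions import ValidationError
from .inference import SignificanceResult, class_test, overall_test, significance_summary
from .metrics import MetricReport, auc_roc, delong_test, metric_report
from .models import CVPlan, PrevalenceModel, cv_probabilities, make_model

CRITERIA = ("auc", "rlr_overall", "rlr_event", "rlr_nonevent")
SCHEMES = ("pvalue", "effect_size")

_CRITERION_COEF = {"rlr_overall": "rLR", "rlr_event": "rLR1", "rlr_nonevent": "rLR0"}


def criterion_value(pred: PredictionSet, criterion: str) -> float:
    """Scalar selection criterion of a (reference, new) prediction pair.

    ``auc`` scores the new model's probabilities alone; the rLR variants
    score the improvement over the pair's reference.
    """
    if criterion == "auc":
        return auc_roc(pred.y, pred.p_new)
    if criterion in _CRITERION_COEF:
        coef = evaluate_pair(pred).rlr
        return float(getattr(coef, _CRITERION_COEF[criterion]))
    raise ValidationError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


@dataclass
class SelectionStep:
    """One action of the stepwise trace."""

    action: str  # enter | remove | stop
    variable: Optional[str]
    criterion_before: Optional[float] = None
    criterion_after: Optional[float] = None
    p_value: Optional[float] = None
    gain: Optional[float] = None
    context_a: Optional[PairEvaluation] = None
    significance_a: Optional[SignificanceResult] = None
    context_b: Optional[PairEvaluation] = None
    significance_b: Optional[SignificanceResult] = None
    variables_after: tuple = ()

    def to_dict(self) -> dict:
        def _ctx(ev, sig):
            if ev is None:
                return None
            out = {
                "decomposition": ev.decomposition.to_dict(),
                "rlr": ev.rlr.to_dict(),
                "i": ev.i.to_dict(),
            }
            if sig is not None:
                out["significance"] = sig.to_dict()
            return out

        return {
            "action": self.action,
            "variable": self.variable,
            "criterion_before": self.criterion_before,
            "criterion_after": self.criterion_after,
            "p_value": self.p_value,
            "gain": self.gain,
            "context_a": _ctx(self.context_a, self.significance_a),
            "context_b": _ctx(self.context_b, self.significance_b),
            "variables_after": list(self.variables_after),
        }


@dataclass
class SelectionTrace:
    """Ordered record of a stepwise run plus the final model's summaries."""

    steps: list[SelectionStep]
    selected_variables: list[str]
    final_metrics: Optional[MetricReport] = None
    final_rlr: Optional[RLRCoefficients] = None
    config: dict = field(default_factory=dict)

    def replay(self) -> list[str]:
        """Re-apply the recorded actions; must reproduce the final set."""
        current: list[str] = []
        for step in self.steps:
            if step.action == "enter":
                current.append(step.variable)
            elif step.action == "remove":
                current.remove(step.variable)
        return current

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "selected_variables": list(self.selected_variables),
            "final_metrics": None if self.final_metrics is None else self.final_metrics.to_dict(),
            "final_rlr": None if self.final_rlr is None else self.final_rlr.to_dict(),
            "config": dict(self.config),
        }


class StepwiseSelector(BaseEstimator):
    """Stepwise variable selector driven by AUC or rLR criteria.

    Parameters
    ----------
    criterion : {"auc", "rlr_overall", "rlr_event", "rlr_nonevent"}
        Quantity maximized when ranking candidate variables.
    scheme : {"pvalue", "effect_size"}
        Entry/removal gating.  ``pvalue`` requires a parametric model.
    p_enter, p_remove : float
        Significance thresholds of the p-value scheme (enter < remove).
    min_gain : float
        Minimum relative criterion improvement of the effect-size scheme.
    model : str or estimator
        ``"logistic"``, ``"forest"`` or any object with ``fit`` and
        ``predict_event_probability``.
    max_steps : int, optional
        Cap on entry steps (default: number of features).
    n_folds, seed : int
        Stratified cross-validation plan.
    eps : float
        Probability clipping bound for likelihood computations.
    alpha : float
        Significance level recorded with each step's line-style flags.

    Attributes
    ----------
    selected_variables_ : list of str
        Final variable set, in entry order.
    support_ : ndarray of bool
        Mask of selected columns.
    trace_ : SelectionTrace
        Full per-step record.
    """

    def __init__(
        self,
        criterion: str = "rlr_overall",
        scheme: str = "pvalue",
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        min_gain: float = 0.03,
        model="logistic",
        max_steps: Optional[int] = None,
        n_folds: int = 10,
        seed: int = 0,
        eps: float = DEFAULT_EPS,
        alpha: float = 0.05,
    ):
        self.criterion = criterion
        self.scheme = scheme
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.min_gain = min_gain
        self.model = model
        self.max_steps = max_steps
        self.n_folds = n_folds
        self.seed = seed
        self.eps = eps
        self.alpha = alpha

    # -- internal helpers ---------------------------------------------------

    def _oof(self, variables: tuple) -> np.ndarray:
        key = tuple(variables)
        if key not in self._cache:
            proto = PrevalenceModel() if not key else self._model
            cols = self._X[list(key)].to_numpy(dtype=np.float64)
            self._cache[key] = cv_probabilities(cols, self._y, proto, self._plan)
        return self._cache[key]

    def _pair(self, ref_vars: tuple, new_vars: tuple) -> PredictionSet:
        return PredictionSet(
            y=self._y, p_ref=self._oof(ref_vars), p_new=self._oof(new_vars), eps=self.eps
        )

    def _entry_pvalue(self, pred: PredictionSet) -> float:
        """One-added-variable test (k = 1) matched to the criterion.

        The rLR variants gate on the likelihood-ratio machinery they
        optimize (overall chi-squared, or the class-specific gamma test);
        traditional AUC maximization gates on the DeLong test for the
        out-of-fold AUC difference, the classical test for comparing two
        correlated ROC curves.
        """
        if self.criterion == "auc":
            return delong_test(pred.y, pred.p_new, pred.p_ref)[1]
        dec = evaluate_pair(pred).decomposition
        if self.criterion == "rlr_event":
            return class_test(dec.LR1, 1, dec.maxLR1 / dec.maxLR)
        if self.criterion == "rlr_nonevent":
            return class_test(dec.LR0, 1, dec.maxLR0 / dec.maxLR)
        return overall_test(dec.LR, 1)

    def _context_summaries(self, ref_vars: tuple, new_vars: tuple):
        """Context A (vs null) and Context B (vs predecessor) evaluations."""
        out = {}
        for tag, ref in (("a", ()), ("b", ref_vars)):
            pred = self._pair(ref, new_vars)
            ev = evaluate_pair(pred)
            sig = None
            if self._parametric:
                k = len(new_vars) - (0 if tag == "a" else len(ref_vars))
                if k >= 1:
                    sig = significance_summary(ev.decomposition, k, self.alpha)
            out[tag] = (ev, sig)
        return out["a"], out["b"]

    def _criterion_context_a(self, variables: tuple) -> float:
        """Criterion of a model in absolute (vs-null) terms, for effect sizes."""
        if self.criterion == "auc":
            return auc_roc(self._y, self._oof(variables))
        if not variables:
            return 0.0
        return criterion_value(self._pair((), variables), self.criterion)

    # -- stepwise phases ----------------------------------------------------

    def _forward_step(self, current: list[str], candidates: list[str]) -> Optional[SelectionStep]:
        best = None  # (value, variable, p, before, after, gain)
        cur = tuple(current)
        if self.scheme == "effect_size":
            before = self._criterion_context_a(cur)
        else:
            before = auc_roc(self._y, self._oof(cur)) if self.criterion == "auc" else 0.0
        for cand in sorted(candidates):
            new = cur + (cand,)
            try:
                pred_b = self._pair(cur, new)
            except ValidationError:
                continue  # model-fitting failure: candidate skipped
            if self.scheme == "pvalue":
                p = self._entry_pvalue(pred_b)
                after = criterion_value(pred_b, self.criterion)
                if p < self.p_enter and after > before:
                    if best is None or after > best[0]:
                        best = (after, cand, p, before, after, None)
            else:
                after = self._criterion_context_a(new)
                gain = (after - before) / max(abs(before), 0.01)
                if gain >= self.min_gain:
                    if best is None or after > best[0]:
                        best = (after, cand, None, before, after, gain)
        if best is None:
            return SelectionStep(action="stop", variable=None, variables_after=cur)
        _, var, p, before, after, gain = best
        new = cur + (var,)
        ctx_a, ctx_b = self._context_summaries(cur, new)
        return SelectionStep(
            action="enter",
            variable=var,
            criterion_before=before,
            criterion_after=after,
            p_value=p,
            gain=gain,
            context_a=ctx_a[0],
            significance_a=ctx_a[1],
            context_b=ctx_b[0],
            significance_b=ctx_b[1],
            variables_after=new,
        )

    def _removal_phase(self, current: list[str]) -> list[SelectionStep]:
        steps: list[SelectionStep] = []
        while current:
            worst = None  # (p, variable)
            for var in sorted(current):
                reduced = tuple(v for v in current if v != var)
                p = self._entry_pvalue(self._pair(reduced, tuple(current)))
                if worst is None or p > worst[0]:
                    worst = (p, var)
            if worst is None or worst[0] < self.p_remove:
                break
            p, var = worst
            reduced = tuple(v for v in current if v != var)
            ctx_a, ctx_b = self._context_summaries(reduced, tuple(current))
            current.remove(var)
            steps.append(
                SelectionStep(
                    action="remove",
                    variable=var,
                    p_value=p,
                    context_a=ctx_a[0],
                    significance_a=ctx_a[1],
                    context_b=ctx_b[0],
                    significance_b=ctx_b[1],
                    variables_after=tuple(current),
                )
            )
        return steps

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y):
        if self.criterion not in CRITERIA:
            raise ValidationError(f"unknown criterion {self.criterion!r}; choose from {CRITERIA}")
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not 0.0 < self.p_enter < self.p_remove < 1.0:
            raise ValidationError("need 0 < p_enter < p_remove < 1")
        if self.min_gain <= 0.0:
            raise ValidationError("min_gain must be positive")

        self._X = pd.DataFrame(X).rename(columns=str)
        self._y = _as_binary_labels(np.asarray(y))
        self._model = make_model(self.model, seed=self.seed) if isinstance(self.model, str) else self.model
        self._parametric = bool(getattr(self._model, "is_parametric", False))
        if self.scheme == "pvalue" and not self._parametric:
            raise ValidationError(
                "the p-value scheme requires a parametric model; "
                "use scheme='effect_size' for non-parametric models"
            )
        self._plan = CVPlan(self.n_folds, self.seed)
        self._cache: dict[tuple, np.ndarray] = {}

        self.n_features_in_ = self._X.shape[1]
        self.feature_names_in_ = np.asarray(self._X.columns, dtype=object)
        max_steps = self.max_steps if self.max_steps is not None else self.n_features_in_

        current: list[str] = []
        steps: list[SelectionStep] = []
        seen_states = {frozenset()}
        n_entries = 0
        while n_entries < max_steps:
            candidates = [c for c in self._X.columns if c not in current]
            step = self._forward_step(current, candidates)
            steps.append(step)
            if step.action == "stop":
                break
            current.append(step.variable)
            n_entries += 1
            if self.scheme == "pvalue":
                steps.extend(self._removal_phase(current))
            state = frozenset(current)
            if state in seen_states:  # oscillation guard
                break
            seen_states.add(state)

        final = tuple(current)
        final_oof = self._oof(final)
        final_rlr = evaluate_pair(self._pair((), final)).rlr
        self.selected_variables_ = list(final)
        self.support_ = np.isin(self.feature_names_in_, list(final))
        self.trace_ = SelectionTrace(
            steps=steps,
            selected_variables=list(final),
            final_metrics=metric_report(self._y, final_oof, eps=self.eps),
            final_rlr=final_rlr,
            config=self.get_params(),
        )
        # free fitting state but keep the out-of-fold cache for inspection
        self.oof_probabilities_ = {k: v for k, v in self._cache.items()}
        for attr in ("_X", "_y", "_cache", "_plan", "_model"):
            delattr(self, attr)
        return self

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        X = pd.DataFrame(X).rename(columns=str)
        return X[self.selected_variables_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def stepwise_select(X, y, **config) -> SelectionTrace:
    """Functional wrapper: run a :class:`StepwiseSelector` and return its trace."""
    return StepwiseSelector(**config).fit(X, y).trace_
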