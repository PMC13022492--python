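"""Tests for stepwise variable selection."""

import json

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from usmile import (
    PredictionSet,
    StepwiseSelector,
    ValidationError,
    criterion_value,
    stepwise_select,
)
from usmile.io import to_jsonable
from usmile.scenarios import ScenarioSpec, generate


def _logistic_labels(rng, logits):
    return (rng.uniform(size=len(logits)) < 1 / (1 + np.exp(-logits))).astype(int)


def _noise_frame(rng, n, k, prefix="N"):
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"{prefix}{i}" for i in range(1, k + 1)])


class TestCriterionValue:
    def test_toy_values(self, toy_pair):
        assert criterion_value(toy_pair, "rlr_overall") == pytest.approx(0.2925, abs=2e-4)
        assert criterion_value(toy_pair, "rlr_event") == pytest.approx(0.2925, abs=2e-4)

    def test_auc_scores_new_model_only(self):
        pred = PredictionSet([0, 0, 1, 1], [0.5] * 4, [0.1, 0.2, 0.8, 0.9])
        assert criterion_value(pred, "auc") == 1.0

    def test_identical_models_give_zero(self):
        p = [0.3, 0.7, 0.4, 0.6]
        pred = PredictionSet([0, 1, 0, 1], p, p)
        assert criterion_value(pred, "rlr_event") == 0.0

    def test_unknown_criterion(self, toy_pair):
        with pytest.raises(ValidationError):
            criterion_value(toy_pair, "accuracy")


class TestForwardEntry:
    def test_informative_candidate_beats_noise(self):
        """A single strong predictor among nine noise columns should be the
        first entry in (almost) every seed."""
        hits = 0
        n_seeds = 15
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            x1 = rng.normal(size=500)
            y = _logistic_labels(rng, 1.5 * x1)
            if min(y.sum(), 500 - y.sum()) < 10:
                continue
            X = _noise_frame(rng, 500, 9).assign(signal=x1)
            sel = StepwiseSelector(criterion="rlr_overall", seed=s).fit(X, y)
            entered = [st.variable for st in sel.trace_.steps if st.action == "enter"]
            hits += bool(entered) and entered[0] == "signal"
        assert hits >= n_seeds - 1

    def test_all_noise_selects_nothing(self):
        """With only noise columns the cross-validated entry gate should
        keep the model empty in the vast majority of seeds (the family-wise
        chance of a false entry grows with the candidate count, so four
        candidates are screened per replicate)."""
        empty = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            y = np.tile([0, 1], 250)
            X = _noise_frame(rng, 500, 4)
            sel = StepwiseSelector(criterion="rlr_overall", seed=s).fit(X, y)
            empty += not sel.selected_variables_
        assert empty >= n_seeds - 2

    def test_tie_break_is_lexicographic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = _logistic_labels(rng, 1.2 * x)
        X = pd.DataFrame({"b_copy": x, "a_copy": x})
        sel = StepwiseSelector(criterion="rlr_overall", seed=0).fit(X, y)
        first = [st for st in sel.trace_.steps if st.action == "enter"][0]
        assert first.variable == "a_copy"

    def test_entered_p_values_below_threshold(self):
        spec = ScenarioSpec("t", n=600, n_features=5, n_informative=3,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.2, 0.9, 0.6), seed=2)
        X, y = generate(spec)
        sel = StepwiseSelector(criterion="rlr_overall", p_enter=0.05, seed=2).fit(X, y)
        enters = [st for st in sel.trace_.steps if st.action == "enter"]
        assert enters
        assert all(st.p_value < 0.05 for st in enters)


class TestRemoval:
    def test_variable_made_redundant_is_removed(self):
        """An aggregate predictor entered first becomes an exact linear
        combination of two later entries and should be dropped."""
        removed = 0
        n_seeds = 12
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            x1, x2 = rng.normal(size=(2, 1000))
            noisy_agg = x1 + x2 + 0.7 * rng.normal(size=1000)
            y = _logistic_labels(rng, 1.2 * x1 + 1.2 * x2)
            X = pd.DataFrame({"agg": noisy_agg, "x1": x1, "x2": x2})
            sel = StepwiseSelector(criterion="rlr_overall", seed=s).fit(X, y)
            removed += "agg" not in sel.selected_variables_
        assert removed >= n_seeds - 2

    def test_effect_size_scheme_never_removes(self):
        spec = ScenarioSpec("t", n=500, n_features=4, n_informative=2,
                            n_redundant=1, label_noise=0.0,
                            effect_sizes=(1.3, 0.8), seed=0)
        X, y = generate(spec)
        sel = StepwiseSelector(criterion="rlr_overall", scheme="effect_size",
                               seed=0).fit(X, y)
        assert all(st.action != "remove" for st in sel.trace_.steps)


class TestSchemes:
    def test_effect_size_criterion_nondecreasing(self):
        spec = ScenarioSpec("t", n=600, n_features=6, n_informative=4,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.4, 1.1, 0.8, 0.5), seed=1)
        X, y = generate(spec)
        sel = StepwiseSelector(criterion="rlr_overall", scheme="effect_size",
                               min_gain=0.03, seed=1).fit(X, y)
        after = [st.criterion_after for st in sel.trace_.steps if st.action == "enter"]
        assert after == sorted(after)
        gains = [st.gain for st in sel.trace_.steps if st.action == "enter"]
        assert all(g >= 0.03 for g in gains)

    def test_pvalue_scheme_requires_parametric_model(self):
        X = pd.DataFrame({"V1": np.arange(40.0)})
        y = np.tile([0, 1], 20)
        with pytest.raises(ValidationError):
            StepwiseSelector(scheme="pvalue", model="forest").fit(X, y)

    def test_forest_effect_size_runs_without_significance(self):
        spec = ScenarioSpec("t", n=300, n_features=3, n_informative=2,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.5, 1.0), seed=0)
        X, y = generate(spec)
        from usmile import BaggedTreesModel
        sel = StepwiseSelector(criterion="rlr_overall", scheme="effect_size",
                               model=BaggedTreesModel(30, random_state=0),
                               n_folds=5, seed=0).fit(X, y)
        assert sel.selected_variables_  # the strong features are found
        for st in sel.trace_.steps:
            assert st.significance_a is None and st.significance_b is None


class TestTraceAndEstimatorSurface:
    def test_same_seed_gives_identical_trace(self):
        spec = ScenarioSpec("t", n=400, n_features=5, n_informative=2,
                            n_redundant=1, label_noise=0.05,
                            effect_sizes=(1.2, 0.8), seed=9)
        X, y = generate(spec)
        traces = [
            json.dumps(to_jsonable(StepwiseSelector(seed=9).fit(X, y).trace_),
                       sort_keys=True)
            for _ in range(2)
        ]
        assert traces[0] == traces[1]

    def test_replay_reproduces_final_set(self):
        spec = ScenarioSpec("t", n=400, n_features=5, n_informative=3,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.3, 1.0, 0.7), seed=3)
        X, y = generate(spec)
        trace = stepwise_select(X, y, criterion="rlr_overall", seed=3)
        assert trace.replay() == trace.selected_variables

    def test_max_steps_caps_entries(self):
        spec = ScenarioSpec("t", n=500, n_features=6, n_informative=4,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.4, 1.2, 1.0, 0.8), seed=0)
        X, y = generate(spec)
        sel = StepwiseSelector(criterion="rlr_overall", max_steps=2, seed=0).fit(X, y)
        assert sum(st.action == "enter" for st in sel.trace_.steps) <= 2

    def test_sklearn_surface(self):
        spec = ScenarioSpec("t", n=300, n_features=4, n_informative=2,
                            n_redundant=0, label_noise=0.0,
                            effect_sizes=(1.5, 1.0), seed=0)
        X, y = generate(spec)
        sel = StepwiseSelector(criterion="rlr_overall", seed=0)
        cloned = clone(sel)  # params round-trip through get_params/set_params
        assert cloned.get_params() == sel.get_params()
        sel.fit(X, y)
        assert sel.support_.sum() == len(sel.selected_variables_)
        assert list(sel.transform(X).columns) == sel.selected_variables_
        assert sel.trace_.final_metrics.auc_roc > 0.5
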