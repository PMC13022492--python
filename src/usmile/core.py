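"""Likelihood-ratio decomposition and the relative likelihood ratio (rLR) hierarchy.

A *new* probabilistic classifier is compared with a *reference* one on the
same observations through the classical likelihood-ratio statistic

    LR = 2 * (ll_new - ll_ref),

where ``ll`` is the Bernoulli log-likelihood of the predicted event
probabilities.  The statistic is split by outcome class (non-event ``0``,
event ``1``) and, within each class, into the improvement (+) and worsening
(-) parts of the per-observation contributions.  Dividing each part by the
class-specific ceiling ``maxLR_c`` -- the LR a perfect classifier would
attain against the same reference -- yields the dimensionless rLR hierarchy:

* level 3: ``rLR = LR / maxLR`` (overall),
* level 2: ``rLR_0``, ``rLR_1`` (net, per class),
* level 1: ``rLR_0^+``, ``rLR_0^-``, ``rLR_1^+``, ``rLR_1^-`` (subclasses).

With the intercept-only (prevalence) model as reference, ``rLR`` coincides
with McFadden's pseudo-R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import DegenerateReferenceError, ValidationError

#: Default probability clipping bound applied before any logarithm.
DEFAULT_EPS = 1e-12


def _as_binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValidationError(f"labels must be one-dimensional, got shape {y.shape}")
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)]
        raise ValidationError(f"labels must be 0/1; found values {bad}")
    return y.astype(np.int64)


def _as_probabilities(p, name: str, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.shape[0] != n:
        raise ValidationError(
            f"{name} must be a vector of length {n}, got shape {p.shape}"
        )
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"{name} contains non-finite values")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError(
            f"{name} must lie in [0, 1]; range is [{p.min()}, {p.max()}]"
        )
    return p


def clip_probabilities(p, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Clip probabilities into ``[eps, 1 - eps]``.

    Probabilities already inside the open interval are returned bit-identical;
    only exact (or near-) 0/1 predictions are moved, keeping log-likelihoods
    finite.
    """
    if not 0.0 < eps < 0.5:
        raise ValidationError(f"eps must be in (0, 0.5), got {eps}")
    return np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)


@dataclass
class PredictionSet:
    """Outcome labels with paired reference/new event probabilities.

    Parameters
    ----------
    y : array-like of 0/1
        Outcome label per observation (0 = non-event, 1 = event).
    p_ref, p_new : array-like of float
        Event probability per observation under the reference and the new
        model.  Values are validated to lie in ``[0, 1]`` and then clipped
        into ``[eps, 1 - eps]``.
    eps : float
        Clipping bound.
    """

    y: np.ndarray
    p_ref: np.ndarray
    p_new: np.ndarray
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        self.y = _as_binary_labels(self.y)
        n = self.y.shape[0]
        if n < 2:
            raise ValidationError(f"need at least 2 observations, got {n}")
        if self.y.sum() == 0 or self.y.sum() == n:
            raise ValidationError("both outcome classes must be present")
        self.p_ref = clip_probabilities(
            _as_probabilities(self.p_ref, "p_ref", n), self.eps
        )
        self.p_new = clip_probabilities(
            _as_probabilities(self.p_new, "p_new", n), self.eps
        )

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def n0(self) -> int:
        return int(self.n - self.y.sum())

    @property
    def n1(self) -> int:
        return int(self.y.sum())


@dataclass
class LRDecomposition:
    """Raw LR statistic with class/subclass split and perfect-classifier maxima.

    All quantities are on the likelihood-ratio-test scale (2 x log-likelihood
    difference).  Identities: ``LR = LR0 + LR1``, ``LR_c = LR_c_plus -
    LR_c_minus``, ``maxLR = maxLR0 + maxLR1``.
    """

    LR: float
    LR0: float
    LR1: float
    LR0_plus: float
    LR0_minus: float
    LR1_plus: float
    LR1_minus: float
    maxLR0: float
    maxLR1: float
    maxLR: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class RLRCoefficients:
    """The normalized seven-coefficient rLR hierarchy."""

    rLR: float
    rLR0: float
    rLR1: float
    rLR0_plus: float
    rLR0_minus: float
    rLR1_plus: float
    rLR1_minus: float

    def by_criterion(self, which: str) -> float:
        """Return the net coefficient named by ``which``
        (``overall`` | ``nonevent`` | ``event``)."""
        return {"overall": self.rLR, "nonevent": self.rLR0, "event": self.rLR1}[which]

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class ICoefficients:
    """Within-class proportions of improved (+) / worsened (-) observations.

    Ties (zero log-likelihood change) belong to neither subclass, so
    ``I_c_plus + I_c_minus <= 1`` for each class.
    """

    I0_plus: float
    I0_minus: float
    I1_plus: float
    I1_minus: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


class PairEvaluation(NamedTuple):
    decomposition: LRDecomposition
    rlr: RLRCoefficients
    i: ICoefficients


def loglik_contributions(y, p, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Per-observation Bernoulli log-likelihood ``y*ln(p) + (1-y)*ln(1-p)``.

    Probabilities are clipped into ``[eps, 1-eps]`` first, so every
    contribution is finite and non-positive.
    """
    y = _as_binary_labels(y)
    p = _as_probabilities(p, "p", y.shape[0])
    p = clip_probabilities(p, eps)
    return np.where(y == 1, np.log(p), np.log1p(-p))


def null_reference(y) -> np.ndarray:
    """Constant probability vector of the intercept-only (null) model.

    Every entry equals the event prevalence of ``y`` -- the maximum-likelihood
    fit of a model with no predictors.
    """
    y = _as_binary_labels(y)
    prevalence = y.mean()
    if prevalence in (0.0, 1.0):
        raise ValidationError(
            "null model is degenerate: labels contain a single class"
        )
    return np.full(y.shape[0], prevalence, dtype=np.float64)


def _loglik_delta(pred: PredictionSet) -> np.ndarray:
    """Per-observation ``d_i = 2 * (l_i(new) - l_i(ref))``."""
    ll_ref = np.where(pred.y == 1, np.log(pred.p_ref), np.log1p(-pred.p_ref))
    ll_new = np.where(pred.y == 1, np.log(pred.p_new), np.log1p(-pred.p_new))
    return 2.0 * (ll_new - ll_ref)


def decompose_lr(pred: PredictionSet) -> LRDecomposition:
    """Decompose the LR statistic of ``pred`` into class/subclass parts.

    ``maxLR_c`` is the class-c LR attained by a perfect classifier
    (probability 1 on the true class everywhere) against the same reference:
    ``maxLR1 = -2 * sum_{y=1} ln(p_ref)``, ``maxLR0 = -2 * sum_{y=0}
    ln(1 - p_ref)``.

    Raises
    ------
    DegenerateReferenceError
        If the reference is already (near-)perfect overall, i.e. ``maxLR``
        is at the clipping floor.
    """
    d = _loglik_delta(pred)
    ev = pred.y == 1

    def _split(mask: np.ndarray) -> tuple[float, float]:
        dm = d[mask]
        return float(dm[dm > 0].sum()), float(-dm[dm < 0].sum())

    lr0_plus, lr0_minus = _split(~ev)
    lr1_plus, lr1_minus = _split(ev)
    lr0 = lr0_plus - lr0_minus
    lr1 = lr1_plus - lr1_minus

    max_lr0 = float(-2.0 * np.log1p(-pred.p_ref[~ev]).sum())
    max_lr1 = float(-2.0 * np.log(pred.p_ref[ev]).sum())
    max_lr = max_lr0 + max_lr1
    if max_lr <= 10.0 * pred.n * pred.eps:
        raise DegenerateReferenceError(
            "reference model is already perfect (maxLR = 0); rLR is undefined"
        )
    return LRDecomposition(
        LR=lr0 + lr1,
        LR0=lr0,
        LR1=lr1,
        LR0_plus=lr0_plus,
        LR0_minus=lr0_minus,
        LR1_plus=lr1_plus,
        LR1_minus=lr1_minus,
        maxLR0=max_lr0,
        maxLR1=max_lr1,
        maxLR=max_lr,
    )


def rlr_coefficients(dec: LRDecomposition, *, n: int | None = None,
                     eps: float = DEFAULT_EPS) -> RLRCoefficients:
    """Normalize an :class:`LRDecomposition` into the seven rLR coefficients.

    Each class part is divided by its own ceiling ``maxLR_c``; the overall
    statistic by ``maxLR``.  A class whose ceiling sits at the clipping floor
    makes the ratio undefined and raises :class:`DegenerateReferenceError`.
    """
    floor = 10.0 * (n if n is not None else 1) * eps
    for cls, m in (("non-event", dec.maxLR0), ("event", dec.maxLR1)):
        if m <= floor:
            raise DegenerateReferenceError(
                f"reference model is already perfect for the {cls} class "
                f"(maxLR_c = {m:g}); class rLR is undefined"
            )
    return RLRCoefficients(
        rLR=dec.LR / dec.maxLR,
        rLR0=dec.LR0 / dec.maxLR0,
        rLR1=dec.LR1 / dec.maxLR1,
        rLR0_plus=dec.LR0_plus / dec.maxLR0,
        rLR0_minus=dec.LR0_minus / dec.maxLR0,
        rLR1_plus=dec.LR1_plus / dec.maxLR1,
        rLR1_minus=dec.LR1_minus / dec.maxLR1,
    )


def i_coefficients(pred: PredictionSet) -> ICoefficients:
    """Within-class proportions of observations improved / worsened by the
    new model.  Drives the point sizes of the U-smile plot."""
    d = _loglik_delta(pred)
    ev = pred.y == 1
    n0, n1 = (~ev).sum(), ev.sum()
    return ICoefficients(
        I0_plus=float((d[~ev] > 0).sum() / n0),
        I0_minus=float((d[~ev] < 0).sum() / n0),
        I1_plus=float((d[ev] > 0).sum() / n1),
        I1_minus=float((d[ev] < 0).sum() / n1),
    )


def evaluate_pair(pred: PredictionSet) -> PairEvaluation:
    """One-call façade: decomposition, rLR coefficients and I coefficients."""
    dec = decompose_lr(pred)
    return PairEvaluation(
        decomposition=dec,
        rlr=rlr_coefficients(dec, n=pred.n, eps=pred.eps),
        i=i_coefficients(pred),
    )
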