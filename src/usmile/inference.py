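"""Significance testing for the overall and class-specific LR statistics.

For parametric (maximum-likelihood) models the overall statistic ``LR``
follows, under the null of no improvement, an asymptotic chi-squared
distribution with ``k`` degrees of freedom, ``k`` being the number of added
variables.  The class components ``LR_0`` and ``LR_1`` are modelled as the
linear shares ``w_c * chi2_k`` with ``w_c = maxLR_c / maxLR`` -- a gamma
distribution with shape ``k/2`` and scale ``2 * w_c``.  This is the unique
linear transformation of LR consistent with the weighted recombination
identity ``rLR = rLR0 * w0 + rLR1 * w1``.

All tests are one-sided tests of *improvement*: a non-positive statistic
(the new model fits no better, e.g. overfitting under cross-validation)
yields p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .core import LRDecomposition
from .exceptions import ValidationError


def _check_df(k) -> int:
    if isinstance(k, bool) or int(k) != k or k < 1:
        raise ValidationError(f"degrees of freedom must be a positive integer, got {k!r}")
    return int(k)


@dataclass
class SignificanceResult:
    """P-values for the overall and class LR statistics plus plot line flags.

    ``solid0`` / ``solid1`` are the U-smile line styles: solid (True) when
    the class improvement is significant at ``alpha``, dashed otherwise.
    """

    k: int
    p_overall: float
    p0: float
    p1: float
    alpha: float = 0.05

    @property
    def solid0(self) -> bool:
        return self.p0 < self.alpha

    @property
    def solid1(self) -> bool:
        return self.p1 < self.alpha

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "p_overall": float(self.p_overall),
            "p0": float(self.p0),
            "p1": float(self.p1),
            "alpha": float(self.alpha),
            "solid0": self.solid0,
            "solid1": self.solid1,
        }


def overall_test(LR: float, k: int) -> float:
    """Upper-tail chi-squared(k) p-value for the overall LR statistic.

    ``LR <= 0`` returns p = 1 (one-sided improvement test).
    """
    k = _check_df(k)
    if LR <= 0.0:
        return 1.0
    return float(stats.chi2.sf(LR, df=k))


def class_test(LR_c: float, k: int, w_c: float) -> float:
    """Upper-tail p-value for a class statistic under its gamma null law.

    Under H0 the class share of the chi-squared statistic is
    ``w_c * chi2_k ~ Gamma(shape=k/2, scale=2*w_c)``.  ``w_c = 1`` recovers
    :func:`overall_test`.
    """
    k = _check_df(k)
    if not 0.0 < w_c <= 1.0:
        raise ValidationError(f"class weight w_c must be in (0, 1], got {w_c}")
    if LR_c <= 0.0:
        return 1.0
    return float(stats.gamma.sf(LR_c, a=k / 2.0, scale=2.0 * w_c))


def significance_summary(
    dec: LRDecomposition, k: int, alpha: float = 0.05
) -> SignificanceResult:
    """Combine the overall and class tests for a decomposition.

    Class weights are taken from the decomposition itself,
    ``w_c = maxLR_c / maxLR``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    w0 = dec.maxLR0 / dec.maxLR
    w1 = dec.maxLR1 / dec.maxLR
    return SignificanceResult(
        k=_check_df(k),
        p_overall=overall_test(dec.LR, k),
        p0=class_test(dec.LR0, k, w0),
        p1=class_test(dec.LR1, k, w1),
        alpha=alpha,
    )
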