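"""Companion threshold-free metrics: AUC-ROC, AUC-PR, Cllr, F1, McFadden R².

These complement the rLR hierarchy.  AUC-ROC and AUC-PR are delegated to
scikit-learn (Mann-Whitney and average-precision forms).  Cllr -- the cost
of log-likelihood ratios from the forensic-evaluation literature -- and
McFadden's pseudo-R² are computed here.  A DeLong test for comparing two
correlated ROC curves is included for AUC-driven stepwise selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .core import DEFAULT_EPS, _as_binary_labels, _as_probabilities, clip_probabilities, null_reference
from .exceptions import ValidationError


@dataclass
class MetricReport:
    """Scalar evaluation metrics of one probability vector."""

    auc_roc: float
    auc_pr: float
    cllr: float
    f1: float
    mcfadden: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _checked(y, p):
    y = _as_binary_labels(y)
    p = _as_probabilities(p, "p", y.shape[0])
    return y, p


def auc_roc(y, p) -> float:
    """Probability that a random event outscores a random non-event
    (ties count 1/2)."""
    y, p = _checked(y, p)
    if y.sum() in (0, len(y)):
        raise ValidationError("AUC-ROC requires both classes")
    return float(roc_auc_score(y, p))


def auc_pr(y, p) -> float:
    """Area under the precision-recall curve in average-precision form
    (step-wise interpolation over descending scores)."""
    y, p = _checked(y, p)
    if y.sum() == 0:
        raise ValidationError("AUC-PR requires at least one event")
    return float(average_precision_score(y, p))


def cllr(y, p, eps: float = DEFAULT_EPS) -> float:
    """Cost of log-likelihood ratios.

    Posterior probabilities are converted to likelihood ratios with the
    sample prevalence ``pi`` as prior odds, ``LR_i = p_i/(1-p_i) *
    (1-pi)/pi``, and

        Cllr = 1/2 * [ mean_{y=0} log2(1 + LR_i) + mean_{y=1} log2(1 + 1/LR_i) ].

    0 = perfect, 1 = uninformative (``p_i = pi`` for all i).
    """
    y, p = _checked(y, p)
    if y.sum() in (0, len(y)):
        raise ValidationError("Cllr requires both classes")
    p = clip_probabilities(p, eps)
    pi = y.mean()
    log_lr = np.log(p) - np.log1p(-p) + np.log1p(-pi) - np.log(pi)
    # log2(1+e^x) via logaddexp for numerical stability at extreme odds
    c0 = np.logaddexp(0.0, log_lr[y == 0]).mean()
    c1 = np.logaddexp(0.0, -log_lr[y == 1]).mean()
    return float(0.5 * (c0 + c1) / np.log(2.0))


def f1_at_threshold(y, p, t: float = 0.5) -> float:
    """F1 score of the hard classification ``p >= t`` (0 when no positive
    predictions hit)."""
    y, p = _checked(y, p)
    if not 0.0 < t < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {t}")
    return float(f1_score(y, (p >= t).astype(int), zero_division=0))


def mcfadden_r2(y, p, eps: float = DEFAULT_EPS) -> float:
    """McFadden pseudo-R²: ``1 - ll(p) / ll(null)`` with the prevalence
    model as null.  Identical to rLR computed against the null reference."""
    y, p = _checked(y, p)
    p = clip_probabilities(p, eps)
    p0 = null_reference(y)
    ll = np.where(y == 1, np.log(p), np.log1p(-p)).sum()
    ll0 = np.where(y == 1, np.log(p0), np.log1p(-p0)).sum()
    return float(1.0 - ll / ll0)


def metric_report(y, p, threshold: float = 0.5, eps: float = DEFAULT_EPS) -> MetricReport:
    """All companion metrics of one probability vector in a single report."""
    return MetricReport(
        auc_roc=auc_roc(y, p),
        auc_pr=auc_pr(y, p),
        cllr=cllr(y, p, eps),
        f1=f1_at_threshold(y, p, threshold),
        mcfadden=mcfadden_r2(y, p, eps),
        threshold=threshold,
    )


def _delong_placements(y: np.ndarray, p: np.ndarray):
    """Mid-rank placement values of the DeLong ROC machinery."""
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa, ties = 1/2
    order = np.concatenate([pos, neg])
    ranks = stats.rankdata(order)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    return v10, v01


def delong_test(y, p1, p2) -> tuple[float, float]:
    """DeLong test for the difference of two correlated ROC AUCs.

    Returns ``(delta, p_value)`` where ``delta = auc(p1) - auc(p2)`` and the
    p-value is one-sided for ``auc(p1) > auc(p2)``.  Standard errors come
    from the structural-components estimator of DeLong et al.
    """
    y, p1 = _checked(y, p1)
    p2 = _as_probabilities(p2, "p2", len(y))
    if y.sum() in (0, len(y)):
        raise ValidationError("DeLong test requires both classes")
    v10_a, v01_a = _delong_placements(y, p1)
    v10_b, v01_b = _delong_placements(y, p2)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = float(auc_a - auc_b)
    if var <= 0.0:
        # identical placements (e.g. p1 == p2): no evidence of difference
        return delta, 1.0
    z = delta / np.sqrt(var)
    return delta, float(stats.norm.sf(z))
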