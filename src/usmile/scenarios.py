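"""Seeded synthetic scenario generator for the simulation study.

Five built-in scenarios span a power gradient (low / medium / high),
class imbalance (90/10) and an asymmetric variant in which V1 separates
the classes through its variance rather than its mean:

==========================  ===========  =========  ======  ===========
scenario                    informative  redundant  noise   event prior
==========================  ===========  =========  ======  ===========
``low_power``               2            2          10 %    0.5
``medium_power``            5            2          5 %     0.5
``high_power``              8            0          0 %     0.5
``imbalanced``              5            2          5 %     0.1
``imbalanced_asymmetric``   5            2          5 %     0.1 (+ V1 flip)
==========================  ===========  =========  ======  ===========

Generated tables have 1000 rows and columns ``V1``..``V10`` plus the binary
outcome.  Informative feature ``j`` is class-conditionally Gaussian:
non-event ``N(0, 1)``, event ``N(delta_j, 1)``.  Redundant features are
random unit-norm linear combinations of the informative block plus
``N(0, 0.1^2)`` jitter; the remaining columns are independent standard
normals.  ``label_noise`` is the fraction of observations whose label is
re-drawn from ``Bernoulli(event_prior)`` after feature generation,
injecting irreducible error while preserving the class prior.  In the
asymmetric variant V1 becomes ``N(1, 2^2)`` for non-events and ``N(0, 1)``
for events, i.e. informative for the event class only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Endpoints of the default linearly declining effect-size ladder for the
#: low/medium/imbalanced scenarios (standardized mean differences).
DEFAULT_EFFECT_RANGE = (1.4, 1.0)

#: Stronger ladder for the high-power scenario, sized so that an oracle
#: model is near-perfect (all headline metrics ~ 1.0).
HIGH_POWER_EFFECT_RANGE = (4.5, 2.5)


def default_effect_sizes(
    n_informative: int, effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE
) -> tuple[float, ...]:
    """Linearly declining per-feature class separations."""
    hi, lo = effect_range
    return tuple(np.linspace(hi, lo, n_informative))


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic scenario."""

    name: str
    n: int = 1000
    n_features: int = 10
    n_informative: int = 5
    n_redundant: int = 2
    label_noise: float = 0.05
    event_prior: float = 0.5
    asymmetric_v1: bool = False
    effect_sizes: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValidationError(
                "n_informative + n_redundant exceeds n_features"
            )
        if not 0.0 <= self.label_noise < 0.5:
            raise ValidationError(f"label_noise must be in [0, 0.5), got {self.label_noise}")
        if not 0.0 < self.event_prior < 1.0:
            raise ValidationError(f"event_prior must be in (0, 1), got {self.event_prior}")
        if self.n < 2 or self.n_informative < 1:
            raise ValidationError("need n >= 2 and at least one informative feature")
        if not self.effect_sizes:
            object.__setattr__(
                self, "effect_sizes", default_effect_sizes(self.n_informative)
            )
        if len(self.effect_sizes) != self.n_informative:
            raise ValidationError(
                f"effect_sizes has {len(self.effect_sizes)} entries for "
                f"{self.n_informative} informative features"
            )

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return ScenarioSpec(**{**self.__dict__, "seed": seed})


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The five named scenarios of the simulation study."""
    medium = dict(n_informative=5, n_redundant=2, label_noise=0.05)
    return {
        "low_power": ScenarioSpec(
            "low_power", n_informative=2, n_redundant=2, label_noise=0.10
        ),
        "medium_power": ScenarioSpec("medium_power", **medium),
        "high_power": ScenarioSpec(
            "high_power",
            n_informative=8,
            n_redundant=0,
            label_noise=0.0,
            effect_sizes=default_effect_sizes(8, HIGH_POWER_EFFECT_RANGE),
        ),
        "imbalanced": ScenarioSpec("imbalanced", event_prior=0.1, **medium),
        "imbalanced_asymmetric": ScenarioSpec(
            "imbalanced_asymmetric", event_prior=0.1, asymmetric_v1=True, **medium
        ),
    }


def generate(spec: ScenarioSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate one dataset from a scenario spec.

    Returns a feature table with columns ``V1``..``V{n_features}`` and the
    binary outcome series ``y``.  Identical specs (including seed) yield
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n, spec.n_informative
    y = rng.binomial(1, spec.event_prior, size=n)

    X = np.empty((n, spec.n_features))
    X[:, :k] = rng.standard_normal((n, k)) + y[:, None] * np.asarray(spec.effect_sizes)
    for j in range(k, k + spec.n_redundant):
        w = rng.standard_normal(k)
        w /= np.linalg.norm(w)
        X[:, j] = X[:, :k] @ w + 0.1 * rng.standard_normal(n)
    n_pure = spec.n_features - k - spec.n_redundant
    if n_pure:
        X[:, k + spec.n_redundant:] = rng.standard_normal((n, n_pure))
    if spec.asymmetric_v1:
        # replace V1 after the redundant combinations are formed: its
        # variance signal (non-event N(1, 4), event N(0, 1)) must be carried
        # by V1 alone, not leaked into the redundant columns
        X[:, 0] = np.where(y == 1, rng.standard_normal(n), 1.0 + 2.0 * rng.standard_normal(n))

    if spec.label_noise > 0.0:
        n_noisy = int(round(spec.label_noise * n))
        idx = rng.choice(n, size=n_noisy, replace=False)
        y[idx] = rng.binomial(1, spec.event_prior, size=n_noisy)

    columns = [f"V{j + 1}" for j in range(spec.n_features)]
    return pd.DataFrame(X, columns=columns), pd.Series(y, name="y")
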