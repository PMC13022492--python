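import numpy as np
import pytest

from usmile import PredictionSet


@pytest.fixture
def toy_pair() -> PredictionSet:
    """Four-observation worked example: one improved non-event, one improved
    event, two unchanged."""
    return PredictionSet(
        y=[0, 0, 1, 1],
        p_ref=[0.5, 0.5, 0.5, 0.5],
        p_new=[0.25, 0.5, 0.75, 0.5],
    )


@pytest.fixture
def worsening_pair() -> PredictionSet:
    """Two observations, both pushed toward the wrong class."""
    return PredictionSet(y=[0, 1], p_ref=[0.5, 0.5], p_new=[0.9, 0.1])


def random_prediction_set(rng: np.random.Generator, n: int = 50) -> PredictionSet:
    """A random but valid PredictionSet (both classes guaranteed)."""
    y = rng.integers(0, 2, size=n)
    y[0], y[1] = 0, 1
    return PredictionSet(y=y, p_ref=rng.uniform(0.02, 0.98, n),
                         p_new=rng.uniform(0.02, 0.98, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
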