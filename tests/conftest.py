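import numpy as np
import pandas as pd
import pytest

from fairaudit.cohort import Cohort
from fairaudit.synthetic import (
    SyntheticConfig,
    generate_cohort,
    median_split_label,
    null_config,
)


@pytest.fixture
def default_cohort():
    """The emulated study cohort: 55 participants, biased generator defaults."""
    return median_split_label(generate_cohort(SyntheticConfig(seed=7)))


@pytest.fixture
def biased_cohort():
    """A larger biased cohort (shift and negative legacy both active)."""
    cfg = SyntheticConfig(
        n_participants=200, group_shift=0.6, legacy_strength=0.7, seed=11
    )
    return median_split_label(generate_cohort(cfg))


@pytest.fixture
def null_cohort():
    """No group shift, no legacy: labels independent of gender."""
    return median_split_label(generate_cohort(null_config(seed=3, n_participants=200)))


@pytest.fixture
def toy_cohort():
    """Two groups of three with well-separated feature values {1,2,3} / {11,12,13}."""
    df = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(6)],
            "group": ["a", "a", "a", "b", "b", "b"],
            "feat_1": [1.0, 2.0, 3.0, 11.0, 12.0, 13.0],
            "score": [0.0] * 6,
        }
    )
    return Cohort(df, privileged="b")


def random_predictions(rng, n_max=200):
    """A random (y_true, y_pred, group) instance with both groups nonempty."""
    n = rng.integers(4, n_max + 1)
    y_true = rng.integers(0, 2, n)
    y_pred = rng.integers(0, 2, n)
    group = np.where(rng.random(n) < 0.5, "m", "w")
    if (group == "m").all() or (group == "w").all():
        group[0], group[1] = "m", "w"
    return y_true, y_pred, group
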