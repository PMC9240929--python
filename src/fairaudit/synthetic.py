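"""Synthetic cohort generator.

Emulates the statistical structure of a small phone-sensing mental-health
study cohort: ~55 participants, a ~62/38 gender split with men as the
privileged group, phone-usage features whose distributions differ by gender,
a noisy monotone link from usage features to a continuous mental-health
score, and a controllable *negative legacy* — an under-representation of the
minority group among high-score (positive) labels.

Generative model
----------------
Each participant has a 5-dimensional latent behavioural state
``z ~ N(0, I)``.  Observed features are noisy linear mixtures of the latent
state; minority-group members are additionally shifted down along the
score-index direction in latent space, scaled so that per-feature
standardized mean differences between the groups have root-mean-square
magnitude ≈ ``group_shift`` with feature-dependent sign.  The mental-health score is a positive linear index
of the *group-centered* latent state (a value at a given within-group
percentile means the same thing in either group), minus a negative-legacy
offset ``LEGACY_SCALE * legacy_strength`` for the minority, plus Gaussian
noise.  With ``legacy_strength = 0`` the score — and hence a median-split
label — is independent of group even when feature distributions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError, SchemaError

N_LATENT = 5
#: SD of feature-specific noise on top of the latent mixtures. Small, so the
#: top-5 principal components of the default cohort explain >99% of variance.
FEATURE_NOISE_SD = 0.1
#: Score offset per unit of legacy_strength, in units of the score index SD.
LEGACY_SCALE = 0.2

PRIVILEGED = "male"
MINORITY = "female"


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation parameters.

    Defaults mirror the emulated study cohort: 55 participants, 38% women.
    """

    n_participants: int = 55
    minority_fraction: float = 0.38
    n_features: int = 10
    group_shift: float = 0.6
    legacy_strength: float = 0.7
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 10:
            raise ConfigurationError("n_participants must be >= 10")
        if not 0.0 < self.minority_fraction < 1.0:
            raise ConfigurationError("minority_fraction must lie in (0, 1)")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0.0 <= self.legacy_strength <= 1.0:
            raise ConfigurationError("legacy_strength must lie in [0, 1]")
        if self.noise_sd < 0.0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.group_shift < 0.0:
            raise ConfigurationError("group_shift must be >= 0")


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort; a pure function of ``config`` (same config ⇒ identical
    table). The returned cohort carries the continuous score only; call
    :func:`median_split_label` to attach binary labels."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_participants, config.n_features

    minority = rng.random(n) < config.minority_fraction

    # Mixing matrix (latent -> features), unit-norm columns; score coefficients
    # positive so the score is monotone in every latent factor.
    W = rng.normal(size=(N_LATENT, k))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    beta = np.abs(rng.normal(size=N_LATENT))
    beta /= np.linalg.norm(beta)

    z = rng.normal(size=(n, N_LATENT))
    # Minority shift along the score-index direction, scaled so per-feature
    # standardized mean differences have RMS = group_shift. Gendered usage
    # differences lie along the same behavioral axis that predicts the score:
    # a pooled threshold then systematically misreads the minority group.
    shift_vec = config.group_shift * np.sqrt(N_LATENT) * beta
    z_obs = z - shift_vec * minority[:, None]

    X = z_obs @ W + FEATURE_NOISE_SD * rng.normal(size=(n, k))

    index = z @ beta  # group-centered: percentile within one's own group
    score = (
        index
        - LEGACY_SCALE * config.legacy_strength * minority
        + config.noise_sd * rng.normal(size=n)
    )

    df = pd.DataFrame({"id": [f"P{i + 1:03d}" for i in range(n)]})
    df["group"] = np.where(minority, MINORITY, PRIVILEGED)
    for j in range(k):
        df[f"feat_{j + 1}"] = X[:, j]
    df["score"] = score
    return Cohort(df, privileged=PRIVILEGED)


def median_split_label(cohort: Cohort, center: str = "median") -> Cohort:
    """Dichotomize the continuous score at the cohort center.

    label = 1 iff score > center(scores); scores equal to the center get 0
    (deterministic tie rule). ``center`` is "median" (default) or "mean".
    """
    scores = cohort.scores
    bad = ~np.isfinite(scores)
    if bad.any():
        ids = list(cohort.ids[bad])
        raise SchemaError(f"missing or non-finite scores for ids: {ids}")
    if center == "median":
        cutoff = float(np.median(scores))
    elif center == "mean":
        cutoff = float(np.mean(scores))
    else:
        raise ConfigurationError("center must be 'median' or 'mean'")
    return cohort.with_labels((scores > cutoff).astype(int))


def inject_missingness(cohort: Cohort, rate: float, seed: int) -> Cohort:
    """Set each feature cell missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("rate must lie in [0, 1)")
    if rate == 0.0:
        return Cohort(cohort.data.copy(), cohort.privileged)
    rng = np.random.default_rng(seed)
    X = cohort.features
    mask = rng.random(X.shape) < rate
    X = X.copy()
    X[mask] = np.nan
    return cohort.with_features(X)


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Convenience: a no-bias configuration (no shift, no legacy)."""
    return replace(
        SyntheticConfig(seed=seed), group_shift=0.0, legacy_strength=0.0, **overrides
    )
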