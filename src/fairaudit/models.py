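"""The five classifier families behind a uniform fit/predict contract.

Families: logistic regression, support-vector machine (RBF kernel), random
forest (100 trees, max depth 6), k-nearest neighbors, and a multilayer
perceptron. Hyperparameters beyond the random-forest pair are the
implementing library's defaults, frozen here so runs are reproducible; the
audit's subject is group disparity, not tuning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

FAMILIES = ("logistic_regression", "svm", "random_forest", "knn", "mlp")

#: Frozen per-family defaults (merged under user hyperparameters).
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "logistic_regression": {"max_iter": 1000},
    "svm": {"kernel": "rbf"},
    "random_forest": {"n_estimators": 100, "max_depth": 6},
    "knn": {"n_neighbors": 5},
    "mlp": {"hidden_layer_sizes": (100,), "max_iter": 1500},
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown classifier family {self.family!r}; choose from {FAMILIES}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def make_classifier(spec: ClassifierSpec):
    """Instantiate an (unfitted) estimator for a spec."""
    params = spec.resolved_hyperparameters()
    if spec.family == "logistic_regression":
        return LogisticRegression(random_state=spec.seed, **params)
    if spec.family == "svm":
        return SVC(random_state=spec.seed, **params)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.family == "knn":
        return KNeighborsClassifier(**params)
    if spec.family == "mlp":
        return MLPClassifier(random_state=spec.seed, **params)
    raise ConfigurationError(f"unknown classifier family {spec.family!r}")


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit a classifier; deterministic given ``spec.seed``.

    Convergence warnings (MLP/logistic) are logged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = make_classifier(spec)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.debug("convergence warning for %s: %s", spec.family, w.message)
    return model


def predict(model, X: np.ndarray) -> np.ndarray:
    """One 0/1 label per row; empty input gives an empty vector."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({n_expected})"
        )
    return np.asarray(model.predict(X), dtype=int)
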