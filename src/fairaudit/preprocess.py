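"""Preprocessing chain: median imputation, standardization, SMOTE, PCA.

Everything is fitted on training data only and applied unchanged to held-out
data; SMOTE balances the training classes while test folds keep their
original class ratio. The default pipeline order is
impute → standardize → SMOTE → PCA (the PCA is fitted on the SMOTE-balanced
standardized training matrix); set ``smote_before_pca=False`` to fit the PCA
on the unbalanced training matrix instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .cohort import Cohort
from .errors import PreprocessingError, SmoteError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    smote_k: int = 5
    n_components: int = 5
    variance_target: float = 0.99
    smote_before_pca: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise PreprocessingError("smote_k must be >= 1")
        if self.n_components < 1:
            raise PreprocessingError("n_components must be >= 1")
        if not 0.0 < self.variance_target <= 1.0:
            raise PreprocessingError("variance_target must lie in (0, 1]")


@dataclass
class FittedTransform:
    """Train-fitted imputation/standardization/PCA parameters."""

    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray               # (r, k), orthonormal rows
    explained_variance_ratio: np.ndarray  # (r,), nonincreasing

    @property
    def n_features(self) -> int:
        return len(self.medians)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """impute → standardize → project, with train-fitted parameters only."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise PreprocessingError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty((0, self.n_components))
        X = np.where(np.isnan(X), self.medians, X)
        Z = (X - self.means) / self.sds
        return Z @ self.components.T

    def standardize(self, X: np.ndarray) -> np.ndarray:
        """impute → standardize only (no projection)."""
        X = np.asarray(X, dtype=float)
        X = np.where(np.isnan(X), self.medians, X)
        return (X - self.means) / self.sds


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, Cohort):
        return table.features
    return np.asarray(table, dtype=float)


def fit_imputer_scaler_pca(
    train, config: PreprocessConfig | None = None, labels=None
) -> FittedTransform:
    """Fit the preprocessing chain on a training table.

    ``train`` is a :class:`Cohort` or a raw (n, k) matrix. If labels are
    available (cohort with labels, or the ``labels`` argument) and
    ``config.smote_before_pca`` is set, the PCA is fitted on the
    SMOTE-balanced standardized matrix; imputation and scaling statistics are
    always computed on the original training rows.
    """
    config = config or PreprocessConfig()
    X = _as_matrix(train)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise PreprocessingError("train must have >= 2 rows and >= 1 feature")
    if labels is None and isinstance(train, Cohort) and train.has_labels:
        labels = train.labels

    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        idx = int(np.argmax(all_missing))
        name = (
            train.feature_cols[idx] if isinstance(train, Cohort) else f"column {idx}"
        )
        raise PreprocessingError(f"feature {name!r} has no observed values")

    medians = np.nanmedian(X, axis=0)
    Xi = np.where(np.isnan(X), medians, X)
    means = Xi.mean(axis=0)
    sds = Xi.std(axis=0)
    zero_var = sds == 0.0
    if zero_var.any():
        logger.warning(
            "zero-variance feature(s) at columns %s; using scale 1",
            np.flatnonzero(zero_var).tolist(),
        )
        sds = np.where(zero_var, 1.0, sds)
    Z = (Xi - means) / sds

    Z_fit = Z
    if config.smote_before_pca and labels is not None:
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) == 2:
            Z_fit, _ = smote_oversample(Z, y, k=config.smote_k, seed=config.seed)

    pca = PCA(svd_solver="full").fit(Z_fit)
    evr = pca.explained_variance_ratio_
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if rank >= config.n_components:
        r = config.n_components
    else:
        # rank-deficient fallback: smallest count reaching the variance target
        cum = np.cumsum(evr)
        r = int(np.searchsorted(cum, config.variance_target) + 1)
        r = min(r, len(evr))
    return FittedTransform(
        medians=medians,
        means=means,
        sds=sds,
        components=pca.components_[:r],
        explained_variance_ratio=evr[:r],
    )


def apply_transform(t: FittedTransform, table) -> np.ndarray:
    """Project a table into the train-fitted component space (no refitting)."""
    return t.transform(_as_matrix(table))


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority-class oversampling.

    Balances the two classes by adding synthetic minority points drawn
    uniformly on segments between a minority point and one of its ``k``
    nearest minority neighbors. Original rows are preserved unchanged (they
    form the prefix of the output). If the minority class has ``m <= k``
    members, ``k`` is reduced to ``m - 1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise SmoteError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SmoteError("SMOTE requires two classes in y")
    if len(classes) > 2:
        raise SmoteError("SMOTE supports binary labels only")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()

    minority_class = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise SmoteError("minority class needs >= 2 members to form neighbor pairs")
    k_eff = min(k, n_min - 1)

    X_min = X[y == minority_class]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    # column 0 is the point itself
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.random(size=n_new)
    x0 = X_min[base]
    x1 = X_min[neighbor_idx[base, pick]]
    synthetic = x0 + u[:, None] * (x1 - x0)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority_class, dtype=int)])
    return X_out, y_out
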