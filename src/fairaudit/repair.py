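"""Disparate impact remover: per-group quantile alignment with partial repair.

Each feature is repaired group-by-group: a value at within-group percentile
``p`` is moved toward the *target* quantile function — the median (with two
groups, the midpoint) of the per-group empirical quantile curves — evaluated
at the same ``p``. The repair amount λ interpolates between the original
value (λ=0) and full alignment (λ=1):

    x  ↦  (1 − λ) · x + λ · q̄(F_g(x))

``F_g`` is the group's interpolated empirical CDF from the fitting data
(sorted fit values mapped onto plotting positions 0, 1/(m−1), …, 1), and
``q̄`` is the target curve, stored on a fixed quantile grid with linear
interpolation. Values outside a group's fitted range clamp to the 0th/100th
percentile. The map is nondecreasing in x, so within-group feature ranks are
preserved for every λ; at λ=1 the group distributions coincide up to grid
resolution. Labels, scores and the protected attribute are never touched,
and downstream classifiers need no modification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .errors import RepairError

DEFAULT_GRID_POINTS = 101


@dataclass
class RepairModel:
    """Per-feature, per-group quantile maps plus the median target curve."""

    feature_names: list[str]
    group_levels: list[str]
    privileged: str
    lam: float
    grid: np.ndarray                          # (g,) quantile grid in [0, 1]
    group_values: dict[str, list[np.ndarray]]  # level -> per-feature sorted fit values
    target: np.ndarray = field(repr=False)     # (n_features, g) target quantiles

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "group_levels": self.group_levels,
            "privileged": self.privileged,
            "lam": self.lam,
            "grid": self.grid.tolist(),
            "group_values": {
                g: [v.tolist() for v in vals] for g, vals in self.group_values.items()
            },
            "target": self.target.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RepairModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            group_levels=d["group_levels"],
            privileged=d["privileged"],
            lam=d["lam"],
            grid=np.asarray(d["grid"], dtype=float),
            group_values={
                g: [np.asarray(v, dtype=float) for v in vals]
                for g, vals in d["group_values"].items()
            },
            target=np.asarray(d["target"], dtype=float),
        )


def fit_repair_arrays(
    X: np.ndarray,
    groups: np.ndarray,
    lam: float = 1.0,
    n_grid: int = DEFAULT_GRID_POINTS,
    feature_names: list[str] | None = None,
    privileged: str = "",
) -> RepairModel:
    """Array-level fitting core (used directly by the audit harness)."""
    if not 0.0 <= lam <= 1.0:
        raise RepairError("lambda must lie in [0, 1]")
    if n_grid < 2:
        raise RepairError("quantile grid needs >= 2 points")
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(np.unique(groups).tolist())
    if len(levels) != 2:
        raise RepairError(f"repair needs exactly two groups, found {levels}")
    for level in levels:
        if int(np.sum(groups == level)) < 2:
            raise RepairError(f"group {level!r} has fewer than 2 members")
    if np.isnan(X).any():
        raise RepairError("repair requires complete features; impute first")
    if feature_names is None:
        feature_names = [f"feat_{j + 1}" for j in range(X.shape[1])]

    grid = np.linspace(0.0, 1.0, n_grid)
    group_values: dict[str, list[np.ndarray]] = {str(level): [] for level in levels}
    curves = np.empty((2, X.shape[1], n_grid))
    for gi, level in enumerate(levels):
        vals = X[groups == level]
        for f in range(vals.shape[1]):
            sorted_vals = np.sort(vals[:, f])
            group_values[str(level)].append(sorted_vals)
            curves[gi, f] = np.quantile(sorted_vals, grid)
    # median across groups; with two groups this is the midpoint
    target = np.median(curves, axis=0)

    return RepairModel(
        feature_names=list(feature_names),
        group_levels=[str(level) for level in levels],
        privileged=privileged,
        lam=lam,
        grid=grid,
        group_values=group_values,
        target=target,
    )


def fit_repair(
    train: Cohort, lam: float = 1.0, n_grid: int = DEFAULT_GRID_POINTS
) -> RepairModel:
    """Fit per-group quantile maps and the cross-group median target curve.

    Both groups must be present with at least 2 members each.
    """
    return fit_repair_arrays(
        train.features,
        train.groups,
        lam=lam,
        n_grid=n_grid,
        feature_names=list(train.feature_cols),
        privileged=train.privileged,
    )


def _ecdf(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Interpolated empirical CDF at plotting positions; clamps out of range."""
    m = len(sorted_vals)
    positions = np.linspace(0.0, 1.0, m)
    return np.interp(x, sorted_vals, positions)


def apply_repair_arrays(
    model: RepairModel, X: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Array-level application core; returns the repaired feature matrix."""
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups).astype(str)
    unseen = set(np.unique(groups)) - set(model.group_levels)
    if unseen:
        raise RepairError(f"unseen group level(s): {sorted(unseen)}")
    repaired = X.copy()
    if model.lam == 0.0:
        return repaired
    for level in model.group_levels:
        mask = groups == level
        if not mask.any():
            continue
        for f in range(model.n_features):
            p = _ecdf(model.group_values[level][f], X[mask, f])
            aligned = np.interp(p, model.grid, model.target[f])
            repaired[mask, f] = (1.0 - model.lam) * X[mask, f] + model.lam * aligned
    return repaired


def apply_repair(model: RepairModel, table: Cohort) -> Cohort:
    """Repair every feature of ``table`` with the fitted quantile maps."""
    if list(table.feature_cols) != model.feature_names:
        raise RepairError(
            f"feature columns {table.feature_cols} do not match the fitted "
            f"model {model.feature_names}"
        )
    if model.lam == 0.0:
        # still validates group levels, then returns a bit-identical copy
        apply_repair_arrays(model, table.features, table.groups)
        return Cohort(table.data.copy(), table.privileged)
    return table.with_features(apply_repair_arrays(model, table.features, table.groups))


def repair_pipeline_hook(
    train: Cohort, test: Cohort, lam: float
) -> tuple[Cohort, Cohort]:
    """Fit the repair on the training table only and apply it to both tables.

    The downstream classifier is untouched (preprocessing-only mitigation);
    test values outside a group's training range clamp to the extreme
    quantiles.
    """
    model = fit_repair(train, lam)
    repaired_train = apply_repair(model, train)
    repaired_test = (
        Cohort(test.data.copy(), test.privileged)
        if test.n == 0
        else apply_repair(model, test)
    )
    return repaired_train, repaired_test
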