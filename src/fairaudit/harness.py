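"""Repeated cross-validated audit harness.

One *iteration* = a reshuffled stratified k-fold cross-validation of the
cohort. Within each training fold, and strictly inside it, the pipeline
optionally fits and applies the disparate-impact repair, then fits the
imputer/scaler/PCA, balances the classes with SMOTE, and trains the
classifier; the held-out fold is transformed with train-fitted parameters
only and keeps its original class ratio. Out-of-fold predictions are pooled
across folds and scored with the full fairness report. An *audit* repeats
this for ``n_iterations`` reseeded iterations and aggregates means, SDs and
significance tests.

Two t tests are reported for the group-accuracy comparison:

* ``t_test_iterations`` — Welch t on the per-iteration privileged vs
  unprivileged accuracy vectors. This mirrors common practice in audit
  reports, but iterations of a single cohort are not independent replicates,
  so its p-values overstate evidence against the null.
* ``t_test_participants`` — Welch t comparing per-participant mean
  out-of-fold correctness between the two groups. Participants are the
  independent units, so this test holds its nominal size on unbiased
  cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import sklearn
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .errors import (
    DegenerateSampleError,
    HarnessError,
    RepairError,
    SmoteError,
    UndefinedMetricError,
)
from .metrics import FairnessReport, confusion_by_group, t_test_two_tailed
from .models import ClassifierSpec, predict, train
from .preprocess import PreprocessConfig, fit_imputer_scaler_pca, smote_oversample
from .repair import apply_repair_arrays, fit_repair_arrays

#: Metric keys aggregated across iterations.
METRIC_KEYS = (
    "delta_accuracy",
    "delta_tpr",
    "delta_fpr",
    "spd",
    "disparate_impact",
    "ber",
)
ACCURACY_KEYS = ("accuracy_overall", "accuracy_priv", "accuracy_unpriv")
ALL_KEYS = METRIC_KEYS + ACCURACY_KEYS + ("delta_accuracy_abs",)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class HarnessConfig:
    n_folds: int = 5
    n_iterations: int = 100
    model: ClassifierSpec = field(default_factory=ClassifierSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    repair_lambda: float | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise HarnessError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise HarnessError("n_iterations must be >= 1")
        if self.repair_lambda is not None and not 0.0 <= self.repair_lambda <= 1.0:
            raise HarnessError("repair_lambda must lie in [0, 1]")


@dataclass
class IterationResult:
    """One shuffled-CV run: pooled out-of-fold predictions and their report."""

    index: int
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None
    is_privileged: np.ndarray | None = None
    report: FairnessReport | None = None
    skipped: bool = False
    reason: str | None = None

    @property
    def correct(self) -> np.ndarray:
        return (self.y_true == self.y_pred).astype(float)


@dataclass
class AuditSummary:
    """Aggregates of one audit: per-metric means/SDs, retained per-iteration
    vectors, significance tests and a run manifest."""

    model_family: str
    n_folds: int
    n_iterations: int
    n_skipped: int
    repair_lambda: float | None
    vectors: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    t_test_iterations: tuple[float, float] | None
    t_test_participants: tuple[float, float] | None
    skip_reasons: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def n_effective(self) -> int:
        return self.n_iterations - self.n_skipped

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_family": self.model_family,
            "n_folds": self.n_folds,
            "n_iterations": self.n_iterations,
            "n_skipped": self.n_skipped,
            "repair_lambda": self.repair_lambda,
            "vectors": {k: np.asarray(v).tolist() for k, v in self.vectors.items()},
            "means": self.means,
            "sds": self.sds,
            "t_test_iterations": self.t_test_iterations,
            "t_test_participants": self.t_test_participants,
            "skip_reasons": self.skip_reasons,
            "manifest": self.manifest,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AuditSummary":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            model_family=d["model_family"],
            n_folds=d["n_folds"],
            n_iterations=d["n_iterations"],
            n_skipped=d["n_skipped"],
            repair_lambda=d["repair_lambda"],
            vectors={k: np.asarray(v, dtype=float) for k, v in d["vectors"].items()},
            means=d["means"],
            sds=d["sds"],
            t_test_iterations=(
                tuple(d["t_test_iterations"]) if d["t_test_iterations"] else None
            ),
            t_test_participants=(
                tuple(d["t_test_participants"]) if d["t_test_participants"] else None
            ),
            skip_reasons=d.get("skip_reasons", []),
            manifest=d.get("manifest", {}),
        )


def _stratification_labels(y: np.ndarray, priv: np.ndarray, n_folds: int) -> np.ndarray:
    """Stratify on the joint (label x group) cell when every nonempty cell has
    at least ``n_folds`` members, else fall back to the label alone."""
    joint = y * 2 + priv.astype(int)
    counts = np.bincount(joint, minlength=4)
    if counts[counts > 0].min() >= n_folds:
        return joint
    return y


def _run_iteration_arrays(
    X: np.ndarray,
    y: np.ndarray,
    priv: np.ndarray,
    config: HarnessConfig,
    iteration: int,
) -> IterationResult:
    seed = (config.base_seed + iteration) % _SEED_MOD
    n = len(y)
    preds = np.full(n, -1, dtype=int)
    groups_str = np.where(priv, "priv", "unpriv")

    try:
        strat = _stratification_labels(y, priv, config.n_folds)
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=seed
        )
        for fold, (tr, te) in enumerate(skf.split(X, strat)):
            fold_seed = (seed * 131 + fold) % _SEED_MOD
            X_tr, y_tr = X[tr], y[tr]
            X_te = X[te]
            if config.repair_lambda is not None and np.isnan(X_tr).any():
                # repair needs complete features; impute with train-fold medians
                med = np.nanmedian(X_tr, axis=0)
                X_tr = np.where(np.isnan(X_tr), med, X_tr)
                X_te = np.where(np.isnan(X_te), med, X_te)
            if config.repair_lambda is not None:
                rmodel = fit_repair_arrays(
                    X_tr, groups_str[tr], lam=config.repair_lambda
                )
                X_te = apply_repair_arrays(rmodel, X_te, groups_str[te])
                X_tr = apply_repair_arrays(rmodel, X_tr, groups_str[tr])
            pp = replace(config.preprocess, seed=fold_seed)
            transform = fit_imputer_scaler_pca(X_tr, pp, labels=y_tr)
            Z_tr = transform.standardize(X_tr)
            Zb, yb = smote_oversample(Z_tr, y_tr, k=pp.smote_k, seed=fold_seed)
            model = train(
                replace(config.model, seed=fold_seed),
                Zb @ transform.components.T,
                yb,
            )
            preds[te] = predict(model, transform.transform(X_te))
        report = FairnessReport.from_confusion(
            confusion_by_group(y, preds, priv, privileged=True)
        )
    except (SmoteError, RepairError, UndefinedMetricError, ValueError) as exc:
        return IterationResult(index=iteration, skipped=True, reason=str(exc))

    return IterationResult(
        index=iteration,
        y_true=y.copy(),
        y_pred=preds,
        is_privileged=priv.copy(),
        report=report,
    )


def run_iteration(
    cohort: Cohort, config: HarnessConfig, iteration: int
) -> IterationResult:
    """Run one shuffled stratified-CV evaluation of the cohort."""
    return _run_iteration_arrays(
        cohort.features, cohort.labels, cohort.is_privileged, config, iteration
    )


def run_audit(cohort: Cohort, config: HarnessConfig) -> AuditSummary:
    """Run ``config.n_iterations`` reseeded iterations and aggregate."""
    X, y, priv = cohort.features, cohort.labels, cohort.is_privileged
    results = [
        _run_iteration_arrays(X, y, priv, config, i)
        for i in range(config.n_iterations)
    ]
    active = [r for r in results if not r.skipped]
    n_skipped = config.n_iterations - len(active)
    if n_skipped > config.n_iterations / 2:
        reasons = sorted({r.reason for r in results if r.skipped})
        raise HarnessError(
            f"{n_skipped}/{config.n_iterations} iterations skipped; reasons: {reasons}"
        )

    vectors: dict[str, np.ndarray] = {}
    for key in METRIC_KEYS + ACCURACY_KEYS:
        vectors[key] = np.array([getattr(r.report, key) for r in active])
    vectors["delta_accuracy_abs"] = np.abs(vectors["delta_accuracy"])
    means = {k: float(np.mean(v)) for k, v in vectors.items()}
    sds = {k: float(np.std(v)) for k, v in vectors.items()}

    def _safe_t(a, b):
        try:
            return t_test_two_tailed(a, b)
        except DegenerateSampleError:
            return None

    t_iter = (
        _safe_t(vectors["accuracy_priv"], vectors["accuracy_unpriv"])
        if len(active) >= 2
        else None
    )
    mean_correct = np.mean([r.correct for r in active], axis=0)
    t_part = _safe_t(mean_correct[priv], mean_correct[~priv])

    manifest = {
        "config": {
            "n_folds": config.n_folds,
            "n_iterations": config.n_iterations,
            "base_seed": config.base_seed,
            "repair_lambda": config.repair_lambda,
            "model": {
                "family": config.model.family,
                "hyperparameters": config.model.resolved_hyperparameters(),
                "seed": config.model.seed,
            },
            "preprocess": {
                "smote_k": config.preprocess.smote_k,
                "n_components": config.preprocess.n_components,
                "variance_target": config.preprocess.variance_target,
                "smote_before_pca": config.preprocess.smote_before_pca,
            },
        },
        "versions": {"numpy": np.__version__, "scikit-learn": sklearn.__version__},
        "n_participants": int(len(y)),
    }

    return AuditSummary(
        model_family=config.model.family,
        n_folds=config.n_folds,
        n_iterations=config.n_iterations,
        n_skipped=n_skipped,
        repair_lambda=config.repair_lambda,
        vectors=vectors,
        means=means,
        sds=sds,
        t_test_iterations=t_iter,
        t_test_participants=t_part,
        skip_reasons=[r.reason for r in results if r.skipped],
        manifest=manifest,
    )


@dataclass
class Comparison:
    """Before/after-repair comparison in the shape of a results table."""

    table: "object"  # pandas.DataFrame, 6 metric rows
    accuracy_before: float
    accuracy_after: float
    accuracy_cost: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def compare_before_after(baseline: AuditSummary, repaired: AuditSummary) -> Comparison:
    """Per-metric before/after means, SDs, absolute difference and a Welch t
    test on the per-iteration vectors, plus the overall-accuracy cost."""
    import pandas as pd

    if baseline.n_iterations != repaired.n_iterations:
        raise HarnessError(
            "mismatched iteration counts: "
            f"{baseline.n_iterations} vs {repaired.n_iterations}"
        )
    rows = []
    for key in METRIC_KEYS:
        a, b = baseline.vectors[key], repaired.vectors[key]
        if len(a) == len(b) and np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = t_test_two_tailed(a, b)
        rows.append(
            {
                "metric": key,
                "before_mean": baseline.means[key],
                "before_sd": baseline.sds[key],
                "after_mean": repaired.means[key],
                "after_sd": repaired.sds[key],
                "difference": abs(baseline.means[key] - repaired.means[key]),
                "t_stat": t,
                "p_value": p,
            }
        )
    acc_b = baseline.means["accuracy_overall"]
    acc_a = repaired.means["accuracy_overall"]
    return Comparison(
        table=pd.DataFrame(rows),
        accuracy_before=acc_b,
        accuracy_after=acc_a,
        accuracy_cost=acc_b - acc_a,
    )
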