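"""Group-fairness metrics on a per-group confusion matrix.

All metrics operate on a :class:`GroupedConfusion` — TP/FP/TN/FN counts split
by the binary protected attribute (privileged vs unprivileged group). The
five audit metrics are delta accuracy, ΔTPR (equal opportunity), ΔFPR,
statistical parity difference (SPD) and disparate impact (DI), reported with
the convention that positive differences favour the privileged group. The
balanced error rate (BER) is the unweighted mean of the two group error
rates, so a model that sacrifices a small group for overall accuracy is
penalized: 90 privileged rows all right plus 10 unprivileged rows all wrong
gives overall error 0.1 but BER (0+1)/2 = 0.5.

Zero denominators raise :class:`~fairaudit.errors.UndefinedMetricError`
rather than returning NaN, so the harness can count skipped iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, UndefinedMetricError

#: Conventional (four-fifths rule) disparate-impact threshold below which a
#: model is flagged as biased.
DI_BIAS_THRESHOLD = 0.8


@dataclass(frozen=True)
class GroupedConfusion:
    """Per-protected-group confusion counts."""

    tp_priv: int = 0
    fp_priv: int = 0
    tn_priv: int = 0
    fn_priv: int = 0
    tp_unpriv: int = 0
    fp_unpriv: int = 0
    tn_unpriv: int = 0
    fn_unpriv: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in asdict(self).values()):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_priv(self) -> int:
        return self.tp_priv + self.fp_priv + self.tn_priv + self.fn_priv

    @property
    def n_unpriv(self) -> int:
        return self.tp_unpriv + self.fp_unpriv + self.tn_unpriv + self.fn_unpriv

    @property
    def n(self) -> int:
        return self.n_priv + self.n_unpriv

    def swapped(self) -> "GroupedConfusion":
        """Counts with the two group roles exchanged."""
        return GroupedConfusion(
            tp_priv=self.tp_unpriv,
            fp_priv=self.fp_unpriv,
            tn_priv=self.tn_unpriv,
            fn_priv=self.fn_unpriv,
            tp_unpriv=self.tp_priv,
            fp_unpriv=self.fp_priv,
            tn_unpriv=self.tn_priv,
            fn_unpriv=self.fn_priv,
        )


def confusion_by_group(y_true, y_pred, group, privileged) -> GroupedConfusion:
    """Tally TP/FP/TN/FN separately for each protected group.

    ``group`` must take at most two levels; ``privileged`` names the
    privileged level (the other level, if present, is the unprivileged one).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    group = np.asarray(group)
    if not (len(y_true) == len(y_pred) == len(group)):
        raise ValueError(
            f"length mismatch: y_true {len(y_true)}, y_pred {len(y_pred)}, "
            f"group {len(group)}"
        )
    levels = np.unique(group)
    if len(levels) > 2:
        raise ValueError(f"group must be binary, found levels {list(levels)}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")

    counts = {}
    for role, mask in (("priv", group == privileged), ("unpriv", group != privileged)):
        t, p = y_true[mask], y_pred[mask]
        counts[f"tp_{role}"] = int(np.sum((t == 1) & (p == 1)))
        counts[f"fp_{role}"] = int(np.sum((t == 0) & (p == 1)))
        counts[f"tn_{role}"] = int(np.sum((t == 0) & (p == 0)))
        counts[f"fn_{role}"] = int(np.sum((t == 1) & (p == 0)))
    return GroupedConfusion(**counts)


def _require_nonempty(c: GroupedConfusion) -> None:
    if c.n_priv == 0:
        raise UndefinedMetricError("privileged group is empty")
    if c.n_unpriv == 0:
        raise UndefinedMetricError("unprivileged group is empty")


def group_accuracies(c: GroupedConfusion) -> tuple[float, float]:
    """(privileged, unprivileged) accuracy as proportions."""
    _require_nonempty(c)
    acc_p = (c.tp_priv + c.tn_priv) / c.n_priv
    acc_u = (c.tp_unpriv + c.tn_unpriv) / c.n_unpriv
    return acc_p, acc_u


def overall_accuracy(c: GroupedConfusion) -> float:
    if c.n == 0:
        raise UndefinedMetricError("empty confusion")
    return (c.tp_priv + c.tn_priv + c.tp_unpriv + c.tn_unpriv) / c.n


def delta_accuracy(c: GroupedConfusion) -> float:
    """acc(privileged) − acc(unprivileged), in percentage points."""
    acc_p, acc_u = group_accuracies(c)
    return 100.0 * (acc_p - acc_u)


def delta_tpr(c: GroupedConfusion) -> float:
    """TPR(privileged) − TPR(unprivileged), percentage points (equal opportunity)."""
    pos_p = c.tp_priv + c.fn_priv
    pos_u = c.tp_unpriv + c.fn_unpriv
    if pos_p == 0:
        raise UndefinedMetricError("no positives in privileged group: TPR undefined")
    if pos_u == 0:
        raise UndefinedMetricError("no positives in unprivileged group: TPR undefined")
    return 100.0 * (c.tp_priv / pos_p - c.tp_unpriv / pos_u)


def delta_fpr(c: GroupedConfusion) -> float:
    """FPR(privileged) − FPR(unprivileged), percentage points."""
    neg_p = c.fp_priv + c.tn_priv
    neg_u = c.fp_unpriv + c.tn_unpriv
    if neg_p == 0:
        raise UndefinedMetricError("no negatives in privileged group: FPR undefined")
    if neg_u == 0:
        raise UndefinedMetricError("no negatives in unprivileged group: FPR undefined")
    return 100.0 * (c.fp_priv / neg_p - c.fp_unpriv / neg_u)


def _positive_rates(c: GroupedConfusion) -> tuple[float, float]:
    _require_nonempty(c)
    rate_p = (c.tp_priv + c.fp_priv) / c.n_priv
    rate_u = (c.tp_unpriv + c.fp_unpriv) / c.n_unpriv
    return rate_p, rate_u


def statistical_parity_difference(c: GroupedConfusion, priv_minus_unpriv: bool = True) -> float:
    """Difference in favorable-outcome (positive-prediction) rates, in
    percentage points.

    Sign convention: by default P(ŷ=1 | privileged) − P(ŷ=1 | unprivileged),
    so positive values mean the model favours the privileged group; set
    ``priv_minus_unpriv=False`` to flip.
    """
    rate_p, rate_u = _positive_rates(c)
    diff = 100.0 * (rate_p - rate_u)
    return diff if priv_minus_unpriv else -diff


def disparate_impact(c: GroupedConfusion) -> float:
    """P(ŷ=1 | unprivileged) / P(ŷ=1 | privileged).

    Values below :data:`DI_BIAS_THRESHOLD` (0.8) are conventionally flagged
    as biased; use :func:`is_biased`.
    """
    rate_p, rate_u = _positive_rates(c)
    if rate_p == 0:
        raise UndefinedMetricError(
            "privileged positive-prediction rate is 0: disparate impact undefined"
        )
    return rate_u / rate_p


def is_biased(di: float, threshold: float = DI_BIAS_THRESHOLD) -> bool:
    return di < threshold


def balanced_error_rate(c: GroupedConfusion) -> float:
    """Unweighted mean of the two group error rates, in [0, 1]."""
    acc_p, acc_u = group_accuracies(c)
    return ((1.0 - acc_p) + (1.0 - acc_u)) / 2.0


def overall_error_rate(c: GroupedConfusion) -> float:
    """(all misclassifications) / n, in [0, 1]."""
    if c.n == 0:
        raise UndefinedMetricError("empty confusion")
    errors = c.fp_priv + c.fn_priv + c.fp_unpriv + c.fn_unpriv
    return errors / c.n


def t_test_two_tailed(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Nonpaired two-sample two-tailed t test (Welch by default).

    Identical samples return (0.0, 1.0). Samples with zero variance on both
    sides but different means are degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateSampleError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateSampleError("samples must be finite")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DegenerateSampleError("zero-variance samples with different means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class FairnessReport:
    """The five audit metrics plus BER and per-group accuracy for one
    evaluation (one set of pooled predictions)."""

    delta_accuracy: float
    delta_tpr: float
    delta_fpr: float
    spd: float
    disparate_impact: float
    ber: float
    accuracy_priv: float      # percent
    accuracy_unpriv: float    # percent
    accuracy_overall: float   # percent

    @property
    def di_biased(self) -> bool:
        return is_biased(self.disparate_impact)

    @classmethod
    def from_confusion(cls, c: GroupedConfusion) -> "FairnessReport":
        acc_p, acc_u = group_accuracies(c)
        return cls(
            delta_accuracy=delta_accuracy(c),
            delta_tpr=delta_tpr(c),
            delta_fpr=delta_fpr(c),
            spd=statistical_parity_difference(c),
            disparate_impact=disparate_impact(c),
            ber=balanced_error_rate(c),
            accuracy_priv=100.0 * acc_p,
            accuracy_unpriv=100.0 * acc_u,
            accuracy_overall=100.0 * overall_accuracy(c),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["di_biased"] = self.di_biased
        return d
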