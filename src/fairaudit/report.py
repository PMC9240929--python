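"""Render audit summaries as results tables and machine-readable artifacts.

Rendering is lossless with respect to :class:`~fairaudit.harness.AuditSummary`
fields: every number in a table is read from a summary field, never
recomputed. Percentages are formatted to 2 decimals, ratios to 3.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReportError
from .harness import METRIC_KEYS, AuditSummary

#: Ideal values: 0 for the four difference metrics and BER, 1.0 for DI.
IDEAL_SCORES = {
    "delta_accuracy": 0.0,
    "delta_tpr": 0.0,
    "delta_fpr": 0.0,
    "spd": 0.0,
    "disparate_impact": 1.0,
    "ber": 0.0,
}

METRIC_LABELS = {
    "delta_accuracy": "Delta accuracy (%)",
    "delta_tpr": "Delta true positive rate (%)",
    "delta_fpr": "Delta false positive rate (%)",
    "spd": "Statistical parity difference (%)",
    "disparate_impact": "Disparate impact",
    "ber": "Balanced error rate",
}


def _fmt(mean: float, sd: float, decimals: int) -> str:
    return f"{mean:.{decimals}f} ({sd:.{decimals}f})"


def _fmt_p(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "n/a"
    return "<.001" if p < 0.001 else f"{p:.3f}"


def render_model_grid(summaries: list[AuditSummary], raw: bool = False) -> pd.DataFrame:
    """Per-model accuracy grid: one row per classifier family.

    Columns: overall / privileged / unprivileged accuracy mean (SD), signed
    and absolute delta accuracy mean (SD), and the iteration-level t-test p.
    With ``raw=True`` numeric means are returned instead of formatted strings.
    """
    if not summaries:
        raise ReportError("need at least one audit summary")
    families = [s.model_family for s in summaries]
    if len(set(families)) != len(families):
        raise ReportError(f"duplicate model families: {families}")
    rows = []
    for s in summaries:
        p = s.t_test_iterations[1] if s.t_test_iterations else None
        if raw:
            rows.append(
                {
                    "model": s.model_family,
                    "overall_accuracy": s.means["accuracy_overall"],
                    "accuracy_privileged": s.means["accuracy_priv"],
                    "accuracy_unprivileged": s.means["accuracy_unpriv"],
                    "delta_signed": s.means["delta_accuracy"],
                    "delta_abs": s.means["delta_accuracy_abs"],
                    "p_value": p,
                }
            )
        else:
            rows.append(
                {
                    "model": s.model_family,
                    "overall_accuracy": _fmt(
                        s.means["accuracy_overall"], s.sds["accuracy_overall"], 2
                    ),
                    "accuracy_privileged": _fmt(
                        s.means["accuracy_priv"], s.sds["accuracy_priv"], 2
                    ),
                    "accuracy_unprivileged": _fmt(
                        s.means["accuracy_unpriv"], s.sds["accuracy_unpriv"], 2
                    ),
                    "delta_signed": _fmt(
                        s.means["delta_accuracy"], s.sds["delta_accuracy"], 2
                    ),
                    "delta_abs": _fmt(
                        s.means["delta_accuracy_abs"], s.sds["delta_accuracy_abs"], 2
                    ),
                    "p_value": _fmt_p(p),
                }
            )
    return pd.DataFrame(rows).set_index("model")


def render_bias_table(summary: AuditSummary, raw: bool = False) -> pd.DataFrame:
    """Six bias-metric rows with observed mean (SD) and the ideal score."""
    rows = []
    for key in METRIC_KEYS:
        decimals = 3 if key in ("disparate_impact", "ber") else 2
        if raw:
            observed = summary.means[key]
        else:
            observed = _fmt(summary.means[key], summary.sds[key], decimals)
        rows.append(
            {
                "metric": METRIC_LABELS[key],
                "observed": observed,
                "ideal": IDEAL_SCORES[key],
            }
        )
    return pd.DataFrame(rows)


def write_report(summary: AuditSummary, outdir: str | Path, plots: bool = False) -> None:
    """Write the bias table as CSV and JSON (and optional distribution plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = render_bias_table(summary)
    table.to_csv(outdir / "bias_table.csv", index=False)
    raw = render_bias_table(summary, raw=True)
    (outdir / "bias_table.json").write_text(
        json.dumps(raw.to_dict(orient="records"), indent=2)
    )
    summary.to_json(outdir / "summary.json")
    if plots:
        plot_metric_distributions(summary, outdir / "metric_distributions.png")


def plot_metric_distributions(summary: AuditSummary, path: str | Path) -> None:
    """Histogram of each metric's per-iteration values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 6))
    for ax, key in zip(axes.ravel(), METRIC_KEYS):
        ax.hist(summary.vectors[key], bins=20, color="#4878a8")
        ax.axvline(IDEAL_SCORES[key], color="k", linestyle="--", linewidth=1)
        ax.set_title(METRIC_LABELS[key], fontsize=9)
    fig.suptitle(f"{summary.model_family}: metric distributions across iterations")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
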