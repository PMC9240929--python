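"""The cohort table: one row per participant.

Columns are ``id``, ``group`` (binary protected attribute with a designated
privileged level), ``feat_1..feat_k`` (real-valued phone-usage summaries,
possibly missing), ``score`` (continuous mental-health score) and, once
labelled, ``label`` (1 = high, 0 = low). Every pipeline stage consumes and
produces this shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

FEATURE_PREFIX = "feat_"


@dataclass
class Cohort:
    """A participant table plus the designated privileged group level.

    Parameters
    ----------
    data:
        DataFrame with columns ``id``, ``group``, ``feat_*``, ``score`` and
        optionally ``label``.
    privileged:
        The level of ``group`` treated as the privileged group.
    """

    data: pd.DataFrame
    privileged: str
    feature_cols: list[str] = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("id", "group", "score"):
            if col not in df.columns:
                raise SchemaError(f"cohort table is missing required column {col!r}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes}")
        levels = df["group"].unique()
        if len(levels) > 2:
            raise SchemaError(f"group must be binary, found levels {sorted(levels)}")
        if "label" in df.columns:
            lab = df["label"].dropna()
            if not lab.isin((0, 1)).all():
                raise SchemaError("label must be 0 or 1 when present")
        self.feature_cols = [c for c in df.columns if c.startswith(FEATURE_PREFIX)]

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def is_privileged(self) -> np.ndarray:
        return self.data["group"].to_numpy() == self.privileged

    @property
    def features(self) -> np.ndarray:
        """Feature matrix (n, k), missing cells as NaN."""
        return self.data[self.feature_cols].to_numpy(dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        if "label" not in self.data.columns:
            raise SchemaError("cohort has no label column; run median_split_label first")
        return self.data["label"].to_numpy(dtype=int)

    @property
    def has_labels(self) -> bool:
        return "label" in self.data.columns

    # -- functional updates ------------------------------------------------

    def subset(self, indices: np.ndarray) -> "Cohort":
        """Row subset by positional indices (order preserved)."""
        return Cohort(self.data.iloc[indices].reset_index(drop=True), self.privileged)

    def with_features(self, X: np.ndarray) -> "Cohort":
        """Copy of the cohort with the feature block replaced by ``X``."""
        if X.shape != (self.n, len(self.feature_cols)):
            raise SchemaError(
                f"feature block shape {X.shape} does not match cohort "
                f"({self.n}, {len(self.feature_cols)})"
            )
        df = self.data.copy()
        df[self.feature_cols] = X
        return Cohort(df, self.privileged)

    def with_labels(self, labels: np.ndarray) -> "Cohort":
        df = self.data.copy()
        df["label"] = np.asarray(labels, dtype=int)
        return Cohort(df, self.privileged)

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        """Write ``<path>`` plus a ``<path>.meta.json`` sidecar recording the
        privileged level. Missing cells are written empty."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = {"privileged": self.privileged, "feature_cols": self.feature_cols}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path, privileged: str | None = None) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        if privileged is None:
            sidecar = Path(str(path) + ".meta.json")
            if sidecar.exists():
                privileged = json.loads(sidecar.read_text())["privileged"]
            else:
                raise SchemaError(
                    "privileged level not given and no sidecar meta file found"
                )
        return cls(df, privileged)
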