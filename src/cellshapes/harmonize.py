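"""Cell-record tables: shape coefficients + scalar biology + condition.

A CellRecord row is the unit everything downstream (generation, outlier
detection, augmentation) consumes: flattened shape coefficients (84 for the
2-D body+nucleus schema, 726 for the 3-D schema), one scalar biological
feature (DOA in [0, 1] or monolayer height in um), and a one-hot condition
encoding in the final columns.  The numeric portion is z-scored feature-wise
(population standard deviation); one-hot columns pass through untouched, and
the stored statistics invert the transform exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "NormalizationStats",
    "assemble_table",
    "normalize",
    "denormalize",
    "write_table_csv",
    "read_table_csv",
]

SCHEMA_VERSION = 1


@dataclass
class NormalizationStats:
    """Per-feature mean/sd (ddof=0) plus the zero-variance exclusion list."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    excluded: dict[str, float] = field(default_factory=dict)  # name -> constant
    ddof: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "columns": self.columns,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "excluded": self.excluded,
            "ddof": self.ddof,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(columns=d["columns"], mean=np.asarray(d["mean"]),
                   sd=np.asarray(d["sd"]), excluded=d["excluded"],
                   ddof=d["ddof"])


@dataclass
class CellTable:
    """Harmonized table: numeric block then exactly-one-hot condition block."""

    frame: pd.DataFrame
    numeric_columns: list[str]
    onehot_columns: list[str]
    scalar_column: str | None = None  # e.g. "doa" or "height_um"

    def __post_init__(self) -> None:
        oh = self.frame[self.onehot_columns].to_numpy()
        if len(self.frame) and not np.array_equal(
                oh.sum(axis=1), np.ones(len(self.frame))):
            raise ValueError("each row must have exactly one 1 in the one-hot block")

    @property
    def numeric(self) -> np.ndarray:
        return self.frame[self.numeric_columns].to_numpy(dtype=float)

    @property
    def onehot(self) -> np.ndarray:
        return self.frame[self.onehot_columns].to_numpy(dtype=float)

    @property
    def conditions(self) -> pd.Series:
        idx = self.frame[self.onehot_columns].to_numpy().argmax(axis=1)
        names = [c.removeprefix("cond_") for c in self.onehot_columns]
        return pd.Series([names[i] for i in idx], index=self.frame.index,
                         name="condition")

    @property
    def width(self) -> int:
        return len(self.numeric_columns) + len(self.onehot_columns)


def assemble_table(
    shapes,
    scalars,
    conditions,
    cell_ids=None,
    scalar_name: str = "doa",
    category_names: tuple[str, ...] | None = None,
) -> CellTable:
    """Build the harmonized table from per-cell pieces.

    ``shapes`` is a sequence of flattened coefficient vectors (or objects with
    a ``flatten()`` method); all must share one length.  One-hot columns are
    appended last in the order of ``category_names`` (default: sorted unique
    labels).  Exactly two categories is the validated regime; more are
    accepted but flagged experimental.
    """
    shapes = list(shapes)
    scalars = list(scalars)
    conditions = [str(c) for c in conditions]
    if not (len(shapes) == len(scalars) == len(conditions)):
        raise ValueError("shapes, scalars and conditions must align")
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(len(shapes))]

    vectors = []
    width = None
    for cid, s in zip(cell_ids, shapes):
        vec = np.asarray(s.flatten() if hasattr(s, "flatten") and not
                         isinstance(s, np.ndarray) else s, dtype=float).ravel()
        if width is None:
            width = len(vec)
        elif len(vec) != width:
            raise ValueError(
                f"cell {cid}: coefficient length {len(vec)} != expected {width}")
        vectors.append(vec)

    if category_names is None:
        category_names = tuple(sorted(set(conditions)))
    if len(category_names) > 2:
        warnings.warn(
            f"{len(category_names)} one-hot categories; only 2 are the "
            "validated regime", stacklevel=2)
    unknown = set(conditions) - set(category_names)
    if unknown:
        raise ValueError(f"conditions {unknown} not in {category_names}")

    if width is None:  # empty input -> empty table with no columns
        width = 0
    coef_cols = [f"f{i}" for i in range(width)]
    numeric_cols = coef_cols + [scalar_name]
    onehot_cols = [f"cond_{c}" for c in category_names]
    data = {}
    mat = (np.vstack(vectors) if vectors
           else np.empty((0, width)))
    for j, col in enumerate(coef_cols):
        data[col] = mat[:, j]
    data[scalar_name] = np.asarray(scalars, dtype=float)
    for c, col in zip(category_names, onehot_cols):
        data[col] = np.array([1.0 if lab == c else 0.0 for lab in conditions])
    frame = pd.DataFrame(data, index=pd.Index(cell_ids, name="cell_id"))
    return CellTable(frame=frame, numeric_columns=numeric_cols,
                     onehot_columns=onehot_cols, scalar_column=scalar_name)


def normalize(table: CellTable) -> tuple[pd.DataFrame, NormalizationStats]:
    """Z-score the numeric block; one-hot columns pass through.

    Zero-variance numeric columns are dropped (their constant is recorded in
    the stats so denormalization restores them).  Returns the normalized
    frame (retained numeric columns + one-hot) and the statistics.
    """
    if len(table.frame) < 2:
        raise ValueError("need at least 2 records to normalize")
    X = table.frame[table.numeric_columns]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd <= 0
    excluded = {c: float(mean[c]) for c in X.columns[constant]}
    if excluded:
        warnings.warn(
            f"dropping zero-variance columns: {sorted(excluded)}", stacklevel=2)
    keep = [c for c in table.numeric_columns if c not in excluded]
    stats = NormalizationStats(
        columns=keep,
        mean=mean[keep].to_numpy(),
        sd=sd[keep].to_numpy(),
        excluded=excluded,
    )
    normed = (X[keep] - mean[keep]) / sd[keep]
    out = pd.concat([normed, table.frame[table.onehot_columns]], axis=1)
    return out, stats


def denormalize(matrix, stats: NormalizationStats,
                onehot_columns: list[str] | None = None) -> pd.DataFrame:
    """Invert ``normalize``; restores dropped constant columns.

    ``matrix`` may be a DataFrame (column names checked against the stats) or
    a bare array whose first ``len(stats.columns)`` columns are the retained
    numeric features followed by any one-hot columns.
    """
    k = len(stats.columns)
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns[:k])
        if cols != stats.columns:
            raise ValueError("column order does not match the stored statistics")
        numeric = matrix[stats.columns].to_numpy(dtype=float)
        extra = matrix.iloc[:, k:]
        index = matrix.index
    else:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] < k:
            raise ValueError(
                f"matrix width {matrix.shape[1]} < {k} retained features")
        numeric = matrix[:, :k]
        extra_cols = onehot_columns or [
            f"extra{i}" for i in range(matrix.shape[1] - k)]
        extra = pd.DataFrame(matrix[:, k:], columns=extra_cols)
        index = extra.index
    raw = numeric * stats.sd + stats.mean
    out = pd.DataFrame(raw, columns=stats.columns, index=index)
    for col, const in stats.excluded.items():
        out[col] = const
    for col in extra.columns:
        out[col] = np.asarray(extra[col])
    return out


# ---------------------------------------------------------------------------
# CSV round-trip with metadata header
# ---------------------------------------------------------------------------

def write_table_csv(path, table: CellTable) -> None:
    """CSV with a metadata comment line; floats at 17 significant digits."""
    meta = {
        "schema": SCHEMA_VERSION,
        "numeric_width": len(table.numeric_columns),
        "scalar": table.scalar_column or "",
        "categories": ",".join(
            c.removeprefix("cond_") for c in table.onehot_columns),
    }
    header = "# cellshapes-table " + " ".join(
        f"{k}={v}" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        table.frame.to_csv(fh, float_format="%.17g")


def read_table_csv(path) -> CellTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# cellshapes-table"):
            raise ValueError(
                "not a cellshapes table: missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in first.split()[2:])
        if int(meta["schema"]) != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {meta['schema']}; "
                f"this build reads version {SCHEMA_VERSION}")
        frame = pd.read_csv(fh, index_col="cell_id",
                            float_precision="round_trip")
    onehot = [f"cond_{c}" for c in meta["categories"].split(",")]
    numeric = [c for c in frame.columns if c not in onehot]
    return CellTable(frame=frame, numeric_columns=numeric,
                     onehot_columns=onehot,
                     scalar_column=meta["scalar"] or None)
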