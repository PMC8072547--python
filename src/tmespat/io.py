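"""Reading single-cell detection exports and writing result tables.

Input is the tab-delimited per-cell table produced by image-analysis
software (one row per detected cell, centroid coordinates in µm, a
free-text class string). Export schemas vary across tool versions, so the
column names and the mapping from class strings to the four study classes
are configurable through :class:`ColumnMap`; rows whose class string has no
mapping are dropped with a logged count.

Results (summary functions, confidence bands, divergence tables) are
written as plain tab-separated tables accompanied by a JSON metadata
sidecar (``<path>.meta.json``) recording the estimator provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import ConfidenceBand
from .grid import RGrid
from .interaction import DivergenceResult, classify_specimen
from .pattern import CellClass, PointPattern
from .summary import SummaryFunction
from .window import Window

__all__ = ["ColumnMap", "read_detections", "write_summary", "read_summary",
           "write_detections"]

logger = logging.getLogger(__name__)

#: class strings written by the package's own simulator export
DEFAULT_CLASS_DICTIONARY = {
    "CTL": CellClass.CTL,
    "Tumor: normoxic": CellClass.NORMOXIC_TUMOR,
    "Tumor: hypoxic": CellClass.HYPOXIC_TUMOR,
    "Stroma": CellClass.STROMA,
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from an export schema to the pattern data model."""

    x_column: str = "Centroid X µm"
    y_column: str = "Centroid Y µm"
    class_column: str = "Class"
    class_dictionary: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_DICTIONARY))

    def __post_init__(self):
        names = (self.x_column, self.y_column, self.class_column)
        if len(set(names)) != 3:
            raise ValueError("x, y and class column names must be distinct")
        for k, v in self.class_dictionary.items():
            if not isinstance(v, CellClass):
                object.__setattr__(
                    self,
                    "class_dictionary",
                    {kk: CellClass(vv) for kk, vv in self.class_dictionary.items()},
                )
                break

    @classmethod
    def default(cls) -> "ColumnMap":
        return cls()


def read_detections(path, cmap: ColumnMap | None = None, window: Window | str = "auto") -> PointPattern:
    """Read a tab-delimited detection export into a :class:`PointPattern`.

    ``window="auto"`` uses the bounding rectangle of the points expanded by
    1 µm on each side. Rows with unmapped class strings are dropped and
    counted; non-numeric coordinates are an error naming the row.
    """
    cmap = cmap if cmap is not None else ColumnMap.default()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (cmap.x_column, cmap.y_column, cmap.class_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    n_read = len(df)
    coords = {}
    for col in (cmap.x_column, cmap.y_column):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at data row {row} "
                f"(value {df[col].iloc[row]!r})"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"missing coordinate in column {col!r} at data row {row}")
        coords[col] = vals.to_numpy(dtype=float)

    mapped = df[cmap.class_column].map(
        {k: int(v) for k, v in cmap.class_dictionary.items()}
    )
    keep = mapped.notna().to_numpy()
    n_dropped = int(n_read - keep.sum())
    if n_dropped:
        logger.info("dropped %d of %d rows with unmapped class strings", n_dropped, n_read)
    x = coords[cmap.x_column][keep]
    y = coords[cmap.y_column][keep]
    marks = mapped.to_numpy()[keep].astype(np.int64)

    if isinstance(window, str):
        if window != "auto":
            raise ValueError(f"unknown window spec {window!r}")
        if len(x) == 0:
            window = Window.rectangle(0.0, 1.0, 0.0, 1.0)
        else:
            window = Window.rectangle(x.min() - 1.0, x.max() + 1.0, y.min() - 1.0, y.max() + 1.0)
    metadata = {"source": str(path), "n_read": n_read, "n_kept": int(keep.sum()),
                "n_dropped": n_dropped}
    return PointPattern(x, y, window, marks, metadata)


def write_detections(p: PointPattern, path, cmap: ColumnMap | None = None) -> None:
    """Write a marked pattern as a tab-delimited detection table readable
    by :func:`read_detections` with the same column map."""
    cmap = cmap if cmap is not None else ColumnMap.default()
    if p.marks is None:
        raise ValueError("pattern must be marked to export detections")
    reverse = {int(v): k for k, v in cmap.class_dictionary.items()}
    df = pd.DataFrame(
        {
            cmap.x_column: p.x,
            cmap.y_column: p.y,
            cmap.class_column: [reverse[int(m)] for m in p.marks],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# result serialization


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_summary(result, path) -> None:
    """Write a SummaryFunction, ConfidenceBand or DivergenceResult as a TSV
    table (one row per r) plus a JSON metadata sidecar."""
    path = Path(path)
    if isinstance(result, SummaryFunction):
        df = pd.DataFrame(
            {"r": result.r.values, "estimate": result.estimate,
             "theoretical": result.theoretical}
        )
        meta = {
            "type": "SummaryFunction",
            "kind": result.kind,
            "mode": result.mode,
            "correction": result.correction,
            **_json_safe(result.metadata),
        }
    elif isinstance(result, ConfidenceBand):
        df = pd.DataFrame(
            {"r": result.r.values, "center": result.center,
             "lower": result.lower, "upper": result.upper}
        )
        meta = {
            "type": "ConfidenceBand",
            "level": result.level,
            "n_boot": result.n_boot,
            "seed": result.seed,
            **_json_safe(result.metadata),
        }
    elif isinstance(result, DivergenceResult):
        rv = result.r.values
        sig = np.isin(rv, result.significant_r)
        df = pd.DataFrame(
            {"r": rv, "delta": result.delta, "reverse_delta": result.reverse_delta,
             "significant": sig.astype(int)}
        )
        meta = {
            "type": "DivergenceResult",
            "statistic": result.statistic,
            "call": result.call,
            "specimen_label": classify_specimen(result),
            "trend": result.trend,
            "r_min_eval": result.r_min_eval,
            **_json_safe(result.metadata),
        }
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary(path):
    """Read back a table written by :func:`write_summary`.

    Returns ``(DataFrame, metadata dict)``; reconstructing a
    :class:`ConfidenceBand` from it is enough to reproduce a divergence
    call from serialized bands.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    return df, meta


def band_from_table(df, meta) -> ConfidenceBand:
    """Rebuild a :class:`ConfidenceBand` from its serialized form."""
    return ConfidenceBand(
        RGrid(df["r"].to_numpy()),
        df["center"].to_numpy(),
        df["lower"].to_numpy(),
        df["upper"].to_numpy(),
        level=meta.get("level", 0.95),
        n_boot=meta.get("n_boot", 0),
        seed=meta.get("seed"),
        metadata=meta,
    )
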