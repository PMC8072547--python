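"""Marked planar point patterns of segmented cells.

The data model mirrors the single-cell output of an image-analysis pipeline:
every cell is a point event at its nucleus centroid (µm coordinates) inside
an observation :class:`~tmespat.window.Window`, optionally carrying one of
four categorical marks — cytotoxic T lymphocyte (CTL), normoxic tumor cell,
hypoxic tumor cell, or stromal cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .window import Window

__all__ = ["CellClass", "PointPattern", "build_pattern", "split_by_mark",
           "pairwise_distances", "boundary_distance"]


class CellClass(IntEnum):
    """The four cell populations distinguished by the analysis."""

    CTL = 1
    NORMOXIC_TUMOR = 2
    HYPOXIC_TUMOR = 3
    STROMA = 4

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "CellClass":
        try:
            return _BY_LABEL[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown cell class label {label!r}") from None


_LABELS = {
    CellClass.CTL: "ctl",
    CellClass.NORMOXIC_TUMOR: "normoxic_tumor",
    CellClass.HYPOXIC_TUMOR: "hypoxic_tumor",
    CellClass.STROMA: "stroma",
}
_BY_LABEL = {v: k for k, v in _LABELS.items()}


@dataclass(frozen=True)
class PointPattern:
    """A (possibly marked) point pattern inside an observation window.

    Parameters
    ----------
    x, y
        Centroid coordinates in µm; equal length.
    window
        The observation region. Every point must lie inside it
        (boundary-inclusive).
    marks
        Optional integer array of :class:`CellClass` values, one per point.
        Duplicate coordinates are permitted and counted as distinct events
        (rounded centroid exports can collide).
    metadata
        Free-form provenance dictionary (simulator ground truth, import
        bookkeeping); never consulted by estimators.
    """

    x: np.ndarray
    y: np.ndarray
    window: Window
    marks: np.ndarray | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        x = np.ascontiguousarray(self.x, dtype=float)
        y = np.ascontiguousarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError(
                f"coordinate sequences must be 1-d and of equal length "
                f"(got {len(x)} x and {len(y)} y values)"
            )
        if self.marks is not None:
            marks = np.ascontiguousarray(self.marks, dtype=np.int64)
            object.__setattr__(self, "marks", marks)
            if len(marks) != len(x):
                raise ValueError(
                    f"marks length {len(marks)} does not match {len(x)} points"
                )
            bad = ~np.isin(marks, [c.value for c in CellClass])
            if bad.any():
                raise ValueError(
                    f"invalid mark values at indices {np.flatnonzero(bad)[:10].tolist()}"
                )
        inside = self.window.contains(x, y)
        if not np.all(inside):
            idx = np.flatnonzero(~inside)
            raise ValueError(
                f"{idx.size} point(s) outside the window, first offending "
                f"indices: {idx[:10].tolist()}"
            )

    # -- basic properties -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def intensity(self) -> float:
        """Mean intensity n / |W| in events per µm²."""
        return self.n / self.window.area

    def counts_by_class(self) -> dict[CellClass, int]:
        if self.marks is None:
            raise ValueError("pattern is unmarked")
        return {c: int(np.sum(self.marks == c.value)) for c in CellClass}

    # -- derived patterns -------------------------------------------------

    def subset(self, mask) -> "PointPattern":
        mask = np.asarray(mask)
        return PointPattern(
            self.x[mask],
            self.y[mask],
            self.window,
            None if self.marks is None else self.marks[mask],
        )

    def split_by_mark(self) -> dict[CellClass, "PointPattern"]:
        """Sub-pattern per cell class, all sharing the parent window."""
        if self.marks is None:
            raise ValueError("pattern is unmarked")
        return {c: self.subset(self.marks == c.value) for c in CellClass}

    def with_marks(self, marks) -> "PointPattern":
        return PointPattern(self.x, self.y, self.window, marks, dict(self.metadata))

    # -- geometry services ------------------------------------------------

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def pairwise_distances(self) -> np.ndarray:
        """Full symmetric Euclidean distance matrix (µm); zero diagonal."""
        if self.n == 0:
            return np.zeros((0, 0))
        c = self.coords()
        return cdist(c, c)

    def boundary_distances(self) -> np.ndarray:
        return np.asarray(self.window.boundary_distance(self.x, self.y))

    def nn_distances(self) -> np.ndarray:
        """Nearest-neighbour distance per point (duplicates give 0)."""
        if self.n < 2:
            raise ValueError("nearest-neighbour distances need at least 2 points")
        tree = cKDTree(self.coords())
        d, _ = tree.query(self.coords(), k=2)
        return d[:, 1]


# -- free-function surface mirroring the operation names -------------------

def build_pattern(x, y, marks, window: Window) -> PointPattern:
    """Validate and construct a marked :class:`PointPattern`."""
    return PointPattern(x, y, window, marks)


def split_by_mark(p: PointPattern) -> dict[CellClass, PointPattern]:
    return p.split_by_mark()


def pairwise_distances(p: PointPattern) -> np.ndarray:
    return p.pairwise_distances()


def boundary_distance(p: PointPattern) -> np.ndarray:
    return p.boundary_distances()
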