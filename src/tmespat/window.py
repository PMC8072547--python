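"""Observation windows for planar point patterns.

A window is the bounded region of tissue within which cell centroids were
recorded. Two shapes are supported: rectangles (whole-slide regions of
interest) and discs (tissue-microarray spots). All coordinates and lengths
are in micrometres (µm), areas in µm².

Windows provide the geometric services every estimator needs:

* point containment (boundary-inclusive),
* distance from a point to the window boundary (border edge correction),
* the area ``|W ∩ W + (dx, dy)|`` of the window intersected with a shifted
  copy of itself (translation edge correction),
* the mass of an isotropic Gaussian kernel inside the window (uniform edge
  correction for kernel intensity estimation),
* uniform random sampling and quadrat partitioning.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod

import numpy as np
from scipy.special import ndtr
from scipy.stats import ncx2

__all__ = ["Window", "RectangleWindow", "DiscWindow"]


def _as_array(*xs):
    arrs = [np.asarray(x, dtype=float) for x in xs]
    return arrs


class Window(ABC):
    """Abstract bounded observation region in the plane."""

    shape: str

    # -- construction -----------------------------------------------------

    @staticmethod
    def rectangle(x_min: float, x_max: float, y_min: float, y_max: float) -> "RectangleWindow":
        return RectangleWindow(x_min, x_max, y_min, y_max)

    @staticmethod
    def disc(center_x: float, center_y: float, radius: float) -> "DiscWindow":
        return DiscWindow(center_x, center_y, radius)

    @staticmethod
    def unit_square() -> "RectangleWindow":
        return RectangleWindow(0.0, 1.0, 0.0, 1.0)

    # -- geometry ---------------------------------------------------------

    @property
    @abstractmethod
    def area(self) -> float:
        """Window area in µm²."""

    @property
    @abstractmethod
    def bounds(self) -> tuple[float, float, float, float]:
        """Bounding box ``(x_min, x_max, y_min, y_max)``."""

    @property
    @abstractmethod
    def shorter_side(self) -> float:
        """The shorter extent of the window (rectangle: min side; disc:
        diameter). Drives the default analysis range and bandwidth rules."""

    @abstractmethod
    def contains(self, x, y):
        """Boundary-inclusive containment test (vectorised)."""

    @abstractmethod
    def boundary_distance(self, x, y):
        """Distance from interior points to the window boundary (≥ 0)."""

    @abstractmethod
    def translation_overlap(self, dx, dy):
        """Area of ``W ∩ (W + (dx, dy))``; symmetric in the sign of the
        shift and equal to ``area`` at zero shift."""

    @abstractmethod
    def gaussian_mass(self, x, y, sigma: float):
        """Mass of an isotropic Gaussian N((x, y), σ²·I) inside the window."""

    @abstractmethod
    def sample_uniform(self, n: int, rng: np.random.Generator):
        """Draw ``n`` i.i.d. uniform locations; returns ``(x, y)`` arrays."""

    @abstractmethod
    def quadrat_areas(self, nx: int, ny: int):
        """Areas of an ``nx × ny`` grid of quadrats laid over the bounding
        box, clipped to the window. Returns ``(areas, x_edges, y_edges)``
        with ``areas`` of shape ``(ny, nx)`` (row index = y)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.bounds})"


class RectangleWindow(Window):
    """Axis-aligned rectangle ``[x_min, x_max] × [y_min, y_max]``."""

    shape = "rectangle"

    def __init__(self, x_min: float, x_max: float, y_min: float, y_max: float):
        if not (x_min < x_max and y_min < y_max):
            raise ValueError(
                f"invalid rectangle: need x_min < x_max and y_min < y_max, "
                f"got [{x_min}, {x_max}] x [{y_min}, {y_max}]"
            )
        self.x_min = float(x_min)
        self.x_max = float(x_max)
        self.y_min = float(y_min)
        self.y_max = float(y_max)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def bounds(self):
        return (self.x_min, self.x_max, self.y_min, self.y_max)

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x, y):
        x, y = _as_array(x, y)
        return (
            (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        )

    def boundary_distance(self, x, y):
        x, y = _as_array(x, y)
        return np.minimum.reduce(
            [x - self.x_min, self.x_max - x, y - self.y_min, self.y_max - y]
        )

    def translation_overlap(self, dx, dy):
        dx, dy = _as_array(dx, dy)
        ox = np.clip(self.width - np.abs(dx), 0.0, None)
        oy = np.clip(self.height - np.abs(dy), 0.0, None)
        out = ox * oy
        return float(out) if out.ndim == 0 else out

    def gaussian_mass(self, x, y, sigma: float):
        x, y = _as_array(x, y)
        mx = ndtr((self.x_max - x) / sigma) - ndtr((self.x_min - x) / sigma)
        my = ndtr((self.y_max - y) / sigma) - ndtr((self.y_min - y) / sigma)
        out = mx * my
        return float(out) if out.ndim == 0 else out

    def sample_uniform(self, n: int, rng: np.random.Generator):
        x = rng.uniform(self.x_min, self.x_max, size=n)
        y = rng.uniform(self.y_min, self.y_max, size=n)
        return x, y

    def quadrat_areas(self, nx: int, ny: int):
        x_edges = np.linspace(self.x_min, self.x_max, nx + 1)
        y_edges = np.linspace(self.y_min, self.y_max, ny + 1)
        cell = (self.width / nx) * (self.height / ny)
        return np.full((ny, nx), cell), x_edges, y_edges


class DiscWindow(Window):
    """Disc of given center and radius (TMA spot geometry)."""

    shape = "disc"

    def __init__(self, center_x: float, center_y: float, radius: float):
        if not radius > 0:
            raise ValueError(f"disc radius must be positive, got {radius}")
        self.center_x = float(center_x)
        self.center_y = float(center_y)
        self.radius = float(radius)

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def bounds(self):
        r = self.radius
        return (self.center_x - r, self.center_x + r, self.center_y - r, self.center_y + r)

    @property
    def shorter_side(self) -> float:
        return 2.0 * self.radius

    def _center_distance(self, x, y):
        x, y = _as_array(x, y)
        return np.hypot(x - self.center_x, y - self.center_y)

    def contains(self, x, y):
        # tiny tolerance keeps points placed exactly on the rim inside
        return self._center_distance(x, y) <= self.radius * (1 + 1e-12)

    def boundary_distance(self, x, y):
        return np.clip(self.radius - self._center_distance(x, y), 0.0, None)

    def translation_overlap(self, dx, dy):
        dx, dy = _as_array(dx, dy)
        t = np.hypot(dx, dy)
        r = self.radius
        t = np.clip(t, 0.0, 2.0 * r)
        # lens area of two discs of equal radius r at center distance t
        out = 2.0 * r**2 * np.arccos(t / (2.0 * r)) - (t / 2.0) * np.sqrt(
            np.clip(4.0 * r**2 - t**2, 0.0, None)
        )
        return float(out) if out.ndim == 0 else out

    def gaussian_mass(self, x, y, sigma: float):
        # ||(x,y) + sigma*Z - c||² / sigma² is noncentral chi-square with
        # 2 df and noncentrality (d/sigma)², d the distance to the center.
        d = self._center_distance(x, y)
        out = ncx2.cdf((self.radius / sigma) ** 2, df=2, nc=(d / sigma) ** 2)
        out = np.asarray(out, dtype=float)
        return float(out) if out.ndim == 0 else out

    def sample_uniform(self, n: int, rng: np.random.Generator):
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        rad = self.radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        return self.center_x + rad * np.cos(theta), self.center_y + rad * np.sin(theta)

    def quadrat_areas(self, nx: int, ny: int):
        from shapely.geometry import Point, box

        disc = Point(self.center_x, self.center_y).buffer(self.radius, quad_segs=256)
        x0, x1, y0, y1 = self.bounds
        x_edges = np.linspace(x0, x1, nx + 1)
        y_edges = np.linspace(y0, y1, ny + 1)
        areas = np.zeros((ny, nx))
        for iy in range(ny):
            for ix in range(nx):
                cell = box(x_edges[ix], y_edges[iy], x_edges[ix + 1], y_edges[iy + 1])
                areas[iy, ix] = disc.intersection(cell).area
        # rescale so clipped areas sum exactly to the disc area despite the
        # polygonal approximation of the rim
        areas *= self.area / areas.sum()
        return areas, x_edges, y_edges
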