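"""Univariate summary statistics of a single cell population.

Four classical tools, each in a homogeneous and an inhomogeneity-corrected
flavour:

* **quadrat test** — chi-square test of constant intensity over a grid of
  quadrats; the first-look diagnostic that decides whether the corrected
  estimators are needed at all.
* **G function** — distribution of nearest-neighbour distances. Homogeneous
  mode uses the border (reduced-sample) estimator; inhomogeneous mode the
  van Lieshout style product estimator driven by the minimum of λ̂.
* **K function** — cumulative second-order statistic (expected number of
  further points within r of a typical point, intensity-scaled) with
  translation edge correction; CSR reference πr².
* **pair correlation function (pcf)** — the non-cumulative analogue,
  counting pairs on expanding rings through an Epanechnikov kernel; CSR
  reference 1. Values at distances below the cell-body scale are artefacts
  of collapsing cells to centroids and are flagged, not trusted.

The inhomogeneous K is renormalised so that a *constant* supplied intensity
reproduces the homogeneous estimator exactly; see ``_k_divisor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._pairs import (k_contributions, ordered_close_pairs, pcf_contributions,
                     translation_weights)
from .grid import RGrid
from .intensity import IntensityEstimate
from .pattern import PointPattern

__all__ = [
    "SummaryFunction",
    "QuadratTestResult",
    "quadrat_test",
    "g_function",
    "k_function",
    "pcf",
    "stoyan_bandwidth",
]

#: distances below this scale reflect cell bodies shrunk to centroids,
#: not biology; estimates there are flagged as unreliable
SMALL_R_ARTIFACT_UM = 8.0


@dataclass(frozen=True)
class SummaryFunction:
    """An estimated summary function of distance with its CSR reference."""

    kind: str          # "G" | "K" | "pcf" (cross variants prefix "cross_")
    mode: str          # "homogeneous" | "inhomogeneous"
    r: RGrid
    estimate: np.ndarray
    theoretical: np.ndarray
    correction: str
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.estimate) != len(self.r) or len(self.theoretical) != len(self.r):
            raise ValueError("estimate/theoretical length must match the r grid")

    def at(self, r_value: float) -> float:
        """Estimate at a grid value (nearest grid point)."""
        idx = int(np.argmin(np.abs(self.r.values - r_value)))
        return float(self.estimate[idx])

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r.values, self.estimate, label=f"{self.kind} ({self.mode})", **kwargs)
        ax.plot(self.r.values, self.theoretical, linestyle="--", label="CSR")
        ax.set_xlabel("r (µm)")
        ax.set_ylabel(self.kind)
        ax.legend()
        return ax


@dataclass(frozen=True)
class QuadratTestResult:
    nx: int
    ny: int
    counts: np.ndarray       # (ny, nx) observed
    expected: np.ndarray     # (ny, nx) area-proportional
    residuals: np.ndarray    # (ny, nx) Pearson (O − E)/√E
    statistic: float
    df: int
    p_value: float
    metadata: dict = field(default_factory=dict, compare=False)


def quadrat_test(p: PointPattern, nx: int, ny: int) -> QuadratTestResult:
    """Chi-square test of homogeneous intensity over an nx × ny quadrat grid.

    Expected counts are proportional to (window-clipped) quadrat area; the
    p-value is the upper tail of the chi-square distribution with
    ``(#quadrats with positive area) − 1`` degrees of freedom, i.e. the test
    asks specifically for evidence of *inhomogeneity*.
    """
    if p.n < 1:
        raise ValueError("quadrat test needs at least one point")
    if nx < 1 or ny < 1:
        raise ValueError("quadrat grid dimensions must be >= 1")
    areas, x_edges, y_edges = p.window.quadrat_areas(nx, ny)
    ix = np.clip(np.searchsorted(x_edges, p.x, side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(y_edges, p.y, side="right") - 1, 0, ny - 1)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)
    expected = p.n * areas / areas.sum()
    positive = areas > 0
    resid = np.zeros_like(counts)
    resid[positive] = (counts[positive] - expected[positive]) / np.sqrt(expected[positive])
    statistic = float(np.sum(resid[positive] ** 2))
    df = int(positive.sum()) - 1
    p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    metadata: dict = {}
    if np.any(expected[positive] < 1.0):
        metadata["warning"] = (
            "some expected quadrat counts are below 1; the chi-square "
            "approximation is unreliable"
        )
    return QuadratTestResult(nx, ny, counts, expected, resid, statistic, df, p_value, metadata)


# ---------------------------------------------------------------------------
# G function


def g_function(
    p: PointPattern,
    r: RGrid | None = None,
    mode: str = "homogeneous",
    intensity: IntensityEstimate | None = None,
) -> SummaryFunction:
    """Nearest-neighbour distance distribution function Ĝ(r)."""
    if p.n < 2:
        raise ValueError("G function needs at least 2 points")
    if r is None:
        r = RGrid.default(p.window)
    rv = r.values
    if mode == "homogeneous":
        d = p.nn_distances()
        b = p.boundary_distances()
        # tolerance absorbs floating-point ties at exact grid distances
        tol = 1e-9 * max(r.r_max, 1.0)
        num = np.sum(
            (d[:, None] <= rv[None, :] + tol) & (b[:, None] >= rv[None, :] - tol), axis=0
        )
        den = np.sum(b[:, None] >= rv[None, :] - tol, axis=0).astype(float)
        estimate = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
        lam = p.intensity
        theoretical = 1.0 - np.exp(-lam * np.pi * rv**2)
        meta = {"n": p.n, "estimator": "border (reduced sample)"}
        return SummaryFunction("G", mode, r, estimate, theoretical, "border", meta)
    if mode != "inhomogeneous":
        raise ValueError(f"unknown mode {mode!r}")
    if intensity is None:
        raise ValueError("inhomogeneous G needs an intensity estimate")
    lam = intensity.values_at_points
    lam_min = intensity.lambda_min
    coords = p.coords()
    i, j, d, _, _ = ordered_close_pairs(coords, coords, r.r_max, same_pattern=True)
    # per subject i: cumulative product over neighbours j (sorted by
    # distance) of (1 − λ_min / λ̂_j); indexed against the grid
    prod = np.ones((p.n, len(rv)))
    factors = 1.0 - lam_min / lam
    order = np.lexsort((d, i))
    i_s, j_s, d_s = i[order], j[order], d[order]
    starts = np.searchsorted(i_s, np.arange(p.n), side="left")
    ends = np.searchsorted(i_s, np.arange(p.n), side="right")
    for s in range(p.n):
        lo, hi = starts[s], ends[s]
        if lo == hi:
            continue
        cp = np.cumprod(factors[j_s[lo:hi]])
        idx = np.searchsorted(d_s[lo:hi], rv, side="right")
        prod[s] = np.where(idx > 0, cp[np.maximum(idx - 1, 0)], 1.0)
    estimate = 1.0 - prod.mean(axis=0)
    theoretical = 1.0 - np.exp(-lam_min * np.pi * rv**2)
    meta = {"n": p.n, "estimator": "van Lieshout product", "lambda_min": lam_min,
            "bandwidth": intensity.bandwidth}
    return SummaryFunction("G", mode, r, estimate, theoretical, "none", meta)


# ---------------------------------------------------------------------------
# K function and pcf


def _k_divisor(p: PointPattern, mode: str, intensity: IntensityEstimate | None) -> float:
    """Normalising divisor D with Σ_pairs w / D the K estimate.

    Homogeneous: D = n(n−1)/|W|. Inhomogeneous:
    D = ((n−1)/n) (Σ_i 1/λ̂_i)² / |W|, chosen so that a constant supplied
    λ̂ = n/|W| makes the inhomogeneous estimator coincide with the
    homogeneous one exactly.
    """
    n, area = p.n, p.window.area
    if mode == "homogeneous":
        return n * (n - 1) / area
    s = float(np.sum(1.0 / intensity.values_at_points))
    return (n - 1) / n * s**2 / area


def _pair_weights(p, i, j, dx, dy, mode, intensity):
    w = translation_weights(p.window, dx, dy)
    if mode == "inhomogeneous":
        lam = intensity.values_at_points
        w = w / (lam[i] * lam[j])
    return w


def _check_mode(mode, intensity):
    if mode not in ("homogeneous", "inhomogeneous"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "inhomogeneous" and intensity is None:
        raise ValueError("inhomogeneous mode requires an intensity estimate")


def k_local(
    p: PointPattern,
    r: RGrid,
    mode: str,
    intensity: IntensityEstimate | None,
) -> np.ndarray:
    """Loh local contributions s_i(r) for the univariate K; row mean is K̂."""
    _check_mode(mode, intensity)
    if p.n < 2:
        raise ValueError("K function needs at least 2 points")
    coords = p.coords()
    i, j, d, dx, dy = ordered_close_pairs(coords, coords, r.r_max, same_pattern=True)
    w = _pair_weights(p, i, j, dx, dy, mode, intensity)
    T = k_contributions(i, d, w, p.n, r)
    D = _k_divisor(p, mode, intensity)
    return p.n * T / D


def k_function(
    p: PointPattern,
    r: RGrid | None = None,
    mode: str = "homogeneous",
    intensity: IntensityEstimate | None = None,
    correction: str = "translation",
) -> SummaryFunction:
    """Ripley's K with translation edge correction; CSR reference πr²."""
    if correction != "translation":
        raise ValueError("only the translation correction is implemented for K")
    if r is None:
        r = RGrid.default(p.window)
    S = k_local(p, r, mode, intensity)
    estimate = S.mean(axis=0)
    theoretical = np.pi * r.values**2
    meta = {"n": p.n}
    if mode == "inhomogeneous":
        meta["intensity_bandwidth"] = intensity.bandwidth
        if intensity.floored:
            meta["warning"] = "intensity floor triggered; 1/λ̂ weights may be unstable"
    return SummaryFunction("K", mode, r, estimate, theoretical, correction, meta)


def stoyan_bandwidth(mean_intensity: float) -> float:
    """Stoyan's rule of thumb h = 0.15 / √λ̄ for the pcf ring kernel."""
    return 0.15 / np.sqrt(mean_intensity)


def pcf_local(
    p: PointPattern,
    r: RGrid,
    mode: str,
    intensity: IntensityEstimate | None,
    h: float,
) -> np.ndarray:
    """Loh local contributions for the pcf; row mean is ĝ (nan at r = 0)."""
    _check_mode(mode, intensity)
    if p.n < 2:
        raise ValueError("pcf needs at least 2 points")
    if h <= 0:
        raise ValueError("pcf bandwidth must be positive")
    coords = p.coords()
    i, j, d, dx, dy = ordered_close_pairs(coords, coords, r.r_max + h, same_pattern=True)
    w = _pair_weights(p, i, j, dx, dy, mode, intensity)
    T = pcf_contributions(i, d, w, p.n, r, h)
    D = _k_divisor(p, mode, intensity)
    rv = r.values
    with np.errstate(divide="ignore", invalid="ignore"):
        S = p.n * T / (D * 2.0 * np.pi * rv[None, :])
    S[:, rv == 0] = np.nan
    return S


def pcf(
    p: PointPattern,
    r: RGrid | None = None,
    mode: str = "homogeneous",
    intensity: IntensityEstimate | None = None,
    pcf_bandwidth: float | str = "stoyan",
) -> SummaryFunction:
    """Pair correlation function ĝ(r); CSR reference 1, undefined at r = 0."""
    if r is None:
        r = RGrid.default(p.window)
    if pcf_bandwidth == "stoyan":
        lam_bar = p.intensity if mode == "homogeneous" else float(
            np.mean(intensity.values_at_points)
        )
        h = stoyan_bandwidth(lam_bar)
    else:
        h = float(pcf_bandwidth)
    S = pcf_local(p, r, mode, intensity, h)
    estimate = S.mean(axis=0)
    theoretical = np.ones(len(r))
    meta = {"n": p.n, "pcf_bandwidth": h,
            "unreliable_below_um": SMALL_R_ARTIFACT_UM}
    if mode == "inhomogeneous":
        meta["intensity_bandwidth"] = intensity.bandwidth
    return SummaryFunction("pcf", mode, r, estimate, theoretical, "translation", meta)
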