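"""Cross-type (multitype) K and pair correlation functions.

These quantify attraction or repulsion *between* two cell populations: the
subject ("from") class — fixed to CTL in the study pipeline — and a target
("to") class. Under independence of the two populations the cross K equals
πr² and the cross pcf equals 1, regardless of either population's own
clustering, which is what makes curves for different target classes
directly comparable (and why the unstandardised cross-G is deliberately
absent from this package).

Inhomogeneous variants weight each ordered pair by
1/(λ̂_from(u) · λ̂_to(v)) with *per-class* intensity estimates, and use the
same exactness-preserving renormalisation as the univariate K: constant
supplied intensities reproduce the homogeneous estimator to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._pairs import (k_contributions, ordered_close_pairs, pcf_contributions,
                     translation_weights)
from .grid import RGrid
from .intensity import IntensityEstimate
from .pattern import CellClass, PointPattern
from .summary import SMALL_R_ARTIFACT_UM, SummaryFunction, stoyan_bandwidth

__all__ = ["CrossSpec", "k_cross", "pcf_cross"]


@dataclass(frozen=True)
class CrossSpec:
    """Ordered pair of populations: subject (from) and target (to) class."""

    from_class: CellClass
    to_class: CellClass

    def __post_init__(self):
        if self.from_class == self.to_class:
            raise ValueError("cross statistics need two distinct classes")


def _split_classes(p: PointPattern, spec: CrossSpec):
    if p.marks is None:
        raise ValueError("cross statistics need a marked pattern")
    parts = p.split_by_mark()
    pf, pt = parts[spec.from_class], parts[spec.to_class]
    for cls, part in ((spec.from_class, pf), (spec.to_class, pt)):
        if part.n < 2:
            raise ValueError(
                f"class {cls.name} has {part.n} point(s); cross statistics need >= 2"
            )
    return pf, pt


def _cross_divisor(pf, pt, mode, intensity_from, intensity_to) -> float:
    """D with Σ_pairs w / D the cross-K estimate.

    Homogeneous: D = n_from n_to / |W|; inhomogeneous:
    D = (Σ_u 1/λ̂_from(u)) (Σ_v 1/λ̂_to(v)) / |W| — exact homogeneous limit
    for constant supplied intensities.
    """
    area = pf.window.area
    if mode == "homogeneous":
        return pf.n * pt.n / area
    sf = float(np.sum(1.0 / intensity_from.values_at_points))
    st = float(np.sum(1.0 / intensity_to.values_at_points))
    return sf * st / area


def _cross_checks(mode, intensity_from, intensity_to):
    if mode not in ("homogeneous", "inhomogeneous"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "inhomogeneous" and (intensity_from is None or intensity_to is None):
        raise ValueError("inhomogeneous cross statistics need both class intensities")


def _cross_pair_weights(pf, pt, r_max, mode, intensity_from, intensity_to):
    i, j, d, dx, dy = ordered_close_pairs(pf.coords(), pt.coords(), r_max, same_pattern=False)
    w = translation_weights(pf.window, dx, dy)
    if mode == "inhomogeneous":
        w = w / (intensity_from.values_at_points[i] * intensity_to.values_at_points[j])
    return i, d, w


def k_cross_local(
    p: PointPattern,
    spec: CrossSpec,
    r: RGrid,
    mode: str = "homogeneous",
    intensity_from: IntensityEstimate | None = None,
    intensity_to: IntensityEstimate | None = None,
) -> np.ndarray:
    """Loh local contributions of the cross K; one row per subject point."""
    _cross_checks(mode, intensity_from, intensity_to)
    pf, pt = _split_classes(p, spec)
    i, d, w = _cross_pair_weights(pf, pt, r.r_max, mode, intensity_from, intensity_to)
    T = k_contributions(i, d, w, pf.n, r)
    D = _cross_divisor(pf, pt, mode, intensity_from, intensity_to)
    return pf.n * T / D


def k_cross(
    p: PointPattern,
    spec: CrossSpec,
    r: RGrid | None = None,
    mode: str = "homogeneous",
    intensity_from: IntensityEstimate | None = None,
    intensity_to: IntensityEstimate | None = None,
) -> SummaryFunction:
    """Cross-type K̂_{from,to}(r); independence reference πr²."""
    if r is None:
        r = RGrid.default(p.window)
    S = k_cross_local(p, spec, r, mode, intensity_from, intensity_to)
    estimate = S.mean(axis=0)
    meta = {
        "from_class": spec.from_class.name,
        "to_class": spec.to_class.name,
        "n_from": S.shape[0],
    }
    if mode == "inhomogeneous":
        meta["intensity_bandwidths"] = (intensity_from.bandwidth, intensity_to.bandwidth)
    return SummaryFunction(
        "cross_K", mode, r, estimate, np.pi * r.values**2, "translation", meta
    )


def pcf_cross_local(
    p: PointPattern,
    spec: CrossSpec,
    r: RGrid,
    mode: str = "homogeneous",
    intensity_from: IntensityEstimate | None = None,
    intensity_to: IntensityEstimate | None = None,
    bandwidth: float | str = "stoyan",
) -> np.ndarray:
    """Loh local contributions of the cross pcf (nan at r = 0)."""
    _cross_checks(mode, intensity_from, intensity_to)
    pf, pt = _split_classes(p, spec)
    if bandwidth == "stoyan":
        lam_bar = pt.intensity if mode == "homogeneous" else float(
            np.mean(intensity_to.values_at_points)
        )
        h = stoyan_bandwidth(lam_bar)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("pcf bandwidth must be positive")
    i, d, w = _cross_pair_weights(pf, pt, r.r_max + h, mode, intensity_from, intensity_to)
    T = pcf_contributions(i, d, w, pf.n, r, h)
    D = _cross_divisor(pf, pt, mode, intensity_from, intensity_to)
    rv = r.values
    with np.errstate(divide="ignore", invalid="ignore"):
        S = pf.n * T / (D * 2.0 * np.pi * rv[None, :])
    S[:, rv == 0] = np.nan
    return S


def pcf_cross(
    p: PointPattern,
    spec: CrossSpec,
    r: RGrid | None = None,
    mode: str = "homogeneous",
    intensity_from: IntensityEstimate | None = None,
    intensity_to: IntensityEstimate | None = None,
    bandwidth: float | str = "stoyan",
) -> SummaryFunction:
    """Cross-type pair correlation ĝ_{from,to}(r); independence reference 1."""
    if r is None:
        r = RGrid.default(p.window)
    S = pcf_cross_local(p, spec, r, mode, intensity_from, intensity_to, bandwidth)
    estimate = S.mean(axis=0)
    meta = {
        "from_class": spec.from_class.name,
        "to_class": spec.to_class.name,
        "n_from": S.shape[0],
        "unreliable_below_um": SMALL_R_ARTIFACT_UM,
    }
    return SummaryFunction(
        "cross_pcf", mode, r, estimate, np.ones(len(r)), "translation", meta
    )
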