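"""Synthetic point patterns: archetypes and a tumor-microenvironment model.

Three archetype generators — homogeneous/inhomogeneous Poisson (complete
spatial randomness), Thomas cluster processes, and Matérn-II hard-core
inhibition — provide patterns with known second-order behaviour for
validating every estimator in the package.

On top of them, :func:`simulate_microenvironment` emulates a head-and-neck
carcinoma region of interest with its four cell populations: tumor cells
fill roughly circular islets (hypoxic in the islet core, normoxic in the
rim), stromal cells fill the space between islets, and CTL appear as
Thomas-style clusters in the stroma plus a uniform infiltration of the
islets that is *thinned* inside each compartment by a retention
probability. Setting retention lower in hypoxic cores than in normoxic rims
builds hypoxia-mediated CTL exclusion into the ground truth; setting them
equal gives the null. The default configuration is sized to produce a
pattern of roughly 20,000 cells in a 1 × 1 mm window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .pattern import CellClass, PointPattern
from .window import RectangleWindow, Window

__all__ = [
    "simulate_poisson",
    "simulate_inhomogeneous_poisson",
    "simulate_thomas",
    "simulate_inhibited",
    "MicroenvConfig",
    "simulate_microenvironment",
]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_poisson(
    window: Window,
    intensity: float | None = None,
    n_fixed: int | None = None,
    seed=None,
    mark: CellClass | None = None,
) -> PointPattern:
    """Homogeneous Poisson process (or binomial process at fixed n)."""
    rng = _rng(seed)
    if (intensity is None) == (n_fixed is None):
        raise ValueError("give exactly one of intensity or n_fixed")
    n = rng.poisson(intensity * window.area) if n_fixed is None else int(n_fixed)
    x, y = window.sample_uniform(n, rng)
    marks = None if mark is None else np.full(n, int(mark))
    return PointPattern(x, y, window, marks)


def simulate_inhomogeneous_poisson(
    window: Window,
    intensity_function,
    max_intensity: float,
    seed=None,
    mark: CellClass | None = None,
) -> PointPattern:
    """Inhomogeneous Poisson process by thinning a dominating homogeneous
    proposal; ``intensity_function(x, y)`` must not exceed ``max_intensity``."""
    rng = _rng(seed)
    prop = simulate_poisson(window, intensity=max_intensity, seed=rng)
    lam = np.asarray(intensity_function(prop.x, prop.y), dtype=float)
    if np.any(lam > max_intensity * (1 + 1e-9)):
        raise ValueError("intensity function exceeds the stated maximum")
    keep = rng.uniform(size=prop.n) < lam / max_intensity
    marks = None if mark is None else np.full(int(keep.sum()), int(mark))
    return PointPattern(prop.x[keep], prop.y[keep], window, marks)


def simulate_thomas(
    window: Window,
    parent_intensity: float,
    cluster_sd: float,
    mean_offspring: float,
    seed=None,
    mark: CellClass | None = None,
) -> PointPattern:
    """Thomas cluster process: Poisson parents, Gaussian offspring.

    Parents are simulated in the bounding box buffered by 4 cluster
    standard deviations so that offspring intensity is unbiased near the
    window boundary; offspring falling outside the window are discarded.
    """
    if parent_intensity <= 0 or cluster_sd <= 0 or mean_offspring < 0:
        raise ValueError("Thomas parameters must be positive (mean_offspring >= 0)")
    rng = _rng(seed)
    x0, x1, y0, y1 = window.bounds
    buf = 4.0 * cluster_sd
    bw, bh = (x1 - x0) + 2 * buf, (y1 - y0) + 2 * buf
    n_par = rng.poisson(parent_intensity * bw * bh)
    px = rng.uniform(x0 - buf, x1 + buf, size=n_par)
    py = rng.uniform(y0 - buf, y1 + buf, size=n_par)
    n_off = rng.poisson(mean_offspring, size=n_par)
    cx = np.repeat(px, n_off)
    cy = np.repeat(py, n_off)
    total = int(n_off.sum())
    x = cx + rng.normal(0.0, cluster_sd, size=total)
    y = cy + rng.normal(0.0, cluster_sd, size=total)
    keep = np.asarray(window.contains(x, y))
    x, y = x[keep], y[keep]
    marks = None if mark is None else np.full(len(x), int(mark))
    return PointPattern(x, y, window, marks)


def simulate_inhibited(
    window: Window,
    proposal_intensity: float,
    hardcore_radius: float,
    seed=None,
    mark: CellClass | None = None,
) -> PointPattern:
    """Matérn-II hard-core process by dependent thinning.

    Proposals carry uniform age marks; a proposal survives only if no older
    proposal lies within the hard-core radius, so the minimum pairwise
    distance of the result is at least ``hardcore_radius``.
    """
    if hardcore_radius <= 0:
        raise ValueError("hard-core radius must be positive")
    rng = _rng(seed)
    prop = simulate_poisson(window, intensity=proposal_intensity, seed=rng)
    ages = rng.uniform(size=prop.n)
    dead = np.zeros(prop.n, dtype=bool)
    if prop.n > 1:
        from scipy.spatial import cKDTree

        pairs = cKDTree(prop.coords()).query_pairs(hardcore_radius, output_type="ndarray")
        # strict inequality below keeps pairs at exactly the hard-core
        # distance, matching the minimum-distance guarantee
        close = pairs[
            np.hypot(
                prop.x[pairs[:, 0]] - prop.x[pairs[:, 1]],
                prop.y[pairs[:, 0]] - prop.y[pairs[:, 1]],
            )
            < hardcore_radius
        ]
        younger = np.where(ages[close[:, 0]] > ages[close[:, 1]], close[:, 0], close[:, 1])
        dead[younger] = True
    x, y = prop.x[~dead], prop.y[~dead]
    marks = None if mark is None else np.full(len(x), int(mark))
    return PointPattern(x, y, window, marks)


# ---------------------------------------------------------------------------
# Composite tumor microenvironment


@dataclass(frozen=True)
class MicroenvConfig:
    """Parameters of the synthetic tumor-microenvironment generator.

    Densities are in events/µm², lengths in µm. ``retention_*`` are the
    probabilities that an infiltrating CTL inside a normoxic rim or a
    hypoxic core is retained; the default 1.0 vs. 0.2 encodes a five-fold
    hypoxic CTL exclusion, while equal values give the null model.
    """

    window: Window = None
    n_islets: float = 12.0                 # expected number of islet centers
    islet_radius_mean: float = 120.0
    islet_radius_sd_frac: float = 0.15
    hypoxic_core_fraction: float = 0.5     # core radius / islet radius
    tumor_cell_spacing: float = 10.0       # target spacing; density = 1/spacing²
    stroma_intensity: float = 0.024
    ctl_parent_intensity: float = 20e-6
    ctl_cluster_sd: float = 30.0
    ctl_mean_offspring: float = 80.0
    ctl_islet_infiltration_intensity: float = 3e-3
    retention_normoxic: float = 1.0
    retention_hypoxic: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.window is None:
            object.__setattr__(self, "window", RectangleWindow(0, 1000, 0, 1000))
        if not 0.0 <= self.retention_hypoxic <= 1.0:
            raise ValueError("retention_hypoxic must lie in [0, 1]")
        if not 0.0 <= self.retention_normoxic <= 1.0:
            raise ValueError("retention_normoxic must lie in [0, 1]")
        if not 0.0 < self.hypoxic_core_fraction < 1.0:
            raise ValueError("hypoxic_core_fraction must lie in (0, 1)")

    def null(self) -> "MicroenvConfig":
        """Same geometry with equal retention in cores and rims (no
        hypoxia-specific CTL exclusion)."""
        return replace(self, retention_hypoxic=self.retention_normoxic)

    def scaled_down(self, factor: float = 4.0) -> "MicroenvConfig":
        """Same window and islet geometry with all cell densities divided
        by ``factor`` — a cheaper pattern with the same spatial structure."""
        return replace(
            self,
            tumor_cell_spacing=self.tumor_cell_spacing * math.sqrt(factor),
            stroma_intensity=self.stroma_intensity / factor,
            ctl_mean_offspring=self.ctl_mean_offspring / factor,
            ctl_islet_infiltration_intensity=self.ctl_islet_infiltration_intensity / factor,
        )


def _islet_layout(cfg: MicroenvConfig, rng: np.random.Generator):
    """Islet centers via a Matérn-II process (cores cannot sit on top of
    each other), radii mildly dispersed around the mean."""
    area = cfg.window.area
    target = cfg.n_islets / area
    hardcore = 1.25 * cfg.islet_radius_mean
    cap = 1.0 / (math.pi * hardcore**2)
    if target >= cap:
        raise ValueError("requested islet intensity exceeds the hard-core packing bound")
    lam_p = -math.log(1.0 - target / cap) * cap
    centers = simulate_inhibited(cfg.window, lam_p, hardcore, seed=rng)
    radii = rng.normal(cfg.islet_radius_mean, cfg.islet_radius_sd_frac * cfg.islet_radius_mean,
                       size=centers.n)
    radii = np.clip(radii, 0.5 * cfg.islet_radius_mean, 1.5 * cfg.islet_radius_mean)
    return centers.x, centers.y, radii


def _islet_membership(x, y, icx, icy, irad):
    """For each point: index of its islet (min scaled distance), the scaled
    distance, or -1 when outside every islet."""
    x = np.asarray(x)
    # scaled distance d/R per islet; membership = argmin over islets
    sd = np.full((len(x),), np.inf)
    idx = np.full((len(x),), -1, dtype=np.int64)
    for k in range(len(icx)):
        s = np.hypot(x - icx[k], y - icy[k]) / irad[k]
        closer = s < sd
        sd = np.where(closer, s, sd)
        idx = np.where(closer, k, idx)
    inside = sd <= 1.0
    idx = np.where(inside, idx, -1)
    return idx, sd


def simulate_microenvironment(cfg: MicroenvConfig | None = None, seed=None) -> PointPattern:
    """Generate a four-class synthetic tumor microenvironment.

    Returns a marked pattern whose ``metadata`` records the ground truth:
    per-class counts, the islet layout, and CTL counts per compartment
    (stroma / normoxic rim / hypoxic core) together with the realised
    compartment areas.
    """
    cfg = cfg if cfg is not None else MicroenvConfig()
    rng = _rng(cfg.seed if seed is None else seed)
    icx, icy, irad = _islet_layout(cfg, rng)
    if len(icx) == 0:
        raise ValueError("no tumor islets generated; increase n_islets")
    core_frac = cfg.hypoxic_core_fraction

    # tumor cells: Poisson at the target density, restricted to islets
    tumor_density = 1.0 / cfg.tumor_cell_spacing**2
    prop = simulate_poisson(cfg.window, intensity=tumor_density, seed=rng)
    t_idx, t_sd = _islet_membership(prop.x, prop.y, icx, icy, irad)
    in_islet = t_idx >= 0
    tx, ty, tsd = prop.x[in_islet], prop.y[in_islet], t_sd[in_islet]
    hypoxic = tsd <= core_frac
    tumor_marks = np.where(hypoxic, int(CellClass.HYPOXIC_TUMOR), int(CellClass.NORMOXIC_TUMOR))

    # stromal cells: Poisson outside the islets
    sprop = simulate_poisson(cfg.window, intensity=cfg.stroma_intensity, seed=rng)
    s_idx, _ = _islet_membership(sprop.x, sprop.y, icx, icy, irad)
    sx, sy = sprop.x[s_idx < 0], sprop.y[s_idx < 0]

    # CTL, component 1: Thomas clusters confined to the stroma
    ctl_clusters = simulate_thomas(
        cfg.window, cfg.ctl_parent_intensity, cfg.ctl_cluster_sd, cfg.ctl_mean_offspring,
        seed=rng,
    )
    c_idx, _ = _islet_membership(ctl_clusters.x, ctl_clusters.y, icx, icy, irad)
    keep = c_idx < 0
    cx1, cy1 = ctl_clusters.x[keep], ctl_clusters.y[keep]

    # CTL, component 2: uniform islet infiltration thinned by retention
    iprop = simulate_poisson(cfg.window, intensity=cfg.ctl_islet_infiltration_intensity, seed=rng)
    i_idx, i_sd = _islet_membership(iprop.x, iprop.y, icx, icy, irad)
    in_islet_i = i_idx >= 0
    ix, iy, isd = iprop.x[in_islet_i], iprop.y[in_islet_i], i_sd[in_islet_i]
    in_core = isd <= core_frac
    retention = np.where(in_core, cfg.retention_hypoxic, cfg.retention_normoxic)
    keep_i = rng.uniform(size=len(ix)) < retention
    cx2, cy2, core2 = ix[keep_i], iy[keep_i], in_core[keep_i]

    x = np.concatenate([cx1, cx2, tx, sx])
    y = np.concatenate([cy1, cy2, ty, sy])
    marks = np.concatenate([
        np.full(len(cx1) + len(cx2), int(CellClass.CTL)),
        tumor_marks,
        np.full(len(sx), int(CellClass.STROMA)),
    ])

    counts = {
        CellClass.CTL: len(cx1) + len(cx2),
        CellClass.NORMOXIC_TUMOR: int(np.sum(tumor_marks == int(CellClass.NORMOXIC_TUMOR))),
        CellClass.HYPOXIC_TUMOR: int(np.sum(tumor_marks == int(CellClass.HYPOXIC_TUMOR))),
        CellClass.STROMA: len(sx),
    }
    empty = [c.name for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"configuration produced zero cells of class(es): {', '.join(empty)}")

    # Monte-Carlo compartment areas for ground-truth density bookkeeping
    mc_n = 200_000
    mx, my = cfg.window.sample_uniform(mc_n, rng)
    m_idx, m_sd = _islet_membership(mx, my, icx, icy, irad)
    frac_core = np.mean((m_idx >= 0) & (m_sd <= core_frac))
    frac_rim = np.mean((m_idx >= 0) & (m_sd > core_frac))
    area = cfg.window.area
    metadata = {
        "generator": "microenvironment",
        "counts": {c.name: n for c, n in counts.items()},
        "islets": {"x": icx.tolist(), "y": icy.tolist(), "radius": irad.tolist()},
        "ctl_in_stroma": int(len(cx1)),
        "ctl_in_core": int(np.sum(core2)),
        "ctl_in_rim": int(np.sum(~core2)),
        "area_core": float(frac_core * area),
        "area_rim": float(frac_rim * area),
        "retention_normoxic": cfg.retention_normoxic,
        "retention_hypoxic": cfg.retention_hypoxic,
    }
    return PointPattern(x, y, cfg.window, marks, metadata)
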