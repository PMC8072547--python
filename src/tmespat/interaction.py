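"""Specimen-level inference: does hypoxia repel cytotoxic T lymphocytes?

The question is answered by comparing two cross-type summary curves sharing
the same subject population (the CTL): CTL vs. normoxic tumor cells and CTL
vs. hypoxic tumor cells, each with a Loh bootstrap confidence band computed
from the *same* resampling seed so the comparison is paired.

The decision rule works on the per-distance gap between the two bands:

    delta(r)          = upper envelope (CTL–hypoxic) − lower envelope (CTL–normoxic)
    reverse_delta(r)  = upper envelope (CTL–normoxic) − lower envelope (CTL–hypoxic)

``delta(r) < 0`` means the CTL–hypoxic band lies entirely below the
CTL–normoxic band at distance r — significantly fewer CTL around hypoxic
than around normoxic tumor cells than their own intensities explain, i.e.
hypoxia-mediated inhibition. The reverse gap detects attraction. Distances
below ~8 µm are excluded: there the collapse of cell bodies to centroids
dominates the estimates.

The statsmodels-style entry point is :class:`CrossInteractionModel`, whose
``fit`` returns an :class:`InteractionResults` carrying both statistics
(cross K and cross pcf), their bands, per-statistic calls, and a combined
headline call that requires both statistics to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bootstrap import ConfidenceBand, StatisticSpec, bootstrap_band
from .cross import CrossSpec
from .grid import RGrid
from .intensity import IntensityEstimate, default_bandwidth, kernel_intensity
from .pattern import CellClass, PointPattern
from .summary import SMALL_R_ARTIFACT_UM

__all__ = [
    "DivergenceResult",
    "divergence",
    "divergence_from_bands",
    "classify_specimen",
    "CrossInteractionModel",
    "InteractionResults",
]

_CALLS = ("inhibition", "no_interaction", "attraction")


@dataclass(frozen=True)
class DivergenceResult:
    """Per-distance band gap between the two cross-type curves and the
    resulting specimen-level interaction call."""

    r: RGrid
    delta: np.ndarray
    reverse_delta: np.ndarray
    significant_r: np.ndarray      # r values with delta < 0 (above r_min_eval)
    call: str                      # inhibition | no_interaction | attraction
    trend: int                     # sign of mean(center_norm − center_hyp)
    r_min_eval: float
    statistic: str                 # "k_cross" | "pcf_cross"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.call not in _CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _run_mask(sig: np.ndarray, run_length: int) -> bool:
    """True if ``sig`` contains a run of at least ``run_length`` Trues."""
    run = 0
    for s in sig:
        run = run + 1 if s else 0
        if run >= run_length:
            return True
    return False


def divergence_from_bands(
    band_normoxic: ConfidenceBand,
    band_hypoxic: ConfidenceBand,
    r_min_eval: float = SMALL_R_ARTIFACT_UM,
    run_length: int = 1,
    statistic: str = "k_cross",
) -> DivergenceResult:
    """Apply the band-divergence decision rule to two precomputed bands.

    Depends only on the band envelopes, so serialised bands reproduce the
    call exactly.
    """
    r = band_normoxic.r
    if not np.array_equal(r.values, band_hypoxic.r.values):
        raise ValueError("the two bands must share the same r grid")
    delta = band_hypoxic.upper - band_normoxic.lower
    reverse_delta = band_normoxic.upper - band_hypoxic.lower
    rv = r.values
    evaluable = (rv > r_min_eval) & np.isfinite(delta) & np.isfinite(reverse_delta)
    n_grid_above = int(np.sum(rv > r_min_eval))
    if n_grid_above and np.sum(evaluable) < 0.5 * n_grid_above:
        raise ValueError("bands are undefined on more than half of the r grid")
    sig_inhib = evaluable & (delta < 0)
    sig_attr = evaluable & (reverse_delta < 0)
    inhib = _run_mask(sig_inhib, run_length)
    attr = _run_mask(sig_attr, run_length)
    # inhibition takes precedence: attraction is only called when the
    # inhibition direction is never significant
    if inhib:
        call = "inhibition"
    elif attr:
        call = "attraction"
    else:
        call = "no_interaction"
    gap = band_normoxic.center[evaluable] - band_hypoxic.center[evaluable]
    trend = int(np.sign(np.mean(gap))) if gap.size else 0
    meta = {
        "run_length": run_length,
        "level": band_normoxic.level,
        "n_boot": band_normoxic.n_boot,
        "both_directions_significant": bool(inhib and attr),
    }
    return DivergenceResult(
        r, delta, reverse_delta, rv[sig_inhib], call, trend, r_min_eval, statistic, meta
    )


def _class_intensities(
    p: PointPattern,
    classes: tuple[CellClass, ...],
    bandwidth: float | str = "auto",
) -> dict[CellClass, IntensityEstimate]:
    """Leave-one-out per-class kernel intensities with a shared bandwidth
    (the default rule evaluated on the full pattern's window)."""
    parts = p.split_by_mark()
    if bandwidth == "auto":
        bandwidth = default_bandwidth(p)
    return {
        c: kernel_intensity(parts[c], bandwidth=bandwidth, leave_one_out=True)
        for c in classes
    }


def divergence(
    p: PointPattern,
    statistic: str = "k_cross",
    mode: str = "inhomogeneous",
    r: RGrid | None = None,
    n_boot: int = 999,
    level: float = 0.95,
    seed: int | None = None,
    r_min_eval: float = SMALL_R_ARTIFACT_UM,
    run_length: int = 1,
    subject_class: CellClass = CellClass.CTL,
    intensity_bandwidth: float | str = "auto",
    pcf_bandwidth: float | str = "stoyan",
    return_bands: bool = False,
):
    """Compute both cross-type bands and the specimen-level call.

    The two bands share the subject set (all points of ``subject_class``)
    and the bootstrap seed, so their comparison is a paired one.
    """
    if statistic not in ("k_cross", "pcf_cross"):
        raise ValueError(f"unknown statistic {statistic!r}")
    kind = "K" if statistic == "k_cross" else "pcf"
    classes = (subject_class, CellClass.NORMOXIC_TUMOR, CellClass.HYPOXIC_TUMOR)
    counts = p.counts_by_class()
    short = [c.name for c in classes if counts[c] < 2]
    if short:
        raise ValueError(f"classes with fewer than 2 points: {', '.join(short)}")
    if r is None:
        r = RGrid.default(p.window)
    intensities = (
        _class_intensities(p, classes, intensity_bandwidth)
        if mode == "inhomogeneous"
        else {c: None for c in classes}
    )
    bands = {}
    for target in (CellClass.NORMOXIC_TUMOR, CellClass.HYPOXIC_TUMOR):
        spec = StatisticSpec(
            kind=kind,
            mode=mode,
            cross=CrossSpec(subject_class, target),
            intensity=intensities[subject_class],
            intensity_to=intensities[target],
            pcf_bandwidth=pcf_bandwidth,
        )
        bands[target] = bootstrap_band(p, spec, r, n_boot=n_boot, level=level, seed=seed)
    result = divergence_from_bands(
        bands[CellClass.NORMOXIC_TUMOR],
        bands[CellClass.HYPOXIC_TUMOR],
        r_min_eval=r_min_eval,
        run_length=run_length,
        statistic=statistic,
    )
    if return_bands:
        return result, bands
    return result


def classify_specimen(d: DivergenceResult) -> str:
    """Map the call to the three-way visual-scoring taxonomy, attaching the
    trend direction for non-significant specimens."""
    if d.call == "inhibition":
        return "negative interaction (inhibition)"
    if d.call == "attraction":
        return "positive interaction (clustering)"
    trend = {1: "repellent", -1: "attractant", 0: "none"}[d.trend]
    return f"no interaction (trend: {trend})"


# ---------------------------------------------------------------------------
# Model / Results surface


class CrossInteractionModel:
    """Specimen-level model of CTL–tumor-subtype spatial interaction.

    Parameters
    ----------
    pattern
        Marked point pattern with at least 2 CTL, 2 normoxic and 2 hypoxic
        tumor cells.
    mode
        ``"inhomogeneous"`` (default, per-class intensity reweighting) or
        ``"homogeneous"``.
    r
        Distance grid; defaults to 512 steps up to min(100 µm, side/4).
    r_min_eval
        Distances at or below this value are excluded from the decision
        rule (centroid-collapse artefact scale).
    """

    def __init__(
        self,
        pattern: PointPattern,
        subject_class: CellClass = CellClass.CTL,
        mode: str = "inhomogeneous",
        r: RGrid | None = None,
        intensity_bandwidth: float | str = "auto",
        pcf_bandwidth: float | str = "stoyan",
        r_min_eval: float = SMALL_R_ARTIFACT_UM,
    ):
        self.pattern = pattern
        self.subject_class = subject_class
        self.mode = mode
        self.r = r if r is not None else RGrid.default(pattern.window)
        self.intensity_bandwidth = intensity_bandwidth
        self.pcf_bandwidth = pcf_bandwidth
        self.r_min_eval = r_min_eval

    @classmethod
    def from_detections(cls, path, column_map=None, window="auto", **kwargs):
        """Build the model from a tab-delimited single-cell export."""
        from .io import ColumnMap, read_detections

        cmap = column_map if column_map is not None else ColumnMap.default()
        return cls(read_detections(path, cmap, window), **kwargs)

    def fit(
        self,
        statistics: tuple[str, ...] = ("k_cross", "pcf_cross"),
        n_boot: int = 999,
        level: float = 0.95,
        seed: int | None = None,
        run_length: int = 1,
    ) -> "InteractionResults":
        results, bands = {}, {}
        for stat in statistics:
            res, bds = divergence(
                self.pattern,
                statistic=stat,
                mode=self.mode,
                r=self.r,
                n_boot=n_boot,
                level=level,
                seed=seed,
                r_min_eval=self.r_min_eval,
                run_length=run_length,
                subject_class=self.subject_class,
                intensity_bandwidth=self.intensity_bandwidth,
                pcf_bandwidth=self.pcf_bandwidth,
                return_bands=True,
            )
            results[stat] = res
            bands[stat] = bds
        return InteractionResults(self, results, bands, n_boot, level, seed)


class InteractionResults:
    """Fitted cross-interaction results.

    ``divergences`` maps statistic name to its :class:`DivergenceResult`;
    ``bands`` maps statistic name to the two underlying
    :class:`ConfidenceBand` objects keyed by target class. The headline
    ``call`` requires every fitted statistic to agree; otherwise the
    specimen is reported as no_interaction with the trend attached.
    """

    def __init__(self, model, divergences, bands, n_boot, level, seed):
        self.model = model
        self.divergences = divergences
        self.bands = bands
        self.n_boot = n_boot
        self.level = level
        self.seed = seed

    @property
    def calls(self) -> dict[str, str]:
        return {k: v.call for k, v in self.divergences.items()}

    @property
    def call(self) -> str:
        calls = set(self.calls.values())
        if len(calls) == 1:
            return calls.pop()
        return "no_interaction"

    @property
    def label(self) -> str:
        """Specimen label in the three-way visual-scoring taxonomy."""
        first = next(iter(self.divergences.values()))
        if self.call == first.call:
            return classify_specimen(first)
        trend = {1: "repellent", -1: "attractant", 0: "none"}[first.trend]
        return f"no interaction (trend: {trend})"

    def significant_ranges(self, statistic: str) -> list[tuple[float, float]]:
        """Contiguous r intervals with significant inhibition."""
        res = self.divergences[statistic]
        sig = res.significant_r
        if sig.size == 0:
            return []
        step = res.r.values[1] - res.r.values[0]
        ranges = []
        start = prev = sig[0]
        for v in sig[1:]:
            if v - prev > 1.5 * step:
                ranges.append((float(start), float(prev)))
                start = v
            prev = v
        ranges.append((float(start), float(prev)))
        return ranges

    def summary(self) -> str:
        lines = [
            "Cross-type interaction analysis",
            "=" * 55,
            f"subjects:          {self.model.subject_class.name}"
            f" (n = {int(self.model.pattern.counts_by_class()[self.model.subject_class])})",
            f"mode:              {self.model.mode}",
            f"bootstrap:         n_boot = {self.n_boot}, level = {self.level},"
            f" seed = {self.seed}",
            f"r range:           ({self.model.r_min_eval:g}, {self.model.r.r_max:g}] µm",
            "-" * 55,
        ]
        for stat, res in self.divergences.items():
            ranges = self.significant_ranges(stat)
            rng_txt = (
                ", ".join(f"{a:.1f}-{b:.1f} µm" for a, b in ranges) if ranges else "none"
            )
            lines.append(f"{stat:<12} call: {res.call:<15} significant r: {rng_txt}")
        lines.append("-" * 55)
        lines.append(f"combined call:     {self.call}")
        lines.append(f"specimen label:    {self.label}")
        return "\n".join(lines)

    def plot(self, statistic: str = "k_cross", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(10, 4))
        bands = self.bands[statistic]
        res = self.divergences[statistic]
        for target, color in ((CellClass.NORMOXIC_TUMOR, "tab:red"),
                              (CellClass.HYPOXIC_TUMOR, "tab:green")):
            b = bands[target]
            ax[0].fill_between(b.r.values, b.lower, b.upper, alpha=0.3, color=color)
            ax[0].plot(b.r.values, b.center, color=color, label=target.name.lower())
        ax[0].set_xlabel("r (µm)")
        ax[0].set_ylabel(statistic)
        ax[0].legend()
        ax[1].plot(res.r.values, res.delta, color="black")
        ax[1].axhline(0.0, linestyle="--", color="gray")
        ax[1].set_xlabel("r (µm)")
        ax[1].set_ylabel("delta")
        return ax
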