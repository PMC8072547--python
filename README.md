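# tmespat

Spatial point-pattern statistics for tumor-microenvironment immune
infiltration analysis.

## What it is for

Multiplexed immunofluorescence with single-cell segmentation turns a tumor
section into a *marked planar point pattern*: every cell is a point at its
centroid (µm coordinates) with a class mark — cytotoxic T lymphocyte
(CTL), normoxic tumor cell, hypoxic tumor cell, or stromal cell. `tmespat`
answers two questions about such patterns objectively, replacing visual
scoring:

1. **Do CTL cluster?** Beyond what tissue-level inhomogeneity would
   explain, via the quadrat chi-square test and inhomogeneity-corrected
   G, K and pair correlation functions.
2. **Does hypoxia repel CTL?** By comparing the cross-type
   K/pcf curves of CTL vs. normoxic and CTL vs. hypoxic tumor cells, each
   with a Loh bootstrap confidence band, and calling the specimen
   *inhibition / no interaction / attraction* from the gap between the
   bands.

The audience is researchers in digital pathology and tumor immunology who
have per-cell detection exports (e.g. from QuPath) and want calibrated,
reproducible spatial inference.

## The statistics at the core

For a point process with intensity λ(x) observed in a window W, the
package estimates, on a distance grid r ∈ [0, 100 µm]:

* **K function** (translation edge correction):
  K̂(r) = Σ_{i≠j} 1{d_ij ≤ r} e_ij / D, with e_ij = |W| / |W ∩ W_shift| and,
  in inhomogeneous mode, pair weights 1/(λ̂_i λ̂_j) with a renormalised
  divisor D such that constant λ̂ reproduces the homogeneous estimator
  exactly. CSR reference πr².
* **Pair correlation function** ĝ(r): the non-cumulative analogue on
  expanding rings (Epanechnikov kernel, Stoyan bandwidth 0.15/√λ̄);
  reference 1.
* **G function**: nearest-neighbour distance distribution (border
  estimator, or van Lieshout product estimator in inhomogeneous mode).
* **Cross-type K̂_{12}, ĝ_{12}** over ordered (CTL, tumor-class) pairs with
  per-class intensity estimates; independence reference πr².
* **Loh bootstrap bands**: per-subject local contributions s_i(r) with
  mean equal to the estimate are resampled with replacement; pointwise
  percentile envelopes at 95% (with the √2 variance correction for
  univariate statistics).
* **Divergence rule**: delta(r) = upper band (CTL–hypoxic) − lower band
  (CTL–normoxic); delta(r) < 0 for some r ∈ (8, 100] µm ⇒ significant
  hypoxia-mediated inhibition of CTL infiltration.

A synthetic microenvironment generator (tumor islets with hypoxic cores,
stroma, CTL clusters, compartment-specific CTL retention) provides ground
truth for every stage; see `docs/methods.md`.

## Worked example

Simulate a specimen with an engineered five-fold CTL exclusion from
hypoxic islet cores (retention 0.2 vs. 1.0), then fit the interaction
model:

```python
from tmespat import CrossInteractionModel, MicroenvConfig, simulate_microenvironment

pattern = simulate_microenvironment(MicroenvConfig().scaled_down(), seed=11)
print(pattern.metadata["counts"])
# {'CTL': 454, 'NORMOXIC_TUMOR': 803, 'HYPOXIC_TUMOR': 275, 'STROMA': 3419}

fit = CrossInteractionModel(pattern).fit(n_boot=199, seed=11)
print(fit.summary())
```

```
Cross-type interaction analysis
=======================================================
subjects:          CTL (n = 454)
mode:              inhomogeneous
bootstrap:         n_boot = 199, level = 0.95, seed = 11
r range:           (8, 100] µm
-------------------------------------------------------
k_cross      call: inhibition      significant r: 8.6-62.5 µm
pcf_cross    call: inhibition      significant r: 8.0-41.8 µm
-------------------------------------------------------
combined call:     inhibition
specimen label:    negative interaction (inhibition)
```

Both cross statistics find the CTL–hypoxic band entirely below the
CTL–normoxic band over a contiguous range of distances (roughly one to
five cell diameters): at those scales there are significantly fewer CTL
around hypoxic than around normoxic tumor cells than the populations' own
spatial inhomogeneity explains — the engineered exclusion is recovered.
`fit.plot()` draws the paired bands and the delta curve;
`fit.divergences["k_cross"]` holds the per-r numbers.

The same analysis runs from the shell on a tab-delimited detection export
(columns `Centroid X µm`, `Centroid Y µm`, `Class`, remappable via
`--x-col/--y-col/--class-col/--class-map`):

```sh
tmespat simulate --preset microenv --seed 11 --out cells.txt
tmespat divergence --input cells.txt --n-boot 999 --seed 11 --report out/
tmespat full --preset microenv --seed 11 --out-dir report/
```

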