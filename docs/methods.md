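# Methods

## Problem and data model

The package analyses marked planar point patterns built from segmented-cell
centroids of immunofluorescence-stained tumor sections. Every cell is a
point event in µm coordinates inside a bounded observation window
(rectangular region of interest, or a disc for tissue-microarray spots),
carrying one of four marks: cytotoxic T lymphocyte (CTL), normoxic tumor
cell, hypoxic tumor cell (CA IX-positive), or stromal cell. Two scientific
questions drive the design: do CTL cluster beyond what tissue-level
inhomogeneity explains, and do hypoxic tumor subregions repel CTL more
strongly than normoxic ones?

Collapsing cell bodies (~8 µm across) to centroid points makes all
summary functions unreliable below roughly one cell diameter; estimates at
r ≤ 8 µm are flagged and excluded from inference. The analysis range is
capped at 100 µm (and at a quarter of the shorter window side for small
windows): beyond that scale, "clustering" is indistinguishable from
tissue-level inhomogeneity.

## Estimators

**Intensity.** λ̂(x_i) = Σ_{j≠i} κ_σ(x_i − x_j)/c_W(x_i), isotropic
Gaussian kernel with uniform edge correction (c_W is the exact kernel mass
inside the window: a product of normal CDFs for rectangles, a noncentral
chi-square CDF for discs), leave-one-out at data points, values floored at
10⁻¹² events/µm². Default bandwidth σ = min(shorter side/8, r_max):
deliberately conservative because spiky λ̂ destabilises the reciprocal
weights of the inhomogeneous estimators far more than oversmoothing does.

**K function.** Translation edge correction,
K̂(r) = Σ_{i≠j} 1{d_ij ≤ r} e_ij / D with e_ij = |W|/|W ∩ (W + x_j − x_i)|.
Homogeneous divisor D = n(n−1)/|W|; inhomogeneous pairs are additionally
weighted by 1/(λ̂_i λ̂_j) with D = ((n−1)/n)(Σ_i 1/λ̂_i)²/|W|. That divisor
is a Hamilton-type renormalisation chosen so that a constant supplied
intensity reproduces the homogeneous estimator *exactly* (to machine
precision), which makes the two modes commensurable and testable against
each other. Cross-type variants sum over ordered (subject, target) pairs
with D = n_from n_to/|W| and D = (Σ_u 1/λ̂_from)(Σ_v 1/λ̂_to)/|W|
respectively; intensities are estimated per class (populations of very
different abundance should not share one surface), with a shared default
bandwidth. Reference under CSR/independence: πr².

**Pair correlation function.** Ring-kernel estimator
ĝ(r) = Σ_{i≠j} κ_h(r − d_ij) w_ij / (2πr D) with an Epanechnikov kernel,
the same pair weights and divisors as K, and Stoyan's bandwidth rule
h = 0.15/√λ̄ by default (for cross statistics λ̄ is the target-class mean
intensity). ĝ is undefined at r = 0 and reported as NaN there.

**G function.** Homogeneous mode uses the border (reduced-sample)
estimator over nearest-neighbour distances; inhomogeneous mode the van
Lieshout product estimator driven by λ_min, with reference
1 − exp(−λ_min πr²). G is used for single-population clustering only;
there is intentionally no cross-G because it is not intensity-standardised
and curves for different target classes cannot be compared.

**Quadrat test.** Pearson chi-square over an nx × ny grid with expected
counts proportional to window-clipped quadrat area and an upper-tail
p-value (the question is specifically inhomogeneity). Expected counts
below 1 trigger a recorded warning rather than a failure.

## Loh bootstrap bands

Confidence bands come from resampling per-subject local contributions
s_i(r) (whose mean is the estimator) rather than the points themselves,
which preserves the dependence structure of the process. Bands are
pointwise percentile envelopes at the 95% level (α = 5%), n_boot = 999 by
default (odd count gives clean quantile indices), one seeded generator per
run, and intensity estimates frozen across replicates — re-estimating λ̂
inside a replicate would break the additive decomposition.

For the *univariate* K and pcf every unordered pair enters two subjects'
contributions, so naive subject resampling underestimates the estimator
variance by about a factor of two; the envelopes are therefore widened by
√2 around the estimate (the variance correction used by spatstat's
`lohboot`). Measured pointwise coverage of πr² under CSR at r = 50 µm is
then ~92–94% at nominal 95% — the residual anti-conservativeness is a
documented property of the method. Cross statistics assign each ordered
pair to exactly one subject and are left uncorrected; their calibration is
checked operationally through the null behaviour of the divergence call.

## The divergence rule

For one specimen, both cross bands — CTL vs. normoxic and CTL vs. hypoxic
— are computed with the same subject set (all CTL) and the same bootstrap
seed, so the comparison is paired. The decision statistic is the per-r gap

    delta(r) = upper(CTL–hypoxic) − lower(CTL–normoxic),

negative wherever the hypoxic band lies entirely below the normoxic band:
significantly fewer CTL near hypoxic than near normoxic tumor cells than
their own intensities explain. The call is *inhibition* if delta(r) < 0
anywhere in (8 µm, r_max]; *attraction* if the reverse gap is negative
somewhere and delta never is; *no interaction* otherwise, with the trend
(sign of the mean center-curve difference) attached. The per-r reading of
the band gap is the only construction that yields a delta *curve*; a
global min-vs-max comparison was considered and rejected. A stricter
minimum run length of consecutive significant r values is available
(default 1). The headline specimen call of `CrossInteractionModel.fit`
requires the cross-K and cross-pcf calls to agree; the per-statistic calls
are always reported alongside.

Calls map onto the three-way visual-scoring taxonomy: negative interaction
(inhibition) / no interaction (with trend) / positive interaction
(clustering).

## Synthetic microenvironment

The generator emulates a carcinoma region of interest in a 1 × 1 mm
window, sized to ≈ 20,000 cells: ~12 tumor islets (Matérn-II centers,
hard-core 1.25 × mean radius; radii ~N(120 µm, 18 µm) clipped) filled with
tumor cells at 10 µm spacing, marked hypoxic within half the islet radius
of its center; stroma as Poisson (0.024/µm²) outside islets; CTL as
Thomas clusters confined to the stroma (clustering of CTL in stroma is a
feature of the real material) plus uniform islet infiltration thinned by
compartment-specific retention probabilities — 1.0 in normoxic rims vs.
0.2 in hypoxic cores by default, encoding a five-fold exclusion; equal
retentions give the null. Cluster parents are simulated in a window
buffered by 4 cluster standard deviations so offspring intensity is
unbiased at the boundary. Ground-truth per-class and per-compartment
counts and Monte-Carlo compartment areas are recorded in the pattern
metadata.

What the simulator does *not* reproduce: irregular (non-circular) islet
shapes, gradual hypoxia gradients, segmentation artefacts (over/under
splitting of nuclei), and spatial variation in stromal density. Passing
tests therefore demonstrate correct estimator behaviour and calibrated
inference under a plausible idealised geometry, not performance on any
particular real specimen.

A note on the equal-retention null: because hypoxic cells sit deeper
inside islets than normoxic cells, CTL–hypoxic and CTL–normoxic curves can
differ under that null for purely geometric reasons even after intensity
correction (typically in the *attraction* direction at long range). The
false-inhibition rate is what the decision rule controls (measured ≤ 10%);
a label-permutation null, which removes the geometry, yields
no-interaction calls in ≥ 90% of seeds.

## Problem sizes and numerical choices

Operating characteristics (false-positive rate and power of the
divergence call) are measured on the density-scaled generator (all
densities ÷ 4, ≈ 5,000 cells, identical geometry) with n_boot = 199 and
100 seeds per condition, keeping the whole validation suite fast while
preserving the direction and strength of the engineered effect; full-size
(~20,000-cell) specimens are exercised in the end-to-end determinism and
seed-11 inhibition checks. Distance grids use 512 uniform steps. Floating
point ties at exact grid distances in the border G estimator are absorbed
by a 10⁻⁹-relative tolerance. Degenerate inputs (empty patterns, classes
with < 2 points, zero-area quadrats, undefined band regions) raise errors
naming the offending object, except where a defined value exists (empty
pattern splits, K̂(0) = 0).

## Known limitations

* Only rectangle and disc windows; no polygonal masks.
* Translation correction only for K/pcf (exact for both supported
  shapes); border correction only for G.
* Pointwise bands, not simultaneous envelopes: the any-r divergence rule
  inherits some multiplicity, mitigated by the band-vs-band (rather than
  curve-vs-band) construction and measured on synthetic nulls.
* Fixed four-class taxonomy; no fully automated threshold-free analysis.
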