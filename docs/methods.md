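# Methods

This note documents the models and numerical choices behind
`nicheshift`, what the virtual-species generator does and does not
emulate, and the limits of what the validation suite shows.

## Occurrence preparation

Records are read from delimited text with either `lon`/`lat` or the
GBIF `decimalLongitude`/`decimalLatitude` headers; rows with unparsable
or out-of-range coordinates are dropped and counted. Near-duplicates
are removed by greedy first-come thinning: walking the file in order, a
record is kept iff its haversine distance (sphere radius 6371 km) to
every already-kept record *of the same range* is at least
`min_dist_km` (default 1 km; the boundary is inclusive). Greedy
retention in input order is deterministic and order-stable; thinning is
idempotent. An alternative `grid` mode deduplicates by raster-cell
identity (default 0.5 arcmin), covering the other reasonable reading of
a "within 1 km" rule on ~1-km rasters. Environmental annotation assigns
each record the value of every layer at its containing cell, with
north-up, row-major, half-open cells `[x, x+w) × (y−h, y]`; records
off-grid or in no-data cells are dropped and reported.

## PCA-env and occupancy grids

The ordination is a correlation-matrix PCA (unit-variance scaling,
because bioclim variables mix °C, mm and unitless indices) fitted on
the pooled backgrounds of the two regions — by default *all* raster
cells of each region, optionally subsampled for speed. Component signs
are fixed so the largest-magnitude loading of each axis is positive.
Zero-variance variables are dropped with a warning.

Occupancy is estimated on an R×R grid (default R = 100, the convention
of the niche-dynamics literature) spanning the pooled-background extent.
Densities are binned kernel estimates: a 2-D histogram smoothed with a
Gaussian kernel, per-axis Silverman bandwidth h = σ̂ n^(−1/6) with a
floor of one grid cell (so degenerate point clouds still smooth), mass
smoothed past the border truncated before renormalization. The
availability correction is the density ratio z ∝ o/e, where the
occurrence density o and the background density e are smoothed **with
the same (occurrence) bandwidth**. A common bandwidth keeps the ratio
stable at the climate margin, where two differently-smoothed densities
would otherwise decay at different rates and the ratio would blow up;
it also makes the occupancy exactly invariant to duplicating the
background table. z is zero wherever the background density is zero and
sums to one; the uncorrected occurrence density `z_uncor` is retained
alongside. Background-mass masks mark the smallest cell sets holding
100% and 75% of e (cells ranked by density, so the masks nest).

## Overlap, dynamics, permutation tests

Schoener's D = 1 − ½Σ|z₁ − z₂| on occupancies normalized to sum one;
reported for both corrected and uncorrected occupancy, corrected being
the default (the correction is what minimizes geographic sampling
bias). The niche-dynamics indices are computed inside the intersection
of both background masks at the chosen analog level (1.00 or 0.75),
after renormalizing each occupancy within the mask: expansion is the
introduced occupancy outside the native niche, stability its
complement, unfilling the native occupancy outside the introduced
niche. Because a kernel density is positive everywhere inside the
smoothing radius, "outside the niche" is operationalised as outside the
smallest cell set holding `support_mass` = 0.99 of a range's occupancy;
discrete toy grids keep their exact zero/non-zero reading under this
rule, and unfilling(a, b) = expansion(b, a) holds exactly.

The equivalence test pools both ranges' projected occurrences and
randomly reallocates them into groups of the observed sizes; each
iteration rebuilds both occupancy grids (each against its own
background histogram, bandwidths recomputed for the permuted groups)
and recomputes D. The p-value is (#{D_null ≤ D_obs} + 1)/(n_iter + 1):
equivalence is rejected in the *lower* tail, the reading under which a
shifted niche produces a significant result; the tail is configurable.
The similarity test translates the other range's whole occupancy grid
(shape preserved, off-grid mass dropped, renormalized) to a uniformly
random cell of that range's background mask and recomputes D, with the
*higher* tail supporting similarity beyond chance. Default 1000
iterations; the +1 correction avoids p = 0.

A caveat that matters for interpretation: the equivalence test's null
is exchangeability of the pooled occurrences. When the two regions
offer different climates, even a species with one fixed niche yields
non-exchangeable samples, and the test responds to that availability
difference as well as to genuine niche change. The simulator's
`shared_landscape` option (both ranges drawn on the same climate
realization) exists precisely to create an exchangeable null; the
type-I calibration in the test suite uses it, and nominal error rates
are only guaranteed in that regime.

## Suitability models

The presence–background maximum-entropy model is fitted in its
penalized-GLM form: an L1-regularized logistic regression
(`liblinear`) of presences against background cells on linear +
quadratic features of standardized variables, suitability δ read off
the logistic output in [0, 1]. λ (the inverse of sklearn's `C`) is
selected from {0.01, 0.1, 1} by the one-standard-error rule on
cross-validated AUC (the strongest penalty within one SE of the best
mean) unless given — with few presences per fold, picking the raw AUC
maximum occasionally selects a near-unpenalized model that extrapolates
erratically when transferred to the other region; λ = 0 is rejected
(complete separation). Cross-validation splits the
presences into k = 5 shuffled folds that share the background; fold
AUCs score presences against the background sample. Background:
10,000 random cells per region, capped at the region size, seeded.

Projection freezes the training-region standardization constants (the
transfer convention) and flags cells whose climate lies outside the
training min/max of any variable (a MESS-like novelty indicator). The
increased-introduced-suitability summary is
100 × Σ(δ_introduced − δ_native)/Σδ_introduced over cells valid in both
maps; it is scale-sensitive by design but invariant to all-zero cells.
The ensemble variant evaluates the metric over all k×k fold-model
pairs and reports mean ± SEM.

## Performance and physiology links

Performance is a range's relative occurrence density across equal-width
bins (default 20) of a chosen climate variable (default bio11, mean
temperature of the coldest quarter), evaluated at the experiment's
sampling temperatures by linear interpolation between bin centers
(nearest-bin joining available); temperatures outside a range's
observed span score zero and are flagged. The marker formulas
DPS = (Zx + Ax)/(Vx + Ax + Zx) and H = (FW − DW)/DW are exact closed
forms. Link models are random forests (1000 trees, default mtry,
out-of-bag estimates, seeded): classification of range membership with
overall and per-range permutation importance and OOB error, and
regression of performance on markers per range with OOB explained
variance (in percent; negative when markers carry no signal).

## The virtual-species generator

Climate: each of the 19 bioclim layers is a weighted mixture of two
shared latent surfaces (a thermal and a moisture field; smoothed white
noise, Gaussian kernel of scale `autocorr_scale` = 5 cells) plus
layer-specific smoothed noise, then affinely rescaled to an
ecologically plausible range per variable (annual mean temperature
7–20 °C, annual precipitation 100–1500 mm, and so on). The latent
structure reproduces the strong inter-layer correlation of real bioclim
stacks — which is what makes a 2-D PCA-env meaningful — with the first
two components representing thermal and moisture gradients. The two
regions are drawn independently from the same process by default;
`introduced_cooling` extends the cold end of the introduced region's
temperature layers, and `shared_landscape` reuses the native
realization for both ranges (the exchangeable-null configuration).

Niche and sampling: the true niche is an axis-aligned Gaussian in
climate units (not PCA units) over bio1 and bio12, native center
(13 °C, 800 mm), SD (2.5 °C, 250 mm); the introduced center is
displaced `shift_magnitude` SD (default 2) along −bio1, emulating a
shift toward colder climates. Cells are sampled with probability
proportional to suitability × exp(bias_strength × standardized bio1) —
a one-knob stand-in for geographically uneven collection effort
(bias_strength has no empirical anchor and defaults to 0). Sample sizes
default to 52 native and 492 introduced records, the magnitudes typical
of a well-recorded invader with a sparsely collected native range.
Records sit at cell centers, so thinning at sub-cell distances mainly
removes exact duplicates.

Physiology: the marker table covers two ranges × six plants × five
sampling temperatures (10.3, 10.6, 4.7, 8.6, 12.6 °C mean air
temperature) for 13 markers. Means follow
base + slope × max(0, 10 °C − T): chlorophylls, hydration and stomatal
conductance decline in the cold while de-epoxidation (DPS, Zx) and
α-tocopherol rise, with stronger native responses (notably α-Toc and
Zx) — the qualitative chilling pattern of garden experiments. Gaussian
noise defaults to 5% of each baseline.

What the generator does *not* emulate: real topographic/coastal climate
structure, land/ocean masks, spatially clustered (road-side) sampling
beyond the single bias knob, taxonomic misidentification, dispersal
limitation or biotic interactions, and any covariance between
individual physiology and the occurrence process. Passing tests
therefore demonstrate statistical correctness of the machinery on
known ground truth, not that any real species' niche has shifted.

## Problem sizes and numerics

The validation suite runs scenarios at the default 60×60-cell regions
(unit tests use 25–40 cells per side and 12 layers to keep the suite
quick); permutation-test calibration uses 200 replicate scenarios at 99
permutations, power checks 50 replicates, recovery checks n = 500
presences. Ties in the λ grid resolve toward the stronger penalty.
Degenerate permuted groups with no mass on their background score
D = 0. All stochastic stages consume `numpy` Generator streams derived
from a single scenario seed by fixed offsets, so each stage is
independently reproducible and full runs are byte-identical.

## Known limitations

- The corrected occupancy depends on the bandwidth rule; Silverman
  oversmooths strongly bimodal occurrence clouds, blurring dynamics
  indices measured from single small samples.
- The 100% background mask is the kernel support of the background
  density and hence also bandwidth-dependent.
- The similarity test's shape-preserving translation is one of several
  published nulls (a point-resampling variant would randomize shape as
  well); translations near the background edge lose off-grid mass.
- Presence–background AUC is computed against the background sample,
  so its absolute value depends on background extent; only relative
  comparisons are meaningful.
- With few distinct experimental temperatures, the performance
  regression has few distinct responses; its OOB explained variance is
  then a coarse summary.
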