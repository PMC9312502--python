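# Methods

## The indices

`benthirr` computes two trait-based potentials of soft-sediment macrofauna
communities.

**Community bioirrigation potential (BIPc).** For a sample with taxa
*i = 1…n*, abundance *Aᵢ* (ind·m⁻²) and ash-free dry-weight biomass *Bᵢ*
(g·m⁻²),

    BIPc = Σᵢ (Bᵢ/Aᵢ) · Aᵢ · FTᵢ · BTᵢ · Lᵢ

where *FTᵢ* (feeding type), *BTᵢ* (burrow type) and *Lᵢ* (burrowing/
ventilation depth) are expert-assigned, non-negative trait scores.  The
engine evaluates the expression as written, guarding *Aᵢ = 0* records
(which contribute 0 without evaluating 0/0); for all-positive abundances
the *Aᵢ* factors cancel and the sum reduces to Σ Bᵢ·FTᵢ·BTᵢ·Lᵢ, an identity
the test suite asserts to 1e-12 relative.  A zero in any factor encodes a
trait irrelevant to solute exchange (e.g. epifauna) and forces a zero
contribution.  BIPc is reported on its natural score·g·m⁻² scale; no unit
claim is attached.

**Community bioturbation potential (BPc)**, the established reference
index, uses a square-root biomass weighting and a single mobility (*Mᵢ*) ×
reworking (*Rᵢ*) score pair:

    BPc = Σᵢ √(Bᵢ/Aᵢ) · Aᵢ · Mᵢ · Rᵢ

**Score switching.** BIPc scores come in two variants per taxon because
solute transport is diffusion-dominated in cohesive, low-permeability
sediments (mud to fine sand) and advection-dominated in permeable ones
(medium sand and coarser).  A sample is attributed to a system by its
median grain size against a threshold of **177 µm** (the conventional
fine/medium-sand boundary at 2.5 φ), with per-station expert overrides
taking precedence — overrides exist because fine-sand sites with high
organic content can behave diffusively despite a borderline median.  There
is no silent default: a sample with neither grain size, override nor label
raises.

**Unscored taxa** are excluded, never imputed; the designed diagnostic for
this loss is the coverage statistic (% of sample abundance and biomass
carried by scored taxa).  Taxon matching between community and score tables
is exact, case-insensitive, whitespace-normalised; no fuzzy matching.

**Depth handling.** Layer-restricted indices and vertical profiles use
half-open slices [top, bottom) with a closed final slice, 0-based at the
sediment–water interface, so slices partition the core and slice values
sum to the whole-core index.  "Theoretical" profiles place each taxon at
its literature burrow depth — a point value anticipating the maximum
penetration depth; no within-burrow distribution is modelled — while
"measured" profiles use the observed mid-depth of the slice of occurrence.

## Temporal analysis

Station comparisons run a one-way ANOVA followed by Tukey's HSD over all
station pairs, on log10(x+1)-transformed index values (the transform is
configurable; the log scale is an assumption, chosen for consistency with
the transform applied before spatial modelling).  Pairwise p-values use the
studentized-range distribution with the Tukey–Kramer correction for
unequal group sizes; with zero within-group variance everywhere the
comparison degenerates to exact separation (p = 0 / 1).  The compact letter
display uses the insert-and-absorb algorithm and guarantees: two groups
share a letter iff their adjusted p ≥ α (default α = 0.05).

The advective/diffusive contrast is the ratio of arithmetic means of the
*untransformed* index values (pooled over samples; a station-mean variant
is available by pre-aggregating), with significance from the Tukey test on
the two-level system factor.

## Spatial model

Station index values are log10(x+1)-transformed and regressed on
environmental predictor layers with a random forest:

- **Collinearity screen:** every predictor pair with |Pearson r| > 0.90
  (p < 0.05) loses the member with the smaller |Spearman| correlation to
  the transformed response ("lower predictive power" needs a concrete,
  deterministic definition; this is ours), iterated worst-pair-first until
  clean.  Constant predictors are dropped up front.
- **Fit:** 1000 trees; 1–5 candidate variables per split are tried and the
  setting with the highest out-of-bag % variance explained wins (ties to
  the smaller value).  The seed is recorded in the fit report.
- **Importance:** %IncMSE — the % increase in out-of-bag MSE when a
  predictor's column is permuted — averaged over ≥10 shuffles with a fixed
  sub-seed.
- **Validation:** Kendall's τ (two-sided p) between out-of-bag predictions
  and the transformed observations.  Out-of-bag is the defensible choice
  where resubstitution would flatter the fit.
- **Prediction:** cell-wise over a co-registered raster stack; cells masked
  in any input layer stay masked; the primary product is the log-scale map,
  with 10^ŷ − 1 available as an uncorrected back-transform.

The reference BPc map uses the same pipeline with 500 trees and 3 variables
per split.  Raster layers live in a small container (2-D masked array +
cell-center geotransform, row 0 northernmost) serialised as plain-text
ESRI ASCII grids; station extraction is nearest-cell, no interpolation.

## Hotspot overlay

"Relative hotspot" has no canonical definition, so the overlay is an
explicit operationalisation, not a reproduction: each raster is reduced to
within-raster quantile ranks (making the classification invariant to any
monotone rescaling of either input), and a cell is classed `bipc_higher` /
`bpc_higher` when the rank difference exceeds ±`delta_quantile` (default
0.10), `both_hot` when both ranks are ≥ `hot_quantile` (default 0.75) with
ranks within the delta band, else `neither`.  Both thresholds are exposed.

## Validation statistics

Spearman/Pearson correlation matrices use pairwise-complete deletion
(measurement suites rarely share a common n), midranks for ties, and
two-sided p-values; a constant variable leaves its cells undefined rather
than 0.  For n ≤ 9 the Spearman p is additionally computed exactly by
enumerating all n! rank permutations (the t-approximation and the exact
value can differ in the third decimal at such n; both are reported).  No
multiple-testing correction is applied across matrix cells.  The
univariate "variance explained" statistic is 100·R² of an ordinary
least-squares fit — for a univariate response under Euclidean distance
this is exactly what a distance-based redundancy analysis returns.
Per-analyte flux associations aggregate repeated station visits by mean or
max before correlating.

## Synthetic data: what it emulates, and what it does not

The generators produce, under one global seed fanned out to fixed
per-generator sub-streams:

- **Scores** for a 120-taxon pool: uniform integers in [1, 3], an exact
  10% epifaunal (zero burrow-type) fraction, 50% of taxa with
  independently drawn advective scores, literature depths U(2, 15) cm.
- **Communities** at 8 stations (4 diffusive, 4 advective) × 5 years:
  Bernoulli occupancy (p = 0.4), lognormal abundances and per-individual
  masses (right-skewed, as macrofauna data are — the reason for the
  log10(x+1) transform).  Each sample's biomasses are rescaled so that its
  true index equals base · multiplier(system) · S with S lognormal,
  E[S] = 1, CV = 0.3 and multiplier 5 for advective stations: the expected
  system contrast is therefore exact by construction, and the recorded
  ground truth comes from a plain-loop oracle, not the vectorised engine.
  An extra pool of unscored taxa (8% of the pool size, drawn like the
  others) keeps the coverage diagnostics away from a trivial 100%.
- **Landscapes**: 8 Gaussian-filtered smooth fields (40×40 cells of 600 m,
  filter σ = 4 cells) of which 3 drive the log-scale response linearly
  (declared coefficients 1.5, 1.2, 0.9) and 5 are decoys; station
  observations add N(0, 0.3²) noise, floored at 0 since a log10(x+1) index
  observation cannot be negative.  Smooth fields have few effective degrees
  of freedom, so an independently drawn decoy can correlate substantially
  with the drivers by chance; the driver subspace is therefore projected
  out of each decoy field so that "decoy" is true of the realised field,
  keeping the declared importance ranking well-defined.  A companion
  response with reversed driver weights stands in for the sibling
  bioturbation index in the overlay stage.
- **Measurements**: irrigation = a·BIPc^b·exp(ε) with a = 0.05, b = 1,
  ε ~ N(0, 0.3²), plus a proportional bromide inventory; 14 cores are
  selected round-robin across stations so they span the site contrast, as
  tracer campaigns do.

What passing tests on these data show: the engine computes its defining
sums exactly; the statistical stages recover effect sizes and rankings
they were given.  What they do not show: anything about real Baltic
communities — the generator matches neither the regional species pool nor
absolute index magnitudes, salinity gradients, spatial autocorrelation of
real predictor sets, or the ad-hoc organic-content reasoning behind
expert system overrides.

## Numerical choices and degenerate inputs

- Aᵢ = 0 with Bᵢ = 0 contributes 0 before any division; Bᵢ > 0 with
  Aᵢ = 0 is rejected at validation.
- Ranking ties (key-taxon shares, importance tables) break alphabetically.
- A group with zero summed index gets an empty ranking; zero total
  abundance/biomass leaves coverage undefined (None), never 0.
- Quantiles use linear interpolation.
- Problem sizes in the test and acceptance runs (200 landscape stations,
  40×40 grids, 40 community samples, 14 cores) are chosen as the smallest
  sizes at which the recovered effects are stable; they are deliberately
  far below the emulated survey's 2170 sampling events.

## Known limitations

- The grain-size threshold stands in for a full sediment-class map; users
  with mapped classes should pass labels/overrides instead.
- %IncMSE here is the plain % increase in OOB MSE, not the
  variance-normalised variant some R implementations report; rankings are
  comparable, magnitudes are not.
- The back-transformed prediction raster carries retransformation bias
  (no smearing correction); the log-scale raster is the primary product.
- Exact Spearman p-values stop at n = 9 (enumeration of 10! permutations
  would be slow and the approximation is already adequate there).
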