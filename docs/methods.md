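# Methods

This note documents the models and procedures implemented in `scftir`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Spectral model and preprocessing chain

A single-cell spectrum is an absorbance trace on a strictly descending
wavenumber grid (4,000 → 650 cm⁻¹, spectrometer convention). The default
digital spacing is 2 cm⁻¹ (1,676 points), consistent with a 4 cm⁻¹
instrument resolution after typical zero-filling; the spacing is
configurable. Cohort members must share a bitwise-identical grid — loading
performs no interpolation, and ragged inputs fail loudly naming the
offending cells. Interval membership is always lo ≤ ν̃ ≤ hi regardless of
storage order, and a wavenumber shared by two adjacent regions (1,480 or
1,300 cm⁻¹) belongs to the higher-wavenumber region, so the three
biochemical regions partition the grid and subregional distances never
double-count a point.

The chain runs in the fixed order **EMSC (optional, on raw absorbance) →
9-point smoothing → linear baseline correction → Savitzky–Golay second
derivative**:

* **Smoothing** — centered moving average of width 9 (configurable, odd);
  edge windows shrink symmetrically so a straight line is preserved
  everywhere including the ends.
* **Linear automatic baseline** — "automatic" linear correction is not a
  uniquely defined operation across instrument software; here it subtracts
  the straight line through the minimum point of the first 5% and the
  minimum point of the last 5% of the grid. This single-segment two-anchor
  convention is deterministic (first occurrence wins a tie), leaves the
  corrected spectrum exactly zero at both anchors, and is idempotent on
  spectra whose edges are baseline-dominated. A rubber-band/convex-hull
  correction was deliberately not used.
* **Second derivative** — Savitzky–Golay with window 9 and polynomial
  order 3 (matching the 9-point smoothing scale; both configurable), scaled
  by 1/Δν̃² so values are grid-spacing-invariant, with one-sided polynomial
  fits at the edges. Absorption maxima become sharp minima; linear baselines
  vanish exactly.
* **EMSC Mie correction** — each raw spectrum is regressed by ordinary
  least squares on a reference spectrum (cohort mean by default) plus
  interferents: polynomial terms to order 2 in scaled wavenumber and 9 van
  de Hulst extinction curves Q(ν̃) = 2 − (4/ρ)sin ρ + (4/ρ²)(1 − cos ρ),
  ρ = 2π·d·(n−1)·ν̃, spanning a 3 × 3 grid of sphere diameters
  (8–18 μm) and refractive indices (1.30–1.45). The corrected spectrum is
  (raw − fitted interferents)/b where b is the reference coefficient;
  |b| ≤ 10⁻⁶ is reported as a degenerate fit naming the cell. With
  `iterations > 1` the corrected cohort mean replaces the reference. This is
  the non-resonant Mie-EMSC variant: the resonant treatment (complex
  refractive index via Kramers–Kronig, iterated curve re-estimation) is out
  of scope. The simplification preserves peak positions, which is what the
  downstream features depend on; a second correction pass changes spectra by
  well under 1% RMS.

Whether PCA should consume corrected second derivatives or corrected raw
absorbance is a genuinely open choice; the pipeline applies EMSC before
smoothing/differentiation by default (configurable flag) and PCA always
operates on the second-derivative cohort.

## The 14-dimensional absorption matrix

Peak detection runs on the **cohort-mean** second derivative: per region,
local minima with negative value are ranked by depth and the expected count
is kept — 4 fatty-acid, 7 protein, 3 carbohydrate by default — with depth
ties broken toward higher wavenumber. Too few minima in a region is an
error naming the region, never a silent shortfall. A prominence-quantile
filter exists but defaults to 0 (pure top-N by depth), since nothing more
specific is defensible a priori.

Per cell, each consensus position is refined to the cell's own
second-derivative minimum within ±8 cm⁻¹ (restricted to the peak's region;
an emptied window falls back to the consensus position with a logged note).
The matrix entry is the cell's processed absorbance at the refined grid
point (default), or the sign-flipped second-derivative depth
(`value_source="second_derivative_depth"`). Extracted "values from the
spectra" could in principle mean either; absorbance-at-peak was chosen as
the default because it yields per-cell intensities on the original
absorbance scale. Consensus-plus-refinement guarantees a common
14-dimensional basis across cells — a requirement for Euclidean distances —
while honoring small per-cell peak shifts. Cells failing extraction are
excluded with a logged reason, never imputed.

Column order is peak 1 (highest wavenumber) through peak 14, so the
4/7/3 subregional views are contiguous column blocks and their concatenation
reproduces the matrix exactly.

## Distances, heterogeneity indices, PCA

Distances are plain Euclidean on the scoped columns; no standardization is
applied by default (a z-score option exists but is off, favoring
faithfulness to the conventional analysis over unit-variance convention).
The k × k matrix backs heatmaps; histograms and the summary indices (mean,
median, IQR) use only the k(k−1)/2 unique pairs, with histogram bins
anchored at zero. By construction D²(full) = D²(fatty) + D²(protein) +
D²(carbohydrate) for every pair.

PCA is mean-centered, unscaled, on second-derivative spectra over the full
grid or one region's points; components are ordered by explained variance
and signed so each loading's largest-magnitude element is positive. Group
separation in a score plot is summarized by the silhouette of the group
labels on the first two PCs; the thresholds used in tests (> 0.5 "clearly
separated", < 0.2 "overlapping") are pragmatic surrogates for qualitative
"clustered separately / dispersed" language, not estimates of any published
quantity.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Bands.** Each cell is a sum of 14 Gaussian bands. Default centers are
  canonical cell-FTIR assignments — CH₃/CH₂ stretches 2,956/2,922/2,874/
  2,852; ester C=O 1,740; amide I components 1,695/1,655/1,630; 1,585
  side-chain; amide II 1,545; tyrosine 1,515; PO₂⁻/C–O 1,240/1,085/1,050
  cm⁻¹ — with typical relative amplitudes (amide I dominant). Gaussian
  shapes (not Voigt) keep tests analytically tractable; the analysis depends
  on peak positions, not line shapes. Widths (FWHM 10–20 cm⁻¹) were chosen
  so that the closest default pairs (25 and 22 cm⁻¹ apart) remain resolved
  as distinct second-derivative minima after 9-point smoothing, keeping
  detected positions within one grid step of the generative centers.
  Whether any real cohort's 14 peaks include positions in the
  1,480–1,300 cm⁻¹ fatty-acid interval is configuration-dependent; the
  default places none there.
* **Variability.** Per-cell band amplitudes are scaled by mean-1 log-normal
  factors with coefficient of variation `cell_cv` (default 0.15) and by
  per-group multiplicative effects (scalar or per-band). Mean pairwise
  distance increases monotonically in `cell_cv`.
* **Artifacts.** A van de Hulst Mie baseline with per-cell random diameter
  (8–18 μm) and refractive index (1.30–1.45), scale `mie_amplitude`
  (default 0.05 a.u., i.e. a few percent of the amide I height); a random
  linear drift (sd 0.01 a.u. over the grid span); additive white noise
  (sd 0.002 a.u., a typical single-cell noise floor relative to unit-order
  absorbance).
* **Determinism.** One seeded generator per cohort; per-cell draws are
  consumed in cell-id order, so content does not depend on iteration
  strategy. Identical seeds reproduce cohorts bitwise.

What the generator does **not** emulate: water-vapor/CO₂ lines, detector
nonlinearity, resonant (derivative-shaped) Mie distortion, band-position
shifts between groups, or correlated amplitude structure across bands.
Passing tests therefore demonstrate correctness of the computational chain
under the stated generative model, not robustness to every artifact of real
beamline data.

## Drug-interaction models

All three models act on fractional responses in [0, 1]. CDI is evaluated on
the response kind supplied (its classical formulation is written in
viability terms); Bliss and HSA require inhibition fractions, and
conversion is explicit via the involutory `to_inhibition` (response ↦ 1 −
response). No silent rescaling or reconciliation is performed — notably,
CDI is not invariant under common rescaling of the three responses, and on
a single self-consistent measurement CDI > 1 (viability) is algebraically
equivalent to observed-below-Bliss (inhibition). Discordant published calls
across models therefore imply response estimates from different assays;
`consensus_call` combines per-model results computed on whatever inputs
each model legitimately received, by 2-of-3 majority.

Strict-sign classification is brittle against assay noise, so calls use
small boundary tolerances: CDI within 1 ± 0.05 is "additivity", Bliss/HSA
excess within ±0.01 is "additivity"; both configurable. One published
formulation of the independence rule ("P(a+b) + (1−Pa)(1−Pb) < 1 implies
synergy") contradicts the direction of the rule as defined alongside it;
this package implements the defined rule (synergy iff observed inhibition
exceeds the Bliss expectation) and makes no attempt to guess intent.

Dose conversion is exact (μM = μg/mL ÷ g/mol × 1,000) with a separate
2-decimal round-half-even display helper; published conversion tables often
vary by ±0.01 μM in the last digit, so comparisons should allow 0.02 μM.

**IC50.** The 4PL curve response = bottom + (top − bottom)/(1 + (c/IC50)^h)
is fitted by bounded least squares over (bottom, top, log₁₀ IC50, h) with
multi-start initialization over h ∈ {0.5, 1, 2, 4}; bounds bottom ∈ [0, 0.5],
top ∈ [0.5, 1.1], IC50 within two decades of the observed positive doses.
The reported IC50 is the relative (inflection-point) IC50. Constant
responses and fewer than 4 distinct concentrations are errors; a
non-monotone dose-response (Spearman |ρ| < 0.5) triggers a warning. The fit
is deterministic given the data.

## Problem sizes in tests

Monte-Carlo and recovery tests use cohorts of 30–100 cells per group and
200-replicate IC50 simulations with an 18-point design (6 doses × 3
replicates), sizes at which the standard-error bounds asserted by the tests
are comfortably resolvable while the full suite stays fast.

## Known limitations

* Non-resonant Mie-EMSC only; heavily resonance-distorted spectra (sharp
  derivative-like artifacts at strong bands) will be under-corrected.
* Exact-match grid policy: cohorts measured on different grids must be
  resampled upstream; no resampling is provided.
* Single dose-pair interaction assessment only — no Loewe surfaces,
  Chou–Talalay indices over dose matrices, or isobolograms.
* The consensus peak set is cohort-dependent; comparing feature matrices
  across independently processed cohorts requires detecting peaks on the
  pooled cohort.
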