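# Methods

## The measurement problem

Pioneer phototrophic microorganisms (cyanobacteria and green microalgae)
colonizing a stone surface build biofilms with recognizably different
architectures: *compact* mats blanket the substrate with few voids, while
*porous* growth forms a reticulate network of filaments that leaves many
empty volumes between cells. The architecture matters for
biodeterioration — it controls water and gas entrapment in the mat and
whether other organisms can lodge in its gaps — so a quantitative,
operator-independent way to place a strain on the porous↔compact axis is
useful. This package implements such a procedure for confocal Z-stacks
of biofilm autofluorescence acquired on stone tesserae, together with
substrate-scale coverage from ordinary photographs.

## Per-slice architecture quantities

Each Z-stack slice j (1 = bottom of the biofilm) is converted to 8-bit,
binarized with one global Otsu threshold per stack (foreground =
intensity ≥ threshold), and submitted to particle analysis under
8-connectivity. Three dimensionless quantities, each in [0, 1], describe
the biomass pattern F_ij of strain i in slice j:

- **Coverage fraction** 𝒜_ij = A_ij / a_i, the biomass area over the
  slice area.
- **Linear-measure ratio** ℒ_ij = (A_ij / P_ij) / (√a_i / 4). The
  pattern's characteristic linear measure (area over perimeter) is
  compared with that of the full square slice, whose area/perimeter is
  √a_i / 4; a pattern that fills the slice scores 1, a filament network
  with large perimeter per unit area scores near 0. Values are clamped
  to [0, 1] (a discretized contour of a near-full slice can nudge the
  raw ratio above 1; the raw value is retained).
- **Normalized fractal dimension** 𝒟_ij = D_B(F_ij) / 2, where D_B is
  the box-counting dimension estimated as the slope of the OLS fit of
  ln N(δ) against −ln δ, with R² reported. D_B is clamped to [0, 2]
  (raw slope retained).

### Box-counting choices

The grid is anchored at the image origin with a single offset (no offset
averaging), and box sides default to powers of two from **δ = 1** up to
a quarter of the smaller image dimension. Including the single-pixel
scale is deliberate: N(1) is the foreground area, and the finest decade
is where a curve-like reticulate network (local dimension ≈ 1) separates
from a plane-filling blob (≈ 2). With only coarse boxes both
architectures occupy nearly every box and the contrast washes out. The
analytic anchors are unaffected: a filled square yields D_B = 2 with
R² = 1, a one-pixel-wide line D_B = 1, an isolated pixel D_B = 0, all to
machine precision when the box sides divide the image dimensions.

### Perimeter convention

Perimeter is the contour length through the centers of the 4-connected
border pixels (the corner-weighted estimator of
`skimage.measure.perimeter`), under which a solid w×h block measures
2(w−1) + 2(h−1). Particle-analysis tools differ subtly in this
convention; any consistent choice works here because every downstream
quantity is a ratio formed within one convention.

## Aggregation and the colonization index

A strain's N_i-slice series S_i1..S_iN (one per quantity, averaged over
the three replicate sampling points after harmonizing slice counts to
the common minimum by index resampling) is collapsed three ways:

- **maximum** S_i^max = max_j S_ij,
- **mean** S̄_i = (1/N_i) Σ_j S_ij,
- **Gaussian-weighted mean** S_i^w = Σ_j w_j S_ij with
  w_j ∝ exp(−(j − μ_N)² / (2σ_N²)), normalized to Σ w_j = 1, where
  μ_N = λ(1 + N) and σ_N is the population standard deviation of the
  ordinals 1..N. The default λ = 0.5 centers the weights on the
  mid-depth slices, where phototrophic biomass concentrates, and
  down-weights the sparse top and bottom layers. (A `literal_sigma`
  switch replaces 2σ² by 2σ in the exponent for sensitivity analyses
  against non-standard formulations; the standard density is the
  default.)

Aggregated values are rescaled across strains by dividing each
(quantity × operator) column by its maximum over strains, so the best
strain per column scores exactly 1 and all values land in [0, 1]. The
**colonization index** of strain i under a fixed operator is the mean of
its three rescaled quantities; a strain is labelled

- **porous** if I_C < 0.5,
- **intermediate** if 0.5 ≤ I_C < 0.7 (both boundaries assigned upward),
- **compact** if I_C ≥ 0.7.

The strain-level label is the majority over the three operators, with a
disagreement flag; in practice the operators agree.

Degenerate cases: for a single-strain table rescaling is identically 1,
so the label is taken from the raw aggregated quantities (which are
already dimensionless in [0, 1]). A quantity × operator column whose
maximum is zero (no biomass anywhere) is rejected as an input error.

## Substrate-scale coverage

Tessera photographs are segmented by a color rule: a pixel is colonized
when its RGB distance from the pale-gray background reference
(default (200, 200, 200), tolerance 60) exceeds the tolerance **and**
green exceeds red by 10 (blue-green biomass). Coverage is
colonized-pixel count over total pixels, mirroring the per-slice
definition A/a. MIP coverage is computed the same way on the pixelwise
maximum (equivalently, logical OR of the binary slices). The Pearson
correlation between photo coverage and MIP coverage across strains
quantifies how far microscale arrangement is mirrored at the substrate
scale.

## Supporting statistics

Pairwise two-sided Mann–Whitney U tests (α = 0.05 default) compare
groups such as replicate roughness profiles; the exact null is used when
both samples have n ≤ 8 without ties, the tie- and continuity-corrected
normal approximation otherwise. Five-number summaries use inclusive
linear-interpolation quartiles with whiskers at min/max. Roughness
parameters are computed on the raw mean-centered profile (no filtering;
instrument cut-off treatment is out of scope): Ra = mean |z|,
Rq = RMS z, Rt = total peak-to-valley, Rz = mean peak-to-valley over 5
equal contiguous segments (the classical five-sampling-length
convention).

## Synthetic data: what it emulates and what it does not

No micrographs ship with the package, so a seeded generator produces
inputs with exact ground truth:

- **Coverage profile along depth.** Per-slice target coverage is
  Gaussian over the slice ordinal, coverage(j) = peak ·
  exp(−(j − c)² / (2w²)) with c = (N+1)/2 by default — high mid-depth,
  sparse at the top and bottom, as phototrophic biofilms stratify under
  light from above.
- **Compact regime.** Smooth 3-D Gaussian noise (lateral σ = max(w,h)/12,
  axial σ = 1.5 slices for z-continuity) thresholded per slice at the
  quantile that yields the target pixel count exactly: few large blobs
  with smooth boundaries and low perimeter-to-area.
- **Porous regime.** A pool of 8-neighbor random-walk filaments (18–32
  steps, stroke width 1–3 px) shared across slices; each slice
  accumulates pooled walks (with 1-px jitter) until its target count is
  reached, giving a reticulate network with crude z-continuity.
- **Intensities.** Near-binary: background ≈ 8 ± 4, foreground
  ≈ 210 ± 12 on the 8-bit scale. The intensity model is an assumption of
  the generator, not a measured property of autofluorescence.
- **Photographs.** Pale-gray textured background (≈ 200 ± noise) with
  blue-green patches (R ≈ 55, G ≈ 150, B ≈ 125) from a thresholded
  smooth field whose pixel count matches the requested coverage exactly.
- **Roughness profiles.** Gaussian-smoothed white noise, zero-mean,
  rescaled to a requested amplitude; 1600 samples by default, matching a
  palm-rugosimeter acquisition.

Suite defaults: 8 strains, 3 replicate stacks each (sampling points on
one tessera), 9 slices of 128×128 pixels. Frames are a scaled-down
stand-in for 512×512 confocal fields — at 64×64 the usable box-count
range is too short to resolve the architecture contrast well. Compact
strains draw peak slice coverage from (0.55, 0.80) and porous from
(0.12, 0.35), anchored to the observed substrate coverages of surviving
strains of each type (porous ≈ 19–33 %, compact ≈ 71–97 %; projection
coverage sits above peak slice coverage). Photo coverage is tied to the
ground-truth MIP coverage of the first replicate, so substrate- and
micro-scale coverage correlate by construction.

The generator reproduces the *geometric and statistical* structure the
analysis assumes — it is not a biophysical growth model (no nutrient
fields, EPS, or cell mechanics), contains no imaging artifacts (shading,
depth attenuation, spectral bleed-through), and its two regimes are
idealized endpoints. Passing tests therefore demonstrate that the
measurement chain recovers known architecture differences of this kind;
they do not validate the biological classification of any real strain.

## Numerical conventions and edge cases

- 8-bit conversion: linear min–max to 0–255, round half up; a constant
  image maps to all zeros with a warning.
- Thresholding: foreground = intensity ≥ threshold; Otsu over the
  256-bin histogram; single-valued histograms give an all-background
  mask with a warning.
- Slice-count harmonization: keep slices at indices
  round(linspace(1, N_orig, N_min)), order-preserving, duplicate-free.
- Empty slices: 𝒜 = ℒ = 0 by convention; the fractal estimate is
  flagged undefined and 𝒟 contributes 0.
- A positive area with zero perimeter is rejected as geometrically
  impossible under the contour convention.
- Weights at N = 1: σ_N = 0, w = [1].
- Reproducibility: one master seed; per-stack sub-seeds by fixed integer
  arithmetic; identical config + seed reproduces every CSV byte for
  byte.

## Problem sizes

The test suite and the acceptance script run on scaled-down inputs
chosen to exercise every code path: 64×64×9 stacks for bound and
dominance checks (20–40 stacks per property), 128×128×9 for the 8-strain
classification suite, brute-force oracles on masks up to 12×12 and rank
enumerations up to n = 6.

## Known limitations

- Single-channel analysis only; no spectral unmixing or multi-species
  biofilms (the index is defined for monospecific films).
- 2-D box counting per slice; no volumetric (3-D) fractal estimate or
  lacunarity.
- The color-rule photo segmentation assumes pale, near-neutral substrata
  and blue-green biomass; gray-dominant colonization (as some
  sheathed cyanobacteria produce) would need retuned rules.
- Classification thresholds (0.5, 0.7) are empirical conventions, not
  derived quantities; boundary assignment at exactly 0.5/0.7 is a
  package decision.
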