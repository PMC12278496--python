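# Methods

`optircell` analyses single-cell optical photothermal infrared (O-PTIR)
spectra of oleaginous yeast populations. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The measurement model

Each cell is characterised by six single-point spectra acquired on a 3×2
grid across the cell, on a fingerprint wavenumber grid of 950–1801 cm⁻¹ at
0.5 cm⁻¹ spacing (1703 points). The default population is 40 cells, hence
240 spectra. Cell cross-section areas come from binary segmentation masks:
area = (nonzero-pixel count) × res_x × res_y, with resolutions in µm per
pixel. Cells are partitioned into *small* (< 6 µm²), *mid* (6–12 µm²,
closed interval) and *large* (> 12 µm²); the boundary values 6 and 12
belong to *mid* because the outer classes are defined by strict
inequalities. Mask holes count as background.

## Preprocessing

The broadband chain is, in order:

1. **Savitzky–Golay second derivative**, polynomial order 2, window 35
   points. The derivative is reported per cm⁻¹ (index-space output divided
   by the squared grid step); because every downstream statistic is either
   a ratio or computed after unit-norm scaling, this convention only fixes
   the contract for testing. Values at the 17 points nearest each grid edge
   come from scipy's one-sided edge fits; both analysis regions are far
   from the edges on the default grid, so nothing depends on them.
2. **Truncation** to 1780–1350 cm⁻¹ (lipid/protein bands; 861 points) or
   1200–1000 cm⁻¹ (cell-wall carbohydrates; 401 points). Both interval
   endpoints are inclusive; truncation never interpolates or reorders.
3. **Vector normalisation** to unit Euclidean norm. A spectrum whose
   derivative norm is below 1e-9 (a constant or linear input) is rejected
   rather than amplified into noise.

Point intensities (e.g. for the sparse mode) are read at the nearest grid
point with no interpolation — negligible error on a 0.5 cm⁻¹ grid — with
equidistant requests resolved to the lower wavenumber.

## Heterogeneity statistics

Chemical variability is the Pearson distance 1−PCC ∈ [0, 2] between
preprocessed spectra. Intra-cell variability is the mean Pearson distance
of a cell's six spectra to the cell centroid (their pointwise mean);
inter-cell variability is the Pearson distance of the cell centroid to the
population centroid, which is the mean over **all** spectra (for a
balanced design this equals the mean of cell centroids; for unbalanced data
it deliberately weights by spectrum, not by cell). Outliers in either
statistic are flagged when they fall outside Q1 − 1.5·IQR or Q3 + 1.5·IQR,
with quartiles by linear interpolation between order statistics (numpy's
default "type 7" rule; other quartile conventions can flip flags exactly at
the fences, so the convention is fixed here).

The intra-vs-inter relationship is summarised by OLS with intra on the
y-axis; R² is the squared Pearson correlation and is orientation-free. The
"without outliers" fit drops cells flagged in *either* statistic.
Variability in the lipid/protein and carbohydrate regions is compared by
Spearman rank correlation of per-cell centroid-to-population distances,
computed independently per region; the per-cell distance metric defaults to
the Pearson distance with Euclidean distance available as a configuration
switch, since either reading is defensible for this construction.

## Band-ratio chemistry and group tests

Intensities at 1748 cm⁻¹ (TAG ester carbonyl), 1714 cm⁻¹ (FFA carboxylic
carbonyl) and 1659 cm⁻¹ (Amide I) proxy the TAG, FFA and protein content.
Three ratios are formed per spectrum: 1748/1714, 1748/1659, 1714/1659.

* **Broadband mode** reads the three values from preprocessed
  (second-derivative, normalised) spectra and adds an offset of −0.1 to
  *both* numerator and denominator before dividing. Adding the offset to
  both sides shifts the whole intensity scale away from zero without
  biasing one side of the ratio. Derivative values are used as they are
  (negative at absorbance peaks); a `negate` switch exists for exploration
  but is off by default.
* **Sparse mode** simulates four-wavenumber acquisition on raw spectra:
  intensities at the three marker bands minus the intensity at the
  1800 cm⁻¹ silent-region reference, no offset. Sparse values are taken
  from raw spectra because a four-point measurement admits no derivative;
  this also makes the mode an honest simulation of the fast-imaging
  workflow it represents.

PCA is computed on all individual preprocessed spectra in the lipid/protein
region (mean-centred, full SVD for determinism); loadings are unit-norm
with the sign fixed so each loading's largest-magnitude element is
positive.

Size-group differences of the TAG:FFA ratio are tested per spectrum with a
tie-corrected Kruskal–Wallis H,

H = [12/(N(N+1))] Σ nᵢ(R̄ᵢ − (N+1)/2)² / [1 − Σ(t³−t)/(N³−N)],

with a chi-square (k−1 df) p-value — implemented from the rank formula and
cross-checked against an independent library routine in the tests. An
all-tied input returns H = 0. The Shapiro–Wilk test on the pooled ratio
values is reported as the gate that motivates the rank-based test. Testing
per spectrum (240 values) rather than per cell matches the larger effective
sample the group statistics imply.

## The synthetic generator

The generator is the study-design stand-in that makes every stage testable
without restricted raw data. It emulates:

* **Bands**: five components (TAG, FFA, protein, carbohydrate, phosphate),
  each a sum of pseudo-Voigt bands (η = 0.5; FWHM 20 cm⁻¹ for
  carbonyl/amide bands, 40 cm⁻¹ for the carbohydrate envelope) at the
  positions listed in `default_band_library`. No band sits in the
  1790–1810 cm⁻¹ silent window, so the 1800 cm⁻¹ reference works as in the
  real experiment.
* **Size structure**: lognormal cell areas (log-mean 2.088, log-sd 0.352),
  placing roughly 20/67/13% of cells in the small/mid/large bins; each cell
  gets a rasterised elliptical mask and its *realised* mask area drives the
  classification, so geometry and spectra are always consistent.
* **Size-dependent chemistry**: Dirichlet-sampled compositions
  (concentration 150) around class means — small cells protein-dominant
  (45% protein), mid cells FFA-rich (FFA 30% > TAG 15%), large cells
  TAG-rich (TAG 40% > FFA 12%). These means are declared model defaults
  that encode the qualitative size effect; they are not measured values.
* **Intra-cell heterogeneity**: a two-endmember domain model. Lipid bodies
  are 95% lipid; the cytoplasm retains 30% of the cell's lipid level; the
  lipid-body volume fraction m₀ is solved so the mixture reproduces the
  cell composition exactly, and each measurement point draws its local
  lipid-body fraction from Beta(m₀k, (1−m₀)k) with concentration k = 12.
  The Beta variance scales as 1/(k+1), so k = 2.25 quadruples it — the
  handle the variance-behaviour tests use. Setting k = ∞ (or Dirichlet
  concentration = ∞) switches the corresponding variance off exactly,
  which is how the noise-floor fixtures are built.
* **Nuisance structure**: per-spectrum degree-2 polynomial baseline drift
  (constant term uniform in ±0.05, slope/curvature in ±0.01 on the
  normalised grid coordinate) and additive Gaussian noise with σ = 0.005
  against band amplitudes of order 1.

All randomness flows from a single seed through named `SeedSequence`
substreams (sizes, compositions, mixing, baselines, noise, masks), so
identical configurations reproduce datasets bit-for-bit and adding a stage
never perturbs earlier draws.

What the generator does **not** emulate: photothermal physics (laser power,
thermal-expansion differences between lipids and polysaccharides),
instrument drift between the three QCL stages, wavenumber calibration
error, scattering artefacts, the C–H stretch region above 1801 cm⁻¹, and
correlated (non-white) noise. Passing tests therefore demonstrate that the
analysis recovers the statistical structure the generator encodes — not
that it would behave identically on real instrument data, whose nuisance
structure is richer.

## Problem sizes and determinism

The test suite and the acceptance script run the full default design
(40 cells × 6 spectra × 1703 grid points) throughout; repeated-run checks
use 100–200 seeded populations and the null calibration of the
Kruskal–Wallis implementation uses 10,000 simulated three-group datasets
(three groups of 30). Spectra CSVs round-trip doubles exactly
(`%.17g` on write, round-trip float parsing on read). PCA uses the full
SVD solver so repeated runs are bit-identical.

## Known limitations

* Composition means per size class, noise level and baseline ranges are
  plausible defaults, not fitted to data; absolute values of H, R² or
  explained variances from synthetic runs are not comparable to any
  particular instrument's output — only the qualitative ordering and
  significance structure are.
* The outlier-injection fixture displaces cells toward a TAG-rich extreme;
  other displacement directions (e.g. carbohydrate-rich) would also be
  detected by 1−PCC but are not exercised.
* Masks are solid ellipses; irregular or lobed cell shapes only affect the
  area statistic through pixel count, which is the only shape descriptor
  used.
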