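# optircell

Single-cell infrared microspectroscopy analysis for microbial lipid
production. `optircell` quantifies phenotypic heterogeneity in populations
of oleaginous yeast measured by optical photothermal infrared (O-PTIR)
spectroscopy: how much individual cells differ chemically from the
population, how heterogeneous each cell is internally, and how the
triacylglycerol (TAG), free fatty acid (FFA) and protein content depends on
cell size. It is aimed at bioprocess and single-cell spectroscopy groups
who need a reproducible pipeline from point-spectra tables and segmentation
masks to population statistics — and at anyone simulating sparse-wavenumber
O-PTIR imaging before committing instrument time.

## What it computes

* **Preprocessing** — Savitzky–Golay second derivative (order 2, window
  35), truncation to the 1780–1350 cm⁻¹ lipid/protein or 1200–1000 cm⁻¹
  carbohydrate region, vector normalisation.
* **Heterogeneity** — chemical variability as the Pearson distance
  d = 1 − PCC ∈ [0, 2]. Intra-cell: mean distance of a cell's six point
  spectra to the cell centroid. Inter-cell: distance of the cell centroid
  to the population centroid (mean of all 240 spectra). 1.5×IQR outlier
  flags, intra-on-inter OLS regression, and Spearman correlation of
  per-cell distances between the two spectral regions.
* **Chemometrics** — PCA of the preprocessed spectra; band ratios
  i(1748)/i(1714), i(1748)/i(1659), i(1714)/i(1659) as TAG:FFA, TAG and
  FFA proxies; tie-corrected Kruskal–Wallis H across the three size
  classes (small < 6 µm², mid 6–12 µm², large > 12 µm²) with a
  Shapiro–Wilk normality gate.
* **Sparse-acquisition simulation** — the same ratios from only four
  wavenumbers (1659, 1714, 1748 cm⁻¹, baseline-referenced at 1800 cm⁻¹ in
  the silent region), emulating fast sparse-wavenumber imaging, plus a
  broadband-vs-sparse concordance report.
* **Synthetic data** — a forward simulator (pseudo-Voigt band mixtures,
  size-dependent Dirichlet compositions, lipid-body/cytoplasm domain
  mixing, baseline drift, noise) generating populations with the full
  study design: 40 cells × 6 spectra on a 950–1801 cm⁻¹ grid at
  0.5 cm⁻¹.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

```bash
optircell run --seed 1 --outdir run1
# run complete: 40 cells, 240 spectra → run1/run_summary.json
optircell compare run1
# per-cell r_tag_ffa rank correlation rho=0.828; decisions agree: True
```

The run writes `spectra.csv`, `areas.csv`, `variability.csv`,
`regression.json`, `pca_scores.csv`, `pca_loadings.csv`,
`ratios_broadband.csv`, `ratios_sparse.csv`, `group_tests.json` and
`run_summary.json`. For seed 1 the summary reports 10 small, 28 mid and
2 large cells; median intra- and inter-cell Pearson distances of 0.0175
and 0.0250 in the 1780–1350 cm⁻¹ region; and, in sparse mode, median
TAG:FFA ratios of 0.55 (small), 0.52 (mid) and 3.08 (large) with
Kruskal–Wallis H = 38.07, p = 5.4 × 10⁻⁹ across the size classes
(broadband mode: H = 95.66). Read: large cells carry far more TAG relative
to FFA than mid-size cells, the size effect is highly significant in both
acquisition modes, and per-cell chemistry from just four wavenumbers ranks
cells almost identically (ρ = 0.83) to the full broadband analysis.

The same stages are available as library functions
(`optircell.sample_population`, `preprocess_dataset`, `variability_table`,
`ratio_table`, `size_group_comparison`, …) and as individual subcommands
(`simulate`, `area`, `preprocess`, `heterogeneity`, `analyze`, `compare`).
File-based runs take a long-format spectra CSV
(`cell_id,point_id,wavenumber_cm1,intensity`) and per-cell 8-bit PNG masks
with a JSON sidecar giving µm-per-pixel resolutions.

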