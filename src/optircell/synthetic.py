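"""Forward simulation of single-cell O-PTIR spectra of oleaginous yeast.

The generator emulates the study design the analysis pipeline assumes:
40 cells, six single-point spectra per cell on a 3×2 grid, a fingerprint
wavenumber grid of 950–1801 cm⁻¹ at 0.5 cm⁻¹ spacing, and size-dependent
cellular chemistry — small cells protein-rich, mid-size cells FFA-rich,
large cells with a high TAG:FFA ratio.

Chemistry is modelled as a mixture of five components (TAG, FFA, protein,
carbohydrate, phosphate), each a sum of pseudo-Voigt absorption bands at the
positions observed for oleaginous yeast: the TAG ester carbonyl at
1748 cm⁻¹, the FFA carboxylic carbonyl at 1714 cm⁻¹, Amide I at 1659 cm⁻¹
and Amide II at 1547 cm⁻¹, CH₂/CH₃ deformations at 1463/1377 cm⁻¹, C–OH at
1413 cm⁻¹, phosphate near 1245 cm⁻¹ and a broad carbohydrate envelope at
1200–1000 cm⁻¹.  The window around 1800 cm⁻¹ is kept silent so it can serve
as the baseline reference in sparse-wavenumber mode.

Intra-cell heterogeneity arises from a two-endmember domain model: lipid
bodies contain almost pure lipid while the cytoplasm holds the remaining
mixture, and each measurement point probes a Beta-distributed lipid-body
volume fraction.  Inter-cell heterogeneity arises from Dirichlet sampling of
the composition around its size-class mean.  Per-spectrum degree-2 baseline
drift and additive Gaussian noise complete the forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import CellRecord, MaskImage, PopulationDataset, Spectrum
from .geometry import classify_size

COMPONENTS = ("TAG", "FFA", "protein", "carbohydrate", "phosphate")

#: No component may place a band inside this window; 1800 cm⁻¹ is the
#: baseline reference of the sparse acquisition mode.
SILENT_WINDOW = (1790.0, 1810.0)


# ---------------------------------------------------------------------------
# band model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A single absorption band.

    ``shape`` is one of ``gaussian``, ``lorentzian`` or ``pseudo_voigt``;
    for a pseudo-Voigt, ``eta`` is the Lorentzian weight in [0, 1].
    """

    center: float
    fwhm: float
    amplitude: float
    shape: str = "pseudo_voigt"
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if self.shape == "pseudo_voigt" and not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-Voigt eta must lie in [0, 1]")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid (peak height = amplitude)."""
        x = np.asarray(grid, dtype=float) - self.center
        hwhm = self.fwhm / 2.0
        lor = 1.0 / (1.0 + (x / hwhm) ** 2)
        gau = np.exp(-math.log(2.0) * (x / hwhm) ** 2)
        if self.shape == "gaussian":
            prof = gau
        elif self.shape == "lorentzian":
            prof = lor
        else:
            prof = self.eta * lor + (1.0 - self.eta) * gau
        return self.amplitude * prof


BandLibrary = dict[str, list[Band]]


def default_band_library() -> BandLibrary:
    """Band library for oleaginous yeast in the 950–1801 cm⁻¹ fingerprint.

    Carbonyl/amide bands use a 20 cm⁻¹ FWHM, the broad carbohydrate envelope
    40 cm⁻¹; all bands are pseudo-Voigt with η = 0.5.  Amplitudes are
    relative peak heights within a component (the strongest band of each
    component is 1).
    """
    lib: BandLibrary = {
        "TAG": [
            Band(1748.0, 20.0, 1.00),   # ester C=O stretch
            Band(1463.0, 20.0, 0.40),   # CH2/CH3 deformation
            Band(1377.0, 20.0, 0.35),
            Band(1160.0, 30.0, 0.25),   # C-O-C stretch
        ],
        "FFA": [
            Band(1714.0, 20.0, 1.00),   # carboxylic C=O stretch
            Band(1463.0, 20.0, 0.30),
            Band(1413.0, 20.0, 0.40),   # C-OH deformation
        ],
        "protein": [
            Band(1659.0, 20.0, 1.00),   # Amide I
            Band(1547.0, 20.0, 0.60),   # Amide II
        ],
        "carbohydrate": [
            Band(1155.0, 40.0, 0.55),
            Band(1080.0, 40.0, 1.00),   # C-C/C-O/C-O-C envelope
            Band(1030.0, 40.0, 0.80),
        ],
        "phosphate": [
            Band(1245.0, 25.0, 1.00),   # P=O stretch
        ],
    }
    _validate_library(lib)
    return lib


def _validate_library(lib: BandLibrary) -> None:
    lo, hi = SILENT_WINDOW
    for comp, bands in lib.items():
        for band in bands:
            if lo <= band.center <= hi:
                raise ValueError(
                    f"component {comp!r} places a band at {band.center} cm⁻¹ "
                    f"inside the silent window {SILENT_WINDOW}"
                )


def component_spectra(library: BandLibrary, grid: np.ndarray) -> dict[str, np.ndarray]:
    """Pure-component spectra (sum of each component's bands) on a grid."""
    return {
        comp: np.sum([b.profile(grid) for b in bands], axis=0)
        for comp, bands in library.items()
    }


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Mass fractions of the five components; non-negative, summing to 1."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != len(COMPONENTS):
            raise ValueError(f"expected {len(COMPONENTS)} fractions")
        arr = np.asarray(self.fractions, dtype=float)
        if np.any(arr < 0):
            raise ValueError("fractions must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {arr.sum()!r}")

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Composition":
        return cls(tuple(float(d.get(c, 0.0)) for c in COMPONENTS))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COMPONENTS, self.fractions))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def lipid_fraction(self) -> float:
        d = self.as_dict()
        return d["TAG"] + d["FFA"]


# Size-class composition means: small cells protein-dominant, mid-size cells
# FFA over TAG, large cells TAG over FFA.  These are generator defaults
# encoding the qualitative size-dependent chemistry, not measured values.
DEFAULT_COMPOSITION_MEANS: dict[str, Composition] = {
    "small": Composition.from_dict(
        {"TAG": 0.08, "FFA": 0.12, "protein": 0.45, "carbohydrate": 0.28, "phosphate": 0.07}
    ),
    "mid": Composition.from_dict(
        {"TAG": 0.15, "FFA": 0.30, "protein": 0.25, "carbohydrate": 0.23, "phosphate": 0.07}
    ),
    "large": Composition.from_dict(
        {"TAG": 0.40, "FFA": 0.12, "protein": 0.18, "carbohydrate": 0.23, "phosphate": 0.07}
    ),
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the forward simulation.

    Defaults reproduce the acquisition design: 40 cells × 6 points on the
    950–1801 cm⁻¹ grid at 0.5 cm⁻¹ spacing.  ``area_logmean``/``area_logsd``
    parameterise a lognormal cell-area distribution placing roughly 20/67/13%
    of cells in the small/mid/large bins.  ``composition_concentration`` is
    the Dirichlet concentration of per-cell compositions around the class
    mean (``inf`` = no inter-cell composition variance) and
    ``mixing_concentration`` the Beta concentration of per-point lipid-body
    fractions (``inf`` = no intra-cell domain variance).
    """

    n_cells: int = 40
    points_per_cell: int = 6
    grid_start: float = 950.0
    grid_end: float = 1801.0
    grid_step: float = 0.5
    area_logmean: float = 2.088
    area_logsd: float = 0.352
    composition_means: dict[str, Composition] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_MEANS)
    )
    composition_concentration: float = 150.0
    mixing_concentration: float = 12.0
    noise_sd: float = 0.005
    baseline_const_range: tuple[float, float] = (-0.05, 0.05)
    baseline_coeff_range: tuple[float, float] = (-0.01, 0.01)
    mask_res_um: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.points_per_cell < 1:
            raise ValueError("points_per_cell must be >= 1")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")
        if not self.grid_start < self.grid_end:
            raise ValueError("grid_start must be below grid_end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.area_logsd < 0:
            raise ValueError("area_logsd must be non-negative")
        if not self.composition_concentration > 0:
            raise ValueError("composition_concentration must be positive")
        if not self.mixing_concentration > 0:
            raise ValueError("mixing_concentration must be positive")
        if not self.mask_res_um > 0:
            raise ValueError("mask_res_um must be positive")
        for label in ("small", "mid", "large"):
            if label not in self.composition_means:
                raise ValueError(f"composition_means missing size class {label!r}")

    def make_grid(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "points_per_cell": self.points_per_cell,
            "grid_start": self.grid_start,
            "grid_end": self.grid_end,
            "grid_step": self.grid_step,
            "area_logmean": self.area_logmean,
            "area_logsd": self.area_logsd,
            "composition_means": {
                k: v.as_dict() for k, v in self.composition_means.items()
            },
            "composition_concentration": self.composition_concentration,
            "mixing_concentration": self.mixing_concentration,
            "noise_sd": self.noise_sd,
            "baseline_const_range": list(self.baseline_const_range),
            "baseline_coeff_range": list(self.baseline_coeff_range),
            "mask_res_um": self.mask_res_um,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "composition_means" in d:
            d["composition_means"] = {
                k: v if isinstance(v, Composition) else Composition.from_dict(v)
                for k, v in d["composition_means"].items()
            }
        if "baseline_const_range" in d:
            d["baseline_const_range"] = tuple(d["baseline_const_range"])
        if "baseline_coeff_range" in d:
            d["baseline_coeff_range"] = tuple(d["baseline_coeff_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spectrum(
    composition: Composition,
    library: BandLibrary,
    grid: np.ndarray,
    baseline_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    cell_id: str = "",
    point_id: str = "",
) -> Spectrum:
    """Render one spectrum: component mixture + polynomial baseline + noise.

    The baseline is a degree-2 polynomial ``c0 + c1·x + c2·x²`` in the grid
    coordinate ``x`` normalised to [-1, 1].  Noise is i.i.d. Gaussian with
    standard deviation ``noise_sd``; the draw comes from ``rng`` so that a
    fixed generator state reproduces the spectrum exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1:
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("render_spectrum requires a uniform wavenumber grid")
    comp_mat = component_spectra(library, grid)
    intensity = np.zeros_like(grid)
    for comp, frac in composition.as_dict().items():
        intensity += frac * comp_mat[comp]
    x = np.linspace(-1.0, 1.0, grid.size) if grid.size > 1 else np.zeros(1)
    c0, c1, c2 = baseline_coeffs
    intensity = intensity + c0 + c1 * x + c2 * x**2
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(
        wavenumbers=grid, intensities=intensity, cell_id=cell_id, point_id=point_id
    )


def _endmembers(composition: Composition) -> tuple[np.ndarray, np.ndarray, float]:
    """Split a cell composition into lipid-body and cytoplasm endmembers.

    The lipid body holds 95% lipid (TAG:FFA in the cell's own ratio), the
    cytoplasm retains 30% of the cell's lipid level; the lipid-body volume
    fraction ``m0`` is solved so that ``m0·lipid + (1-m0)·cyto`` equals the
    cell composition exactly.
    """
    c = composition.as_array()
    idx = {name: i for i, name in enumerate(COMPONENTS)}
    lipid_total = c[idx["TAG"]] + c[idx["FFA"]]
    nonlipid_total = 1.0 - lipid_total
    if lipid_total <= 0 or nonlipid_total <= 0:
        # degenerate cell (pure lipid or lipid-free): no domain contrast
        return c.copy(), c.copy(), 0.0
    lipid_dir = np.zeros_like(c)
    lipid_dir[idx["TAG"]] = c[idx["TAG"]] / lipid_total
    lipid_dir[idx["FFA"]] = c[idx["FFA"]] / lipid_total
    nonlipid_dir = c.copy()
    nonlipid_dir[idx["TAG"]] = 0.0
    nonlipid_dir[idx["FFA"]] = 0.0
    nonlipid_dir /= nonlipid_total

    p = 0.95                      # lipid fraction inside a lipid body
    q = min(0.3 * lipid_total, 0.9 * lipid_total)  # residual lipid in cytoplasm
    if lipid_total >= p:           # extremely lipid-rich cell: clamp
        return c.copy(), c.copy(), 0.0
    m0 = (lipid_total - q) / (p - q)
    lipid_end = p * lipid_dir + (1.0 - p) * nonlipid_dir
    cyto_end = q * lipid_dir + (1.0 - q) * nonlipid_dir
    return lipid_end, cyto_end, float(m0)


def _ellipse_mask(target_area_um2: float, res_um: float, rng: np.random.Generator) -> MaskImage:
    """Rasterise a filled ellipse of approximately the target area."""
    aspect = rng.uniform(0.7, 1.0)
    # semi-axes in pixels: pi*a*b*res^2 = area
    ab = target_area_um2 / (math.pi * res_um**2)
    a = math.sqrt(ab / aspect)
    b = a * aspect
    pad = 3
    h = int(math.ceil(2 * b)) + 2 * pad
    w = int(math.ceil(2 * a)) + 2 * pad
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    pixels = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    if not pixels.any():
        pixels[h // 2, w // 2] = True
    return MaskImage(pixels=pixels, res_x=res_um, res_y=res_um)


def sample_population(config: SyntheticConfig) -> PopulationDataset:
    """Draw a synthetic yeast population under the configured study design.

    For each cell: sample an area (lognormal), rasterise a matching mask and
    classify its size from the *realised* mask area; draw the cell
    composition from a Dirichlet around the class mean; split it into
    lipid-body/cytoplasm endmembers; then render ``points_per_cell`` spectra
    whose per-point compositions mix the endmembers with Beta-distributed
    lipid-body fractions.  All randomness flows from ``config.seed`` through
    named substreams, so the dataset is reproducible bit-for-bit.
    """
    config.validate()
    grid = config.make_grid()
    library = default_band_library()
    comp_mat = component_spectra(library, grid)
    comp_stack = np.vstack([comp_mat[c] for c in COMPONENTS])  # (5, n_grid)

    # independent substreams per stochastic stage: adding a stage never
    # perturbs earlier draws
    ss = np.random.SeedSequence(config.seed)
    rng_size, rng_comp, rng_mix, rng_base, rng_noise, rng_mask = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    x = np.linspace(-1.0, 1.0, grid.size)
    cells: list[CellRecord] = []
    width = max(2, len(str(config.n_cells - 1)))
    for i in range(config.n_cells):
        cell_id = f"cell_{i:0{width}d}"
        target_area = float(rng_size.lognormal(config.area_logmean, config.area_logsd))
        mask = _ellipse_mask(target_area, config.mask_res_um, rng_mask)
        area = mask.n_pixels * mask.res_x * mask.res_y
        size_class = classify_size(area)

        mean = config.composition_means[size_class].as_array()
        if np.isinf(config.composition_concentration):
            comp = mean.copy()
        else:
            alpha = np.maximum(mean * config.composition_concentration, 1e-3)
            comp = rng_comp.dirichlet(alpha)
        composition = Composition(tuple(comp))

        lipid_end, cyto_end, m0 = _endmembers(composition)
        if np.isinf(config.mixing_concentration) or m0 in (0.0, 1.0):
            m = np.full(config.points_per_cell, m0)
        else:
            k = config.mixing_concentration
            m = rng_mix.beta(m0 * k, (1.0 - m0) * k, size=config.points_per_cell)

        point_comps = np.outer(m, lipid_end) + np.outer(1.0 - m, cyto_end)
        base_intensity = point_comps @ comp_stack  # (points, n_grid)

        c0 = rng_base.uniform(*config.baseline_const_range, size=config.points_per_cell)
        c1 = rng_base.uniform(*config.baseline_coeff_range, size=config.points_per_cell)
        c2 = rng_base.uniform(*config.baseline_coeff_range, size=config.points_per_cell)
        baseline = c0[:, None] + c1[:, None] * x[None, :] + c2[:, None] * x[None, :] ** 2
        intensity = base_intensity + baseline
        if config.noise_sd > 0:
            intensity = intensity + rng_noise.normal(
                0.0, config.noise_sd, size=intensity.shape
            )

        spectra = [
            Spectrum(
                wavenumbers=grid,
                intensities=intensity[j],
                cell_id=cell_id,
                point_id=f"p{j}",
            )
            for j in range(config.points_per_cell)
        ]
        cells.append(
            CellRecord(
                cell_id=cell_id,
                spectra=spectra,
                mask=mask,
                area=area,
                size_class=size_class,
                meta={
                    "composition": composition.as_dict(),
                    "lipid_body_fraction_mean": m0,
                    "outlier_injected": False,
                },
            )
        )

    return PopulationDataset(
        cells=cells,
        grid=grid,
        provenance={"generator": "optircell.synthetic", "config": config.to_dict()},
    )


#: Composition far from every size-class mean, used to displace injected
#: outlier cells (near-pure TAG with a carbohydrate remnant).
OUTLIER_COMPOSITION = Composition.from_dict(
    {"TAG": 0.75, "FFA": 0.02, "protein": 0.05, "carbohydrate": 0.15, "phosphate": 0.03}
)


def inject_outlier_cells(
    dataset: PopulationDataset,
    n: int,
    severity: float = 0.8,
    seed: int = 0,
) -> PopulationDataset:
    """Displace ``n`` random cells' chemistry far from the population mean.

    Each chosen cell's composition is moved a fraction ``severity`` of the
    way toward an extreme TAG-dominated composition and its spectra are
    re-rendered (same noise level and baseline ranges as the original run).
    Injected cells are flagged in ``cell.meta['outlier_injected']``.
    """
    if n < 0 or n > dataset.n_cells:
        raise ValueError(f"n must be in [0, {dataset.n_cells}], got {n}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if n == 0:
        return dataset
    config = SyntheticConfig.from_dict(dataset.provenance["config"])
    grid = dataset.grid
    library = default_band_library()
    comp_stack = np.vstack(
        [component_spectra(library, grid)[c] for c in COMPONENTS]
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(dataset.n_cells, size=n, replace=False)
    x = np.linspace(-1.0, 1.0, grid.size)
    extreme = OUTLIER_COMPOSITION.as_array()
    for idx in sorted(int(i) for i in chosen):
        cell = dataset.cells[idx]
        base = Composition.from_dict(cell.meta["composition"]).as_array()
        comp = Composition(tuple((1.0 - severity) * base + severity * extreme))
        lipid_end, cyto_end, m0 = _endmembers(comp)
        npts = len(cell.spectra)
        if np.isinf(config.mixing_concentration) or m0 in (0.0, 1.0):
            m = np.full(npts, m0)
        else:
            k = config.mixing_concentration
            m = rng.beta(m0 * k, (1.0 - m0) * k, size=npts)
        point_comps = np.outer(m, lipid_end) + np.outer(1.0 - m, cyto_end)
        intensity = point_comps @ comp_stack
        c0 = rng.uniform(*config.baseline_const_range, size=npts)
        c1 = rng.uniform(*config.baseline_coeff_range, size=npts)
        c2 = rng.uniform(*config.baseline_coeff_range, size=npts)
        intensity = intensity + (
            c0[:, None] + c1[:, None] * x[None, :] + c2[:, None] * x[None, :] ** 2
        )
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, size=intensity.shape)
        cell.spectra = [
            sp.replace(intensities=intensity[j]) for j, sp in enumerate(cell.spectra)
        ]
        cell.meta = dict(
            cell.meta, composition=comp.as_dict(), outlier_injected=True
        )
    dataset.provenance = dict(
        dataset.provenance,
        outliers_injected={"n": n, "severity": severity, "seed": seed},
    )
    return dataset
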