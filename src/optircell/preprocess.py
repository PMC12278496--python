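"""Spectral preprocessing: Savitzky–Golay second derivative, region
truncation, vector normalisation, and point-intensity extraction for the
sparse-wavenumber acquisition mode.

The canonical chain, applied in this order, is: second derivative
(polynomial order 2, window 35 points), truncation to an analysis region
(1780–1350 cm⁻¹ for lipids/proteins or 1200–1000 cm⁻¹ for cell-wall
carbohydrates), then scaling to unit Euclidean norm.  Derivatives are
reported per cm⁻¹ (the index-space Savitzky–Golay output divided by the
squared grid step); normalisation downstream makes the scaling immaterial,
but the contract is fixed so results are comparable across grids.

Savitzky–Golay values at the (window-1)/2 points nearest each grid edge come
from one-sided polynomial fits; on the default 950–1801 cm⁻¹ grid both
analysis regions lie well inside the interior, so no analysis depends on
edge behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import CellRecord, MODE_DERIVATIVE, MODE_RAW, PopulationDataset, Spectrum

#: The four wavenumbers of the sparse acquisition mode: protein (Amide I),
#: FFA carbonyl, TAG carbonyl, and the silent-region baseline reference.
SPARSE_WAVENUMBERS = {"protein": 1659.0, "FFA": 1714.0, "TAG": 1748.0}
BASELINE_REFERENCE = 1800.0

REGION_LIPID_PROTEIN = (1350.0, 1780.0)
REGION_CARBOHYDRATE = (1000.0, 1200.0)


@dataclass
class PreprocessConfig:
    """Savitzky–Golay and region settings for the preprocessing chain."""

    sg_window: int = 35
    sg_polyorder: int = 2
    sg_derivorder: int = 2
    region: tuple[float, float] = REGION_LIPID_PROTEIN
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        low, high = self.region
        if not low < high:
            raise ValueError("region must satisfy low < high")


def _check_uniform(spectrum: Spectrum) -> float:
    steps = np.diff(spectrum.wavenumbers)
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6, atol=0.0):
        raise ValueError("wavenumber grid is not uniform")
    return float(step)


def savitzky_golay_derivative(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky–Golay derivative of the configured order, per cm⁻¹.

    The grid must be uniform (within 1e-6 relative spacing tolerance) and at
    least as long as the filter window.
    """
    config = config or PreprocessConfig()
    if len(spectrum) < config.sg_window:
        raise ValueError(
            f"grid length {len(spectrum)} shorter than SG window {config.sg_window}"
        )
    step = _check_uniform(spectrum)
    deriv = savgol_filter(
        spectrum.intensities,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.sg_derivorder,
        delta=step,
    )
    return spectrum.replace(intensities=deriv, mode=MODE_DERIVATIVE)


def truncate(spectrum: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Keep grid points within [low, high] inclusive (no interpolation)."""
    low, high = region
    keep = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not keep.any():
        raise ValueError(f"region [{low}, {high}] contains no grid points")
    return spectrum.replace(
        wavenumbers=spectrum.wavenumbers[keep],
        intensities=spectrum.intensities[keep],
        region=f"{low:g}-{high:g}",
    )


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm.

    A spectrum whose norm is zero within numerical tolerance (e.g. the
    second derivative of a constant or linear spectrum, which is zero up to
    floating-point noise) is rejected.
    """
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm < 1e-9:
        raise ValueError(
            f"cannot normalise an (all-)zero spectrum (cell={spectrum.cell_id!r}, "
            f"point={spectrum.point_id!r})"
        )
    return spectrum.replace(intensities=spectrum.intensities / norm)


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Derivative → truncate → normalise, in that order."""
    config = config or PreprocessConfig()
    out = savitzky_golay_derivative(spectrum, config)
    out = truncate(out, config.region)
    if config.normalize:
        out = vector_normalize(out)
    return out


def preprocess_dataset(
    dataset: PopulationDataset, config: PreprocessConfig | None = None
) -> PopulationDataset:
    """Apply the preprocessing chain to every spectrum of a dataset.

    Cell metadata (masks, areas, size classes) is carried over unchanged;
    errors from any stage are re-raised with the offending spectrum id.
    """
    config = config or PreprocessConfig()
    new_cells = []
    new_grid = None
    for cell in dataset.cells:
        new_spectra = []
        for sp in cell.spectra:
            try:
                out = preprocess_spectrum(sp, config)
            except ValueError as exc:
                raise ValueError(
                    f"preprocessing failed for cell={sp.cell_id!r}, "
                    f"point={sp.point_id!r}: {exc}"
                ) from exc
            new_spectra.append(out)
            if new_grid is None:
                new_grid = out.wavenumbers
        new_cells.append(
            CellRecord(
                cell_id=cell.cell_id,
                spectra=new_spectra,
                mask=cell.mask,
                area=cell.area,
                size_class=cell.size_class,
                meta=dict(cell.meta),
            )
        )
    if new_grid is None:
        new_grid = dataset.grid
    provenance = dict(
        dataset.provenance,
        preprocessing={
            "sg_window": config.sg_window,
            "sg_polyorder": config.sg_polyorder,
            "sg_derivorder": config.sg_derivorder,
            "region": list(config.region),
            "normalize": config.normalize,
        },
    )
    return PopulationDataset(cells=new_cells, grid=new_grid, provenance=provenance)


def nearest_index(spectrum: Spectrum, target: float) -> int:
    """Index of the grid point nearest ``target``; ties go to the lower
    wavenumber.  ``target`` must lie within the grid range ± one step."""
    w = spectrum.wavenumbers
    step = _check_uniform(spectrum) if len(spectrum) > 1 else 0.0
    if target < w[0] - step - 1e-9 or target > w[-1] + step + 1e-9:
        raise ValueError(
            f"target {target} cm⁻¹ outside grid range [{w[0]}, {w[-1]}] ± one step"
        )
    # argmin returns the first minimiser; on an ascending grid that is the
    # lower wavenumber, which implements the tie rule
    return int(np.argmin(np.abs(w - target)))


def intensity_at(spectrum: Spectrum, target: float) -> float:
    """Intensity at the grid point nearest ``target`` (no interpolation)."""
    return float(spectrum.intensities[nearest_index(spectrum, target)])


@dataclass
class SparseIntensities:
    """Baseline-referenced intensities of the sparse acquisition mode.

    ``values[name]`` is intensity(band) − intensity(1800 cm⁻¹) for the three
    marker bands; ``resolved[name]`` records the actual grid wavenumber each
    request resolved to.
    """

    values: dict[str, float]
    resolved: dict[str, float]
    mode: str = MODE_RAW
    cell_id: str = ""
    point_id: str = ""


def sparse_intensities(spectrum: Spectrum) -> SparseIntensities:
    """Simulate four-wavenumber acquisition on one spectrum.

    Reads intensities at 1659, 1714 and 1748 cm⁻¹ and subtracts the value at
    the 1800 cm⁻¹ silent-region reference from each.
    """
    if spectrum.wavenumbers[-1] + 1e-9 < BASELINE_REFERENCE:
        raise ValueError(
            f"grid ends at {spectrum.wavenumbers[-1]} cm⁻¹ and does not cover "
            f"the {BASELINE_REFERENCE} cm⁻¹ baseline reference"
        )
    ref_idx = nearest_index(spectrum, BASELINE_REFERENCE)
    ref = float(spectrum.intensities[ref_idx])
    values: dict[str, float] = {}
    resolved: dict[str, float] = {"baseline": float(spectrum.wavenumbers[ref_idx])}
    for name, w in SPARSE_WAVENUMBERS.items():
        idx = nearest_index(spectrum, w)
        values[name] = float(spectrum.intensities[idx]) - ref
        resolved[name] = float(spectrum.wavenumbers[idx])
    return SparseIntensities(
        values=values,
        resolved=resolved,
        mode=spectrum.mode,
        cell_id=spectrum.cell_id,
        point_id=spectrum.point_id,
    )
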