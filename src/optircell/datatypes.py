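"""Core in-memory containers shared across the package.

The atom of the pipeline is a :class:`Spectrum`: one wavenumber grid plus one
intensity vector with acquisition metadata.  A :class:`CellRecord` bundles the
(typically six) point spectra of one cell with its segmentation mask, its
cross-section area in µm² and its size class; a :class:`PopulationDataset`
holds the whole measured (or simulated) population on one shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

SIZE_CLASSES = ("small", "mid", "large")

MODE_RAW = "raw"
MODE_DERIVATIVE = "derivative"


@dataclass
class Spectrum:
    """A single-point spectrum on an ascending wavenumber grid (cm⁻¹).

    Parameters
    ----------
    wavenumbers
        Strictly increasing grid in cm⁻¹.
    intensities
        Intensity values (arbitrary units), same length as the grid.
    cell_id, point_id
        Identifiers linking the spectrum to its cell and measurement point.
    mode
        ``"raw"`` for as-acquired intensities, ``"derivative"`` after
        Savitzky–Golay differentiation.
    region
        Optional label of the spectral window the spectrum was truncated to.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    cell_id: str = ""
    point_id: str = ""
    mode: str = MODE_RAW
    region: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"grid/intensity length mismatch: {self.wavenumbers.size} vs "
                f"{self.intensities.size} (cell={self.cell_id!r}, point={self.point_id!r})"
            )
        if self.wavenumbers.size == 0:
            raise ValueError("empty spectrum")
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(
                f"non-finite intensity (cell={self.cell_id!r}, point={self.point_id!r})"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Grid spacing (mean spacing; uniformity is checked where required)."""
        if len(self) < 2:
            raise ValueError("spacing undefined for a single-point grid")
        return float((self.wavenumbers[-1] - self.wavenumbers[0]) / (len(self) - 1))

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with selected fields replaced."""
        data = dict(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities,
            cell_id=self.cell_id,
            point_id=self.point_id,
            mode=self.mode,
            region=self.region,
        )
        data.update(kwargs)
        return Spectrum(**data)


@dataclass
class MaskImage:
    """Binary segmentation mask with pixel size in µm (one cell per mask)."""

    pixels: np.ndarray
    res_x: float
    res_y: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if self.pixels.size == 0:
            raise ValueError("mask has no pixels")
        if not (self.res_x > 0 and self.res_y > 0):
            raise ValueError(
                f"resolution must be positive, got res_x={self.res_x}, res_y={self.res_y}"
            )

    @property
    def n_pixels(self) -> int:
        """Number of pixels belonging to the cell (nonzero pixels)."""
        return int(self.pixels.sum())


@dataclass
class CellRecord:
    """One cell: its point spectra, mask, area (µm²) and size class."""

    cell_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    mask: MaskImage | None = None
    area: float | None = None
    size_class: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area is not None and not self.area > 0:
            raise ValueError(f"cell {self.cell_id!r}: area must be positive")
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


@dataclass
class PopulationDataset:
    """A population of cells sharing one wavenumber grid.

    ``provenance`` records how the dataset came to be (generator config and
    seed, or source file paths) so that every downstream table can be traced
    back to its inputs.
    """

    cells: list[CellRecord]
    grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell ids: {dupes}")
        for cell in self.cells:
            for sp in cell.spectra:
                if not np.array_equal(sp.wavenumbers, self.grid):
                    raise ValueError(
                        f"spectrum (cell={sp.cell_id!r}, point={sp.point_id!r}) "
                        "is not on the shared grid"
                    )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_spectra(self) -> int:
        return sum(c.n_spectra for c in self.cells)

    def spectra(self) -> Iterator[Spectrum]:
        """Iterate over all spectra in cell order."""
        for cell in self.cells:
            yield from cell.spectra

    def get_cell(self, cell_id: str) -> CellRecord:
        for cell in self.cells:
            if cell.cell_id == cell_id:
                return cell
        raise KeyError(cell_id)

    def intensity_matrix(self) -> np.ndarray:
        """All intensities stacked into an (n_spectra, n_wavenumbers) array."""
        return np.vstack([sp.intensities for sp in self.spectra()])
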