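"""Readers and writers for the on-disk formats.

Spectra travel as long/tidy CSV with columns
``cell_id,point_id,wavenumber_cm1,intensity`` — one row per grid point, one
complete grid per (cell, point) pair.  Segmentation masks are 8-bit grayscale
PNGs (nonzero = cell) with a JSON sidecar giving the pixel size in µm:
``{"res_x_um_per_px": ..., "res_y_um_per_px": ...}``.

Wavenumbers are stored ascending throughout, even though acquisition ranges
are conventionally quoted high-to-low.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import CellRecord, MaskImage, PopulationDataset, Spectrum

SPECTRA_COLUMNS = ("cell_id", "point_id", "wavenumber_cm1", "intensity")


def read_spectra_table(path: str | Path) -> PopulationDataset:
    """Read a long-format spectra CSV into a :class:`PopulationDataset`.

    Rows may appear in any order; each (cell_id, point_id) group must contain
    one complete copy of the shared wavenumber grid.

    Raises
    ------
    ValueError
        If a required column is missing, an intensity is non-finite (the row
        number is reported), or the grids are inconsistent across spectra
        (the offending spectrum ids are listed).
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"cell_id": str, "point_id": str}, float_precision="round_trip"
    )
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return PopulationDataset(cells=[], grid=np.array([]), provenance={"source": str(path)})

    bad = ~np.isfinite(df["intensity"].to_numpy(dtype=float))
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-finite intensity at file row {row}")

    grid: np.ndarray | None = None
    mismatched: list[tuple[str, str]] = []
    cells: dict[str, CellRecord] = {}
    for (cell_id, point_id), group in df.groupby(["cell_id", "point_id"], sort=True):
        order = np.argsort(group["wavenumber_cm1"].to_numpy(dtype=float), kind="stable")
        w = group["wavenumber_cm1"].to_numpy(dtype=float)[order]
        y = group["intensity"].to_numpy(dtype=float)[order]
        if grid is None:
            grid = w
        elif w.shape != grid.shape or not np.array_equal(w, grid):
            mismatched.append((cell_id, point_id))
            continue
        sp = Spectrum(wavenumbers=w, intensities=y, cell_id=cell_id, point_id=point_id)
        cells.setdefault(cell_id, CellRecord(cell_id=cell_id)).spectra.append(sp)
    if mismatched:
        ids = ", ".join(f"({c},{p})" for c, p in mismatched)
        raise ValueError(f"{path}: wavenumber grid differs from the first spectrum for: {ids}")

    return PopulationDataset(
        cells=list(cells.values()), grid=grid, provenance={"source": str(path)}
    )


def write_spectra_table(dataset: PopulationDataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV (full float precision, round-trips)."""
    path = Path(path)
    frames = []
    for sp in dataset.spectra():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": sp.cell_id,
                    "point_id": sp.point_id,
                    "wavenumber_cm1": sp.wavenumbers,
                    "intensity": sp.intensities,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(SPECTRA_COLUMNS))
    # %.17g guarantees binary round-trip of doubles
    out.to_csv(path, index=False, float_format="%.17g")


def read_mask(path_png: str | Path, path_sidecar: str | Path) -> MaskImage:
    """Read an 8-bit PNG mask and its JSON resolution sidecar.

    Any nonzero pixel belongs to the cell.  The sidecar must provide positive
    ``res_x_um_per_px`` and ``res_y_um_per_px``.
    """
    path_sidecar = Path(path_sidecar)
    if not path_sidecar.exists():
        raise FileNotFoundError(f"mask sidecar not found: {path_sidecar}")
    with open(path_sidecar) as fh:
        meta = json.load(fh)
    try:
        res_x = float(meta["res_x_um_per_px"])
        res_y = float(meta["res_y_um_per_px"])
    except KeyError as exc:
        raise ValueError(f"{path_sidecar}: missing key {exc}") from exc
    pixels = np.asarray(Image.open(path_png).convert("L"))
    return MaskImage(pixels=pixels > 0, res_x=res_x, res_y=res_y)


def write_mask(mask: MaskImage, path_png: str | Path, path_sidecar: str | Path) -> None:
    """Write a mask as 8-bit PNG (cell pixels = 255) plus JSON sidecar."""
    img = Image.fromarray((mask.pixels.astype(np.uint8)) * 255, mode="L")
    img.save(Path(path_png))
    with open(Path(path_sidecar), "w") as fh:
        json.dump(
            {"res_x_um_per_px": mask.res_x, "res_y_um_per_px": mask.res_y}, fh, indent=2
        )
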