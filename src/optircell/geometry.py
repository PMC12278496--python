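"""Cell cross-section areas from segmentation masks and size classification.

Areas are the nonzero-pixel count of the mask times the pixel size in X and
Y (µm per pixel).  Cells are partitioned into three size classes: *small*
(< 6 µm²), *mid* (6–12 µm², both endpoints included) and *large* (> 12 µm²).
"""

from __future__ import annotations

import pandas as pd

from .datatypes import CellRecord, MaskImage, PopulationDataset, SIZE_CLASSES  # noqa: F401

SMALL_MAX_UM2 = 6.0
MID_MAX_UM2 = 12.0


def mask_area(mask: MaskImage) -> float:
    """Cross-section area in µm²: nonzero pixel count × res_x × res_y."""
    n = mask.n_pixels
    if n == 0:
        raise ValueError("mask is empty: no nonzero pixels")
    return float(n * mask.res_x * mask.res_y)


def classify_size(area: float) -> str:
    """Map an area in µm² to ``small`` / ``mid`` / ``large``.

    The boundaries 6.0 and 12.0 µm² belong to *mid* (the strict inequalities
    define small and large).
    """
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    if area < SMALL_MAX_UM2:
        return "small"
    if area <= MID_MAX_UM2:
        return "mid"
    return "large"


def attach_geometry(dataset: PopulationDataset) -> PopulationDataset:
    """Fill in ``area`` and ``size_class`` for every cell that has a mask."""
    for cell in dataset.cells:
        if cell.mask is not None:
            cell.area = mask_area(cell.mask)
            cell.size_class = classify_size(cell.area)
    return dataset


def geometry_table(dataset: PopulationDataset) -> pd.DataFrame:
    """Per-cell table of areas and size classes (``cell_id,area_um2,size_class``)."""
    rows = [
        {"cell_id": c.cell_id, "area_um2": c.area, "size_class": c.size_class}
        for c in dataset.cells
    ]
    return pd.DataFrame(rows, columns=["cell_id", "area_um2", "size_class"])
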