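"""Pearson-distance heterogeneity statistics for a cell population.

Chemical variability is quantified as the Pearson distance 1−PCC between
spectra, which lies in [0, 2]: 0 for identical chemical profiles (up to a
positive affine transform), 2 for perfectly anticorrelated ones.

*Intra-cell* variability is the mean Pearson distance from each of a cell's
point spectra to the cell centroid (the average spectrum of that cell).
*Inter-cell* variability is the Pearson distance between a cell centroid and
the population centroid (the average over all measured spectra).  Outliers
in either statistic are flagged by the 1.5×IQR rule.  The intra-vs-inter
relationship is summarised by ordinary least squares, and variability in two
spectral regions is compared via Spearman rank correlation of per-cell
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CellRecord, PopulationDataset, Spectrum
from .preprocess import PreprocessConfig, preprocess_dataset


def pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − sample Pearson correlation between two equal-length vectors.

    Both vectors must have length ≥ 3 and be non-constant (the correlation
    is undefined for a constant vector).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 points for a Pearson distance")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("Pearson distance undefined for a constant vector")
    r = float(np.dot(da, db) / (na * nb))
    # clip numerical excursions a hair outside [-1, 1]
    return 1.0 - max(-1.0, min(1.0, r))


def cell_centroid(cell: CellRecord) -> Spectrum:
    """Pointwise mean of a cell's spectra on their shared grid."""
    if not cell.spectra:
        raise ValueError(f"cell {cell.cell_id!r} has no spectra")
    grid = cell.spectra[0].wavenumbers
    for sp in cell.spectra[1:]:
        if not np.array_equal(sp.wavenumbers, grid):
            raise ValueError(f"cell {cell.cell_id!r}: spectra on mixed grids")
    mean = np.mean([sp.intensities for sp in cell.spectra], axis=0)
    return Spectrum(
        wavenumbers=grid,
        intensities=mean,
        cell_id=cell.cell_id,
        point_id="centroid",
        mode=cell.spectra[0].mode,
        region=cell.spectra[0].region,
    )


def population_centroid(dataset: PopulationDataset) -> Spectrum:
    """Pointwise mean over ALL spectra in the dataset (not over cell
    centroids — the two differ for unbalanced designs)."""
    if dataset.n_spectra == 0:
        raise ValueError("dataset has no spectra")
    mean = dataset.intensity_matrix().mean(axis=0)
    first = next(dataset.spectra())
    return Spectrum(
        wavenumbers=dataset.grid,
        intensities=mean,
        cell_id="population",
        point_id="centroid",
        mode=first.mode,
        region=first.region,
    )


def intra_cell_variability(cell: CellRecord) -> float:
    """Mean Pearson distance from each point spectrum to the cell centroid."""
    if len(cell.spectra) < 2:
        raise ValueError(f"cell {cell.cell_id!r}: need ≥ 2 spectra")
    centroid = cell_centroid(cell)
    return float(
        np.mean(
            [pearson_distance(sp.intensities, centroid.intensities) for sp in cell.spectra]
        )
    )


def inter_cell_variability(cell: CellRecord, pop_centroid: Spectrum) -> float:
    """Pearson distance between the cell centroid and the population centroid."""
    return pearson_distance(cell_centroid(cell).intensities, pop_centroid.intensities)


def iqr_outliers(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation between order statistics (the
    default "type 7" convention of ``numpy.percentile``).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for IQR outlier flagging")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - multiplier * iqr) | (values > q3 + multiplier * iqr)


def variability_table(dataset: PopulationDataset, region_label: str | None = None) -> pd.DataFrame:
    """Per-cell intra/inter variability with 1.5×IQR outlier flags.

    Expects a *preprocessed* dataset (derivative, truncated, normalised).
    Returns columns ``cell_id, region, intra, inter, intra_outlier,
    inter_outlier``.
    """
    if dataset.n_cells < 1:
        raise ValueError("empty dataset")
    pop = population_centroid(dataset)
    region = region_label or (next(dataset.spectra()).region or "")
    rows = []
    for cell in dataset.cells:
        rows.append(
            {
                "cell_id": cell.cell_id,
                "region": region,
                "intra": intra_cell_variability(cell),
                "inter": inter_cell_variability(cell, pop),
            }
        )
    df = pd.DataFrame(rows)
    df["intra_outlier"] = iqr_outliers(df["intra"].to_numpy())
    df["inter_outlier"] = iqr_outliers(df["inter"].to_numpy())
    return df


@dataclass
class RegressionSummary:
    """OLS fit of intra-cell (y) on inter-cell (x) variability."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    outliers_excluded: bool

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "outliers_excluded": self.outliers_excluded,
        }


def variability_regression(
    records: pd.DataFrame, exclude_outliers: bool = False
) -> RegressionSummary:
    """Regress intra-cell on inter-cell variability across cells.

    With ``exclude_outliers``, cells flagged in either the intra or the
    inter 1.5×IQR rule are dropped before fitting.  At least three points
    must remain.
    """
    df = records
    if exclude_outliers:
        df = df[~(df["intra_outlier"] | df["inter_outlier"])]
    if len(df) < 3:
        raise ValueError(f"need ≥ 3 points for regression, have {len(df)}")
    res = stats.linregress(df["inter"].to_numpy(), df["intra"].to_numpy())
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(len(df)),
        outliers_excluded=bool(exclude_outliers),
    )


def _per_cell_distances(
    dataset: PopulationDataset, region: tuple[float, float], metric: str
) -> pd.Series:
    pre = preprocess_dataset(dataset, PreprocessConfig(region=region))
    pop = population_centroid(pre)
    out = {}
    for cell in pre.cells:
        c = cell_centroid(cell)
        if metric == "pearson_distance":
            out[cell.cell_id] = pearson_distance(c.intensities, pop.intensities)
        elif metric == "euclidean":
            out[cell.cell_id] = float(np.linalg.norm(c.intensities - pop.intensities))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return pd.Series(out)


def cross_region_correlation(
    dataset: PopulationDataset,
    region_a: tuple[float, float],
    region_b: tuple[float, float],
    metric: str = "pearson_distance",
) -> tuple[float, float]:
    """Spearman correlation of per-cell distances between two regions.

    The raw dataset is preprocessed independently per region; each cell
    contributes one centroid-to-population distance per region (under
    ``pearson_distance`` or ``euclidean``), and the two per-cell vectors are
    rank-correlated.  Returns ``(rho, p_value)``.
    """
    da = _per_cell_distances(dataset, region_a, metric)
    db = _per_cell_distances(dataset, region_b, metric)
    if len(da) < 3 or len(db) < 3:
        raise ValueError("need at least 3 cells per region")
    db = db.reindex(da.index)
    rho, p = stats.spearmanr(da.to_numpy(), db.to_numpy())
    return float(rho), float(p)
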