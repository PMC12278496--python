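"""PCA, lipid band-ratio chemistry and group statistics.

Three band ratios act as composition proxies, built from intensities at the
TAG carbonyl (1748 cm⁻¹), FFA carbonyl (1714 cm⁻¹) and Amide I
(1659 cm⁻¹) bands:

* ``r_tag_ffa``  = i(1748)/i(1714) — TAG relative to FFA,
* ``r_tag_prot`` = i(1748)/i(1659) — TAG relative to protein,
* ``r_ffa_prot`` = i(1714)/i(1659) — FFA relative to protein.

In *broadband* mode the intensities are read from preprocessed
(second-derivative, vector-normalised) spectra with a −0.1 offset added to
both numerator and denominator to keep denominators away from zero; in
*sparse* mode they are the baseline-referenced raw intensities of the
four-wavenumber acquisition simulation, with no offset.  Second-derivative
values are used as they are (negative at absorbance peaks); no negation is
applied, though :func:`ratio_table` exposes a switch for exploration.

Group differences of ``r_tag_ffa`` across the three size classes are tested
with a hand-implemented tie-corrected Kruskal–Wallis H (chi-square
approximation), gated by a Shapiro–Wilk normality check that motivates the
rank-based test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import PopulationDataset
from .preprocess import SPARSE_WAVENUMBERS, intensity_at, sparse_intensities

BROADBAND_OFFSET = -0.1


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores, unit-norm loadings and explained variance per component.

    Component signs are fixed so that each loading's largest-magnitude
    element is positive (PCA signs are otherwise arbitrary).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray
    mean_spectrum: np.ndarray
    grid: np.ndarray


def pca_spectra(dataset: PopulationDataset, n_components: int = 5) -> PCAResult:
    """Mean-centred PCA of all individual preprocessed spectra.

    Scores index is (cell_id, point_id); loadings columns are the region
    grid wavenumbers.
    """
    X = dataset.intensity_matrix()
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_spectra, grid length)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    index = pd.MultiIndex.from_tuples(
        [(sp.cell_id, sp.point_id) for sp in dataset.spectra()],
        names=["cell_id", "point_id"],
    )
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=dataset.grid),
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        mean_spectrum=pca.mean_,
        grid=dataset.grid,
    )


# ---------------------------------------------------------------------------
# band ratios
# ---------------------------------------------------------------------------

def band_ratio(numerator: float, denominator: float, offset: float = 0.0) -> float:
    """(numerator + offset) / (denominator + offset).

    The offset is added to *both* values, shifting the whole intensity scale
    away from zero rather than biasing one side of the ratio.
    """
    den = denominator + offset
    if den == 0.0:
        raise ValueError("shifted denominator is zero")
    return (numerator + offset) / den


def ratio_table(
    dataset: PopulationDataset,
    mode: str,
    offset: float | None = None,
    negate: bool = False,
) -> pd.DataFrame:
    """Per-spectrum band-ratio records with size classes attached.

    ``mode="broadband"`` expects a preprocessed dataset whose region covers
    the three marker bands and uses offset −0.1 by default;
    ``mode="sparse"`` expects raw spectra covering the 1800 cm⁻¹ reference
    and uses offset 0.  ``negate`` flips the sign of second-derivative
    intensities before the offset is applied (off by default).
    """
    if mode not in ("broadband", "sparse"):
        raise ValueError(f"mode must be 'broadband' or 'sparse', got {mode!r}")
    if offset is None:
        offset = BROADBAND_OFFSET if mode == "broadband" else 0.0
    rows = []
    for cell in dataset.cells:
        for sp in cell.spectra:
            if mode == "broadband":
                vals = {
                    name: intensity_at(sp, w) for name, w in SPARSE_WAVENUMBERS.items()
                }
            else:
                vals = sparse_intensities(sp).values
            if negate:
                vals = {k: -v for k, v in vals.items()}
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "point_id": sp.point_id,
                    "size_class": cell.size_class,
                    "mode": mode,
                    "offset": offset,
                    "i_tag": vals["TAG"],
                    "i_ffa": vals["FFA"],
                    "i_protein": vals["protein"],
                    "r_tag_ffa": band_ratio(vals["TAG"], vals["FFA"], offset),
                    "r_tag_prot": band_ratio(vals["TAG"], vals["protein"], offset),
                    "r_ffa_prot": band_ratio(vals["FFA"], vals["protein"], offset),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Result of a Shapiro–Wilk or Kruskal–Wallis test."""

    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    tie_corrected: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
            "tie_corrected": self.tie_corrected,
        }


def shapiro_wilk(values: np.ndarray) -> GroupTestResult:
    """Shapiro–Wilk normality test (delegates to scipy)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 values")
    if np.ptp(values) == 0.0:
        raise ValueError("Shapiro–Wilk undefined for constant input")
    w, p = stats.shapiro(values)
    return GroupTestResult(
        statistic=float(w), p_value=float(p), group_sizes={"all": int(values.size)}
    )


def kruskal_wallis(values: np.ndarray, group_labels: np.ndarray) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p-value.

    H = 12/(N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)², divided by the tie correction
    1 − Σ(t³−t)/(N³−N); p comes from the chi-square distribution with k−1
    degrees of freedom.  An all-tied input returns H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise ValueError("values and group_labels must have equal length")
    labels = pd.unique(group_labels)
    if len(labels) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 groups")
    sizes = {str(lab): int(np.sum(group_labels == lab)) for lab in labels}
    if any(n == 0 for n in sizes.values()):
        raise ValueError("every group must be nonempty")

    n_total = values.size
    ranks = stats.rankdata(values)  # midranks for ties
    h = 0.0
    for lab in labels:
        sel = group_labels == lab
        h += sel.sum() * (ranks[sel].mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))

    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    tie_corrected = tie_term > 0
    if correction == 0.0:  # every value identical
        return GroupTestResult(0.0, 1.0, sizes, tie_corrected=True)
    h /= correction
    p = float(stats.chi2.sf(h, df=len(labels) - 1))
    return GroupTestResult(float(h), p, sizes, tie_corrected=tie_corrected)


def size_group_comparison(records: pd.DataFrame, ratio: str = "r_tag_ffa") -> dict:
    """Compare a band ratio across size classes.

    Reports the Shapiro–Wilk gate on the pooled ratio values (the reason a
    rank-based test is used), the Kruskal–Wallis test across size classes,
    and per-class medians and sizes.
    """
    present = records.dropna(subset=["size_class"])
    classes = present["size_class"].unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 size classes for a group comparison")
    values = present[ratio].to_numpy(dtype=float)
    labels = present["size_class"].to_numpy()
    gate = shapiro_wilk(values)
    kw = kruskal_wallis(values, labels)
    medians = present.groupby("size_class")[ratio].median().to_dict()
    return {
        "ratio": ratio,
        "shapiro_wilk": gate.as_dict(),
        "kruskal_wallis": kw.as_dict(),
        "medians": medians,
        "group_sizes": kw.group_sizes,
    }
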