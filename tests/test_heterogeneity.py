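"""Pearson-distance statistics: centroids, intra/inter variability, IQR
outliers, regression and cross-region correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import optircell as oc
from optircell.datatypes import CellRecord, PopulationDataset, Spectrum
from optircell.heterogeneity import RegressionSummary  # noqa: F401


def spectra_from_matrix(X, cell_id="c", start=1000.0):
    grid = start + 0.5 * np.arange(X.shape[1])
    return [
        Spectrum(wavenumbers=grid, intensities=row, cell_id=cell_id, point_id=f"p{i}")
        for i, row in enumerate(X)
    ]


class TestPearsonDistance:
    def test_identity_and_affine(self, rng):
        a = rng.normal(size=20)
        assert oc.pearson_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert oc.pearson_distance(a, 2.0 * a + 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        assert oc.pearson_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            oc.pearson_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            oc.pearson_distance([1.0, 2.0], [2.0, 1.0])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=30).filter(
            lambda v: np.ptp(v) > 1e-6
        ),
        st.floats(0.1, 10.0),
        st.floats(-100.0, 100.0),
    )
    def test_affine_invariance_property(self, values, scale, shift):
        a = np.asarray(values)
        b = np.sin(a) + np.linspace(0, 1, a.size)  # some non-constant partner
        if np.ptp(b) <= 1e-9:
            return
        d1 = oc.pearson_distance(a, b)
        d2 = oc.pearson_distance(scale * a + shift, b)
        assert d1 == pytest.approx(d2, abs=1e-8)
        assert 0.0 <= d1 <= 2.0


class TestCentroids:
    def test_cell_centroid_equals_column_means(self, rng):
        X = rng.normal(size=(6, 30))
        cell = CellRecord(cell_id="c", spectra=spectra_from_matrix(X))
        np.testing.assert_allclose(
            oc.cell_centroid(cell).intensities, X.mean(axis=0), atol=1e-14
        )

    def test_opposite_spectra_cancel(self):
        x = np.linspace(0, 1, 20)
        cell = CellRecord(cell_id="c", spectra=spectra_from_matrix(np.vstack([x, -x])))
        np.testing.assert_allclose(oc.cell_centroid(cell).intensities, 0.0, atol=1e-15)

    def test_population_centroid_weights_spectra_not_cells(self, rng):
        """With unbalanced point counts the population centroid differs from
        the mean of cell centroids."""
        grid = 1000.0 + 0.5 * np.arange(30)
        X1 = rng.normal(size=(3, 30))
        X2 = rng.normal(size=(6, 30))
        cells = [
            CellRecord(cell_id="a", spectra=spectra_from_matrix(X1, "a")),
            CellRecord(cell_id="b", spectra=spectra_from_matrix(X2, "b")),
        ]
        ds = PopulationDataset(cells=cells, grid=grid)
        pop = oc.population_centroid(ds).intensities
        all_mean = np.vstack([X1, X2]).mean(axis=0)
        centroid_mean = (X1.mean(axis=0) + X2.mean(axis=0)) / 2.0
        np.testing.assert_allclose(pop, all_mean, atol=1e-14)
        assert not np.allclose(pop, centroid_mean)

    def test_balanced_design_identity(self, preprocessed_dataset):
        pop = oc.population_centroid(preprocessed_dataset).intensities
        cell_means = np.mean(
            [oc.cell_centroid(c).intensities for c in preprocessed_dataset.cells],
            axis=0,
        )
        np.testing.assert_allclose(pop, cell_means, atol=1e-12)


class TestVariability:
    def test_identical_spectra_give_zero_intra(self):
        x = np.sin(np.linspace(0, 6, 40))
        cell = CellRecord(cell_id="c", spectra=spectra_from_matrix(np.tile(x, (6, 1))))
        assert oc.intra_cell_variability(cell) == pytest.approx(0.0, abs=1e-12)

    def test_perturbation_gives_positive_intra(self, rng):
        x = np.sin(np.linspace(0, 6, 40))
        X = x + 0.1 * rng.normal(size=(6, 40))
        cell = CellRecord(cell_id="c", spectra=spectra_from_matrix(X))
        assert oc.intra_cell_variability(cell) > 0

    def test_identical_population_gives_zero_inter(self):
        x = np.sin(np.linspace(0, 6, 40))
        grid = 1000.0 + 0.5 * np.arange(40)
        cells = [
            CellRecord(cell_id=f"c{i}", spectra=spectra_from_matrix(np.tile(x, (3, 1)), f"c{i}"))
            for i in range(5)
        ]
        ds = PopulationDataset(cells=cells, grid=grid)
        pop = oc.population_centroid(ds)
        for cell in cells:
            assert oc.inter_cell_variability(cell, pop) == pytest.approx(0.0, abs=1e-12)

    def test_mixing_variance_increases_intra(self):
        """4× the domain-mixing variance raises the median intra value."""
        base = oc.SyntheticConfig(seed=77, mixing_concentration=12.0)
        # Beta variance scales as 1/(k+1): k 12 → 2.25 quadruples it
        wide = oc.SyntheticConfig(seed=77, mixing_concentration=2.25)
        med = {}
        for name, cfg in (("base", base), ("wide", wide)):
            pre = oc.preprocess_dataset(oc.sample_population(cfg))
            med[name] = oc.variability_table(pre)["intra"].median()
        assert med["wide"] > med["base"]


class TestIqrOutliers:
    def test_constant_values_unflagged(self):
        assert not oc.iqr_outliers([1, 1, 1, 1, 1]).any()

    def test_hand_computed_example(self):
        # sorted [1,2,2,2,3,50]: Q1=2, Q3=2.75 (type-7), fences [0.875, 3.875]
        flags = oc.iqr_outliers([1, 2, 2, 2, 3, 50])
        np.testing.assert_array_equal(flags, [False] * 5 + [True])

    def test_symmetric_data_unflagged(self):
        assert not oc.iqr_outliers([1, 2, 3, 4, 5, 6, 7]).any()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            oc.iqr_outliers([1.0, 2.0, 3.0])


class TestRegression:
    def make_records(self, intra, inter):
        import pandas as pd

        df = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(intra))],
                           "intra": intra, "inter": inter})
        df["intra_outlier"] = oc.iqr_outliers(df["intra"].to_numpy())
        df["inter_outlier"] = oc.iqr_outliers(df["inter"].to_numpy())
        return df

    def test_perfect_line(self):
        x = np.linspace(0.1, 1.0, 10)
        res = oc.variability_regression(self.make_records(x, x))
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_variables_near_zero_r2(self, rng):
        intra = rng.normal(size=2000)
        inter = rng.normal(size=2000)
        res = oc.variability_regression(self.make_records(intra, inter))
        assert res.r_squared < 0.01

    def test_outlier_removal_changes_r2(self, rng):
        intra = rng.normal(0.1, 0.01, size=30)
        inter = rng.normal(0.1, 0.01, size=30)
        intra[0], inter[0] = 1.0, 1.0  # high-leverage point
        df = self.make_records(intra, inter)
        with_out = oc.variability_regression(df, exclude_outliers=False)
        without = oc.variability_regression(df, exclude_outliers=True)
        assert without.n_points < with_out.n_points
        assert abs(with_out.r_squared - without.r_squared) > 0.01

    def test_too_few_points_after_exclusion(self):
        df = self.make_records([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            oc.variability_regression(df.iloc[:2])


class TestCrossRegionCorrelation:
    def test_identical_regions_give_rho_one(self, default_dataset):
        region = (1350.0, 1780.0)
        rho, _ = oc.cross_region_correlation(default_dataset, region, region)
        assert rho == pytest.approx(1.0)

    def test_matches_rank_oracle(self, default_dataset):
        from optircell.heterogeneity import _per_cell_distances

        ra, rb = (1350.0, 1780.0), (1000.0, 1200.0)
        rho, _ = oc.cross_region_correlation(default_dataset, ra, rb)
        da = _per_cell_distances(default_dataset, ra, "pearson_distance")
        db = _per_cell_distances(default_dataset, rb, "pearson_distance").reindex(da.index)
        # independent oracle: rank both vectors, then Pearson on the ranks
        oracle = np.corrcoef(stats.rankdata(da), stats.rankdata(db))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_euclidean_metric_runs(self, default_dataset):
        rho, p = oc.cross_region_correlation(
            default_dataset, (1350.0, 1780.0), (1000.0, 1200.0), metric="euclidean"
        )
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0
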