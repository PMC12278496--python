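"""Savitzky–Golay derivative (against a sliding-polyfit oracle), truncation,
normalisation and sparse point-intensity extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import optircell as oc
from optircell.preprocess import nearest_index
from optircell.synthetic import COMPONENTS, Composition, default_band_library


def sg_oracle_second_derivative(y, x, window, polyorder=2):
    """Independent oracle: sliding least-squares quadratic fit; the second
    derivative at the window centre is 2 × the quadratic coefficient."""
    half = window // 2
    out = np.full_like(y, np.nan, dtype=float)
    for i in range(half, len(y) - half):
        xs = x[i - half: i + half + 1] - x[i]
        ys = y[i - half: i + half + 1]
        coeffs = np.polyfit(xs, ys, polyorder)
        out[i] = 2.0 * coeffs[polyorder - 2]
    return out


def make_spectrum(intensities, start=1000.0, step=0.5):
    w = start + step * np.arange(len(intensities))
    return oc.Spectrum(wavenumbers=w, intensities=np.asarray(intensities, float))


class TestSavitzkyGolay:
    def test_quadratic_gives_constant_two(self):
        w = 950.0 + 0.5 * np.arange(1703)
        sp = oc.Spectrum(wavenumbers=w, intensities=(w - 1500.0) ** 2)
        out = oc.savitzky_golay_derivative(sp)
        interior = out.intensities[17:-17]
        np.testing.assert_allclose(interior, 2.0, rtol=1e-9)
        assert out.mode == "derivative"

    def test_linear_gives_zero_interior(self):
        sp = make_spectrum(3.0 * np.arange(200) + 7.0)
        out = oc.savitzky_golay_derivative(sp)
        np.testing.assert_allclose(out.intensities[17:-17], 0.0, atol=1e-9)

    def test_matches_sliding_polyfit_oracle(self, rng):
        sp = make_spectrum(rng.normal(size=300))
        out = oc.savitzky_golay_derivative(sp)
        oracle = sg_oracle_second_derivative(sp.intensities, sp.wavenumbers, 35)
        interior = slice(17, -17)
        np.testing.assert_allclose(
            out.intensities[interior], oracle[interior], rtol=1e-9, atol=1e-12
        )

    def test_grid_shorter_than_window_rejected(self):
        sp = make_spectrum(np.arange(20.0))
        with pytest.raises(ValueError, match="window"):
            oc.savitzky_golay_derivative(sp)

    def test_nonuniform_grid_rejected(self):
        w = np.concatenate([np.arange(50.0), [50.5], np.arange(52, 80.0)])
        sp = oc.Spectrum(wavenumbers=w, intensities=np.zeros_like(w))
        with pytest.raises(ValueError, match="uniform"):
            oc.savitzky_golay_derivative(sp)


class TestTruncate:
    @pytest.mark.parametrize(
        "region,expected", [((1350.0, 1780.0), 861), ((1000.0, 1200.0), 401)]
    )
    def test_default_regions_point_counts(self, region, expected):
        sp = oc.Spectrum(
            wavenumbers=oc.SyntheticConfig().make_grid(),
            intensities=np.zeros(1703),
        )
        out = oc.truncate(sp, region)
        assert len(out) == expected
        assert out.wavenumbers[0] == region[0] and out.wavenumbers[-1] == region[1]

    def test_empty_region_rejected(self):
        sp = make_spectrum(np.zeros(100))
        with pytest.raises(ValueError, match="no grid points"):
            oc.truncate(sp, (2000.0, 2100.0))

    def test_contiguous_subgrid(self, rng):
        sp = make_spectrum(rng.normal(size=200))
        out = oc.truncate(sp, (1020.0, 1050.0))
        i0 = np.searchsorted(sp.wavenumbers, out.wavenumbers[0])
        np.testing.assert_array_equal(
            out.wavenumbers, sp.wavenumbers[i0: i0 + len(out)]
        )
        np.testing.assert_array_equal(
            out.intensities, sp.intensities[i0: i0 + len(out)]
        )


class TestVectorNormalize:
    def test_three_four_five(self):
        out = oc.vector_normalize(make_spectrum([3.0, 4.0]))
        np.testing.assert_allclose(out.intensities, [0.6, 0.8])

    def test_scale_invariance_and_idempotence(self, rng):
        x = rng.normal(size=50)
        a = oc.vector_normalize(make_spectrum(x))
        b = oc.vector_normalize(make_spectrum(5.0 * x))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-15)
        again = oc.vector_normalize(a)
        np.testing.assert_allclose(again.intensities, a.intensities, atol=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            oc.vector_normalize(make_spectrum(np.zeros(10)))


class TestPreprocessDataset:
    def test_full_chain_counts_and_norms(self, preprocessed_dataset):
        assert preprocessed_dataset.n_spectra == 240
        for sp in preprocessed_dataset.spectra():
            assert len(sp) == 861
            assert np.linalg.norm(sp.intensities) == pytest.approx(1.0, abs=1e-12)
            assert sp.mode == "derivative"

    def test_normalize_off_leaves_norms_varying(self, default_dataset):
        pre = oc.preprocess_dataset(
            default_dataset, oc.PreprocessConfig(normalize=False)
        )
        norms = [np.linalg.norm(sp.intensities) for sp in pre.spectra()]
        assert np.std(norms) > 0

    def test_constant_spectrum_fails_with_id(self):
        grid = 950.0 + 0.5 * np.arange(1703)
        sp = oc.Spectrum(wavenumbers=grid, intensities=np.full(1703, 2.5),
                         cell_id="c1", point_id="p0")
        ds = oc.PopulationDataset(
            cells=[oc.CellRecord(cell_id="c1", spectra=[sp])], grid=grid
        )
        with pytest.raises(ValueError, match="c1"):
            oc.preprocess_dataset(ds)

    def test_chain_is_scale_invariant(self, default_dataset):
        """Derivative is linear and normalisation removes scale, so doubling
        intensities leaves the preprocessed spectra unchanged."""
        cell = default_dataset.cells[0]
        sp = cell.spectra[0]
        cfg = oc.PreprocessConfig()
        a = oc.vector_normalize(
            oc.truncate(oc.savitzky_golay_derivative(sp, cfg), cfg.region)
        )
        doubled = sp.replace(intensities=2.0 * sp.intensities)
        b = oc.vector_normalize(
            oc.truncate(oc.savitzky_golay_derivative(doubled, cfg), cfg.region)
        )
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-14)


class TestPointIntensities:
    def test_exact_and_nearest_and_tie(self):
        sp = make_spectrum(np.arange(100.0), start=1700.0, step=0.5)
        assert oc.intensity_at(sp, 1714.0) == sp.intensities[28]
        assert oc.intensity_at(sp, 1714.2) == sp.intensities[28]
        # equidistant request resolves to the lower wavenumber
        assert oc.intensity_at(sp, 1714.25) == sp.intensities[28]
        assert sp.wavenumbers[nearest_index(sp, 1714.25)] == 1714.0

    def test_outside_tolerance_rejected(self):
        sp = make_spectrum(np.arange(10.0), start=1700.0, step=0.5)
        with pytest.raises(ValueError, match="outside"):
            oc.intensity_at(sp, 1710.0)

    def test_sparse_subtraction_arithmetic(self):
        grid = 1650.0 + 0.5 * np.arange(400)  # covers 1659..1800+
        y = np.zeros(400)
        y[np.argmin(np.abs(grid - 1748.0))] = 0.30
        y[np.argmin(np.abs(grid - 1800.0))] = 0.05
        si = oc.sparse_intensities(oc.Spectrum(wavenumbers=grid, intensities=y))
        assert si.values["TAG"] == pytest.approx(0.25)
        assert si.resolved["baseline"] == 1800.0

    def test_flat_spectrum_gives_zeros(self):
        grid = 1650.0 + 0.5 * np.arange(400)
        si = oc.sparse_intensities(
            oc.Spectrum(wavenumbers=grid, intensities=np.full(400, 0.7))
        )
        assert all(v == 0.0 for v in si.values.values())

    def test_pure_tag_raw_1748_exceeds_1714(self, grid):
        comp = Composition(tuple(1.0 if c == "TAG" else 0.0 for c in COMPONENTS))
        sp = oc.render_spectrum(comp, default_band_library(), grid)
        si = oc.sparse_intensities(sp)
        assert si.values["TAG"] > si.values["FFA"]

    def test_grid_not_covering_1800_rejected(self):
        sp = make_spectrum(np.arange(100.0), start=1650.0, step=0.5)
        with pytest.raises(ValueError, match="1800"):
            oc.sparse_intensities(sp)


@given(st.lists(st.floats(-100, 100), min_size=40, max_size=40).filter(
    lambda v: np.ptp(v) > 1e-6))
def test_sg_linearity_property(values):
    """SG differentiation is linear: D(2y) = 2·D(y)."""
    cfg = oc.PreprocessConfig(sg_window=11)
    sp = make_spectrum(np.asarray(values))
    d1 = oc.savitzky_golay_derivative(sp, cfg).intensities
    d2 = oc.savitzky_golay_derivative(
        sp.replace(intensities=2.0 * sp.intensities), cfg
    ).intensities
    np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-9, atol=1e-9)
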