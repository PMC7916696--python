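"""Wide-CSV I/O, grid contracts and preprocessing."""

import numpy as np
import pytest

from noda2d import (
    SpectralSeries,
    baseline_correct,
    normalize,
    read_series,
    resample_even,
    select_region,
    write_series,
)


def make_series(nu, T, I):
    return SpectralSeries(nu=np.asarray(nu, float), T=np.asarray(T, float), I=np.asarray(I, float))


class TestSeriesValidation:
    def test_axes_sorted_ascending_on_construction(self):
        s = make_series([912, 900, 908], [260, 250], [[3, 1, 2], [6, 4, 5]])
        assert list(s.nu) == [900, 908, 912]
        assert list(s.T) == [250, 260]
        # intensities permuted consistently with both axes: the row that was
        # at T=250 comes first, each row reordered with the wavenumbers
        assert s.I[0].tolist() == [4, 5, 6]
        assert s.I[1].tolist() == [1, 2, 3]

    @pytest.mark.parametrize(
        "nu,T,I,msg",
        [
            ([900, 900, 908], [250, 260], np.ones((2, 3)), "duplicate wavenumber"),
            ([900, 904], [250, 250], np.ones((2, 2)), "duplicate temperature"),
            ([900, 904], [250], np.ones((1, 2)), "at least 2 spectra"),
            ([900], [250, 260], np.ones((2, 1)), "at least 2 wavenumber"),
        ],
    )
    def test_invariant_violations_raise(self, nu, T, I, msg):
        with pytest.raises(ValueError, match=msg):
            make_series(nu, T, I)

    def test_nan_rejected(self):
        I = np.ones((2, 2))
        I[0, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            make_series([900, 904], [250, 260], I)


class TestCsvRoundTrip:
    def test_roundtrip_identity_full_precision(self, small_series, tmp_path):
        path = write_series(small_series, tmp_path / "s.csv")
        back = read_series(path)
        assert back.equals(small_series)

    def test_small_wellformed_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("wavenumber_cm-1,250,260\n900,0.1,0.2\n904,0.3,0.4\n908,0.5,0.6\n")
        s = read_series(p)
        assert (s.n, s.k) == (3, 2)

    def test_out_of_order_temperature_columns_sorted(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("nu,260,250\n900,1.0,2.0\n904,3.0,4.0\n")
        s = read_series(p)
        assert list(s.T) == [250.0, 260.0]
        assert s.I[0].tolist() == [2.0, 4.0]

    def test_column_count_is_k_plus_one(self, tmp_path):
        from noda2d.synthetic import BandSpec, SyntheticSpec, generate_series

        spec = SyntheticSpec(bands=(BandSpec(center=1000.0, width=10.0),))
        series, _ = generate_series(spec)
        assert series.k == 10
        path = write_series(series, tmp_path / "s.csv")
        header = path.read_text().splitlines()[0]
        assert len(header.split(",")) == 11

    @pytest.mark.parametrize(
        "text,msg",
        [
            ("nu,250,260\n900,1,2\n900,3,4\n", "duplicated wavenumber"),
            ("nu,250,250\n900,1,2\n904,3,4\n", "duplicate temperature"),
            ("nu,250,260\n900,1,abc\n904,3,4\n", "non-numeric"),
            ("nu,250,hot\n900,1,2\n904,3,4\n", "does not parse as a temperature"),
            ("nu,250,260\n900,1\n904,3,4\n", "missing value"),
        ],
    )
    def test_malformed_files_raise_with_location(self, tmp_path, text, msg):
        p = tmp_path / "bad.csv"
        p.write_text(text)
        with pytest.raises(ValueError, match=msg):
            read_series(p)


class TestSelectRegion:
    def test_full_range_is_identity(self, small_series):
        s = select_region(small_series, small_series.nu[0], small_series.nu[-1])
        assert s.equals(small_series)

    def test_closed_interval_on_4cm_grid(self):
        nu = np.arange(800.0, 3700.0 + 1, 4.0)
        s = make_series(nu, [250, 260], np.ones((2, nu.size)))
        sub = select_region(s, 900.0, 1200.0)
        assert sub.nu[0] == 900.0 and sub.nu[-1] == 1200.0
        assert np.all((sub.nu >= 900) & (sub.nu <= 1200))
        # grid points preserved exactly, no resampling
        assert np.array_equal(sub.nu, nu[(nu >= 900) & (nu <= 1200)])

    def test_single_point_window_errors(self, small_series):
        with pytest.raises(ValueError, match="at least 2"):
            select_region(small_series, 903.0, 905.0)


class TestNormalize:
    def test_none_is_identity(self, small_series):
        assert normalize(small_series, mode="none").equals(small_series)

    def test_vector_norms_become_unit(self, small_series):
        s = normalize(small_series, mode="vector")
        assert np.allclose(np.linalg.norm(s.I, axis=1), 1.0)

    def test_band_area_makes_standard_window_unit_area(self):
        nu = np.arange(1000.0, 1101.0, 4.0)
        rng = np.random.default_rng(3)
        s = make_series(nu, [250, 260, 270], rng.uniform(0.5, 1.5, (3, nu.size)))
        out = normalize(s, mode="band_area", band_window=(1045.0, 1065.0))
        mask = (out.nu >= 1045) & (out.nu <= 1065)
        areas = np.trapezoid(out.I[:, mask], out.nu[mask], axis=1)
        assert np.allclose(areas, 1.0)

    def test_window_outside_grid_errors(self, small_series):
        with pytest.raises(ValueError, match="outside the grid"):
            normalize(small_series, mode="band_area", band_window=(1045.0, 1065.0))

    def test_zero_norm_errors(self):
        s = make_series([900, 904], [250, 260], [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            normalize(s, mode="vector")


class TestBaseline:
    def test_endpoints_exactly_zero(self, small_series):
        s = baseline_correct(small_series)
        assert np.all(s.I[:, 0] == 0.0)
        assert np.all(s.I[:, -1] == 0.0)

    def test_already_zero_at_endpoints_unchanged(self):
        s = make_series([900, 904, 908], [250, 260], [[0, 5, 0], [0, 2, 0]])
        out = baseline_correct(s)
        assert np.allclose(out.I, s.I)

    def test_constant_offset_removed_entirely(self):
        s = make_series([900, 904, 908], [250, 260], np.full((2, 3), 0.7))
        out = baseline_correct(s)
        assert np.allclose(out.I, 0.0)

    def test_pure_gaussian_change_bounded_by_endpoint_values(self):
        # the subtracted line interpolates the endpoint values, so the
        # correction magnitude never exceeds the larger endpoint
        nu = np.arange(900.0, 1101.0, 4.0)
        g = np.exp(-0.5 * ((nu - 1000.0) / 15.0) ** 2)
        s = make_series(nu, [250, 260], np.vstack([g, 2 * g]))
        out = baseline_correct(s)
        for t in range(2):
            bound = max(abs(s.I[t, 0]), abs(s.I[t, -1]))
            assert np.max(np.abs(out.I[t] - s.I[t])) <= bound + 1e-15


class TestResampleEven:
    def test_uniform_grid_is_noop(self, three_band_series):
        series, _ = three_band_series
        out = resample_even(series)
        assert out.equals(series)

    def test_linear_channel_interpolated_exactly(self):
        T = np.array([250.0, 260.0, 280.0])
        I = np.vstack([2.0 * T + 1.0, -0.5 * T + 3.0]).T  # each channel linear in T
        s = make_series([900, 904], T, I)
        out = resample_even(s)
        assert np.array_equal(out.T, [250.0, 265.0, 280.0])
        assert np.allclose(out.I[:, 0], 2.0 * out.T + 1.0)
        assert np.allclose(out.I[:, 1], -0.5 * out.T + 3.0)

    def test_quadratic_channel_matches_hand_interpolation(self):
        # channel = T^2 on T = {250, 260, 280}; uniform grid {250, 265, 280}.
        # 265 falls between 260 and 280: 67600 + (265-260)/(280-260)*(78400-67600)
        T = np.array([250.0, 260.0, 280.0])
        I = np.vstack([T**2, T**2]).T
        s = make_series([900, 904], T, I)
        out = resample_even(s)
        assert np.allclose(out.I[:, 0], [62500.0, 70300.0, 78400.0])

    def test_endpoints_and_k_preserved(self):
        T = np.array([250.0, 255.0, 290.0, 340.0])
        rng = np.random.default_rng(0)
        s = make_series([900, 904], T, rng.normal(size=(4, 2)))
        out = resample_even(s)
        assert out.k == s.k
        assert out.T[0] == s.T[0] and out.T[-1] == s.T[-1]

    def test_requires_three_spectra(self, small_series):
        s = make_series([900, 904], [250, 260], np.ones((2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            resample_even(s)


class TestCommutation:
    def test_region_then_baseline_differs_from_baseline_then_region(self):
        # baseline endpoints move with the region, so the two orders only
        # commute when the full-range endpoints survive the cut
        nu = np.arange(900.0, 1201.0, 4.0)
        rng = np.random.default_rng(7)
        s = make_series(nu, [250, 260], rng.uniform(0.2, 1.0, (2, nu.size)))
        a = select_region(baseline_correct(s), 1000.0, 1100.0)
        b = baseline_correct(select_region(s, 1000.0, 1100.0))
        assert not np.allclose(a.I, b.I)

    def test_region_and_normalize_commute_when_window_inside(self):
        nu = np.arange(900.0, 1201.0, 4.0)
        rng = np.random.default_rng(8)
        s = make_series(nu, [250, 260], rng.uniform(0.2, 1.0, (2, nu.size)))
        win = (1040.0, 1068.0)
        a = select_region(normalize(s, "band_area", win), 1000.0, 1100.0)
        b = normalize(select_region(s, 1000.0, 1100.0), "band_area", win)
        assert np.allclose(a.I, b.I)
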