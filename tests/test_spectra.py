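"""Unit and property tests for the spectral algebra primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specres.spectra import (
    ExtrapolationError,
    FlatnessWarning,
    GridMismatchError,
    MaskedValueError,
    ResponseDescriptor,
    Spectrum,
    SpectrumError,
    combine,
    default_grid,
    derivative,
    divide,
    factorize,
    normalize,
    plateau_constant,
    read_response,
    read_spectrum_csv,
    resample,
    write_spectrum_csv,
    read_spectra_wide_csv,
    write_spectra_wide_csv,
)


def line(grid, slope=1.0, intercept=0.0, order=0):
    return Spectrum(grid, slope * grid + intercept, order=order, label="line")


def gaussian(grid, center, sigma, height=1.0):
    return Spectrum(grid, height * np.exp(-0.5 * ((grid - center) / sigma) ** 2),
                    label=f"gauss{center}")


class TestSpectrumInvariants:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0, 203.0]), np.zeros(3))

    def test_rejects_decreasing_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([202.0, 201.0, 200.0]), np.zeros(3))

    def test_rejects_bad_order(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0]), np.zeros(2), order=2)

    def test_rejects_length_mismatch(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0, 202.0]), np.zeros(2))


class TestResample:
    def test_identity_on_own_grid(self):
        g = default_grid()
        s = gaussian(g, 250, 10)
        r = resample(s, g)
        np.testing.assert_array_equal(r.values, s.values)

    def test_exact_on_line(self):
        g = np.arange(200.0, 211.0)
        s = line(g)  # y = lambda
        target = np.arange(200.5, 210.0)
        r = resample(s, target)
        np.testing.assert_allclose(r.values, target, atol=1e-12)

    def test_gaussian_fine_resample_error_within_interpolation_bound(self):
        # 1 nm sampling interpolated to 0.5 nm vs the closed form; linear
        # interpolation error is bounded by h^2 * max|f''| / 8 = h^2 h_band
        # / (8 sigma^2) for a Gaussian of height h_band
        coarse = np.arange(200.0, 301.0, 1.0)
        fine = np.arange(200.0, 300.5, 0.5)
        for sigma in (5.0, 8.0, 10.0):
            s = gaussian(coarse, 250, sigma)
            r = resample(s, fine)
            exact = np.exp(-0.5 * ((fine - 250) / sigma) ** 2)
            bound = 1.0 / (8.0 * sigma**2)
            assert np.max(np.abs(r.values - exact)) < 1.05 * bound

    def test_band_scale_resample_error_below_1e3(self):
        # at realistic band scale (the 0.533 AU extended band, sigma 10 nm)
        # the interpolation error is below 1e-3 AU
        coarse = np.arange(250.0, 351.0, 1.0)
        fine = np.arange(250.0, 350.5, 0.5)
        s = gaussian(coarse, 304, 10.0, height=0.533)
        r = resample(s, fine)
        exact = 0.533 * np.exp(-0.5 * ((fine - 304) / 10.0) ** 2)
        assert np.max(np.abs(r.values - exact)) < 1e-3

    def test_extrapolation_raises_with_bounds(self):
        s = gaussian(np.arange(210.0, 301.0), 250, 10)
        with pytest.raises(ExtrapolationError, match="210"):
            resample(s, np.arange(200.0, 301.0))


class TestCombine:
    def test_self_subtraction_is_zero(self, grid):
        s = gaussian(grid, 260, 12)
        z = combine(s, s, 1.0, -1.0)
        np.testing.assert_array_equal(z.values, np.zeros_like(grid))

    def test_scaling_via_zero_partner(self, grid):
        s = gaussian(grid, 260, 12)
        zero = s.with_values(np.zeros_like(grid))
        d = combine(s, zero, 2.0, 1.0)
        np.testing.assert_allclose(d.values, 2.0 * s.values)

    def test_grid_mismatch_raises(self, grid):
        a = gaussian(grid, 260, 12)
        b = gaussian(grid[:-2], 260, 12)
        with pytest.raises(GridMismatchError):
            combine(a, b)

    def test_order_mismatch_raises(self, grid):
        a = gaussian(grid, 260, 12)
        b = Spectrum(grid, a.values, order=1)
        with pytest.raises(GridMismatchError):
            combine(a, b)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(wa=st.floats(-5, 5), wb=st.floats(-5, 5))
    def test_linearity_property(self, wa, wb):
        g = default_grid(200, 220, 1.0)
        a = gaussian(g, 205, 5)
        b = gaussian(g, 215, 5)
        c = combine(a, b, wa, wb)
        np.testing.assert_allclose(c.values, wa * a.values + wb * b.values,
                                   atol=1e-12)


class TestDivide:
    def test_self_division_is_one(self, grid):
        s = gaussian(grid, 260, 12, height=2.0)
        r = divide(s, s, epsilon=1e-6)
        assert np.allclose(r.values[r.mask], 1.0)

    def test_points_below_epsilon_are_masked(self, grid):
        num = gaussian(grid, 260, 12)
        div = gaussian(grid, 220, 8)  # vanishes at long wavelengths
        r = divide(num, div, epsilon=1e-4)
        assert not r.mask.all() and r.mask.any()
        assert np.isnan(r.values[~r.mask]).all()

    def test_entirely_below_epsilon_raises(self, grid):
        num = gaussian(grid, 260, 12)
        div = num.with_values(np.full_like(grid, 1e-6))
        with pytest.raises(SpectrumError):
            divide(num, div, epsilon=1e-4)


class TestDerivative:
    def test_constant_maps_to_zero(self, grid):
        s = Spectrum(grid, np.full_like(grid, 0.7))
        d = derivative(s)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)
        assert d.order == 1

    def test_line_maps_to_scaled_slope(self, grid):
        s = line(grid, slope=0.03, intercept=-1.0)
        d = derivative(s, delta_lambda=4.0, scale=10.0)
        np.testing.assert_allclose(d.values, 10.0 * 0.03, atol=1e-12)

    def test_trims_half_window(self, grid):
        d = derivative(line(grid), delta_lambda=4.0)
        assert d.wavelengths[0] == grid[0] + 2.0
        assert d.wavelengths[-1] == grid[-1] - 2.0

    def test_zero_crossing_at_each_band_center(self, grid, models):
        from specres.synthetic import component_spectrum
        d = derivative(component_spectrum(models["TCB"], 10.0, grid))
        for center in (220.0, 304.0):
            before = d.value_at(center - 2.0)
            after = d.value_at(center + 2.0)
            assert before > 0 > after  # absorbance rises into, falls out of, the band

    def test_unrepresentable_window_raises(self, grid):
        with pytest.raises(SpectrumError):
            derivative(line(grid), delta_lambda=1.3)

    def test_first_order_input_rejected(self, grid):
        s = Spectrum(grid, np.zeros_like(grid), order=1)
        with pytest.raises(SpectrumError):
            derivative(s)


class TestReadResponse:
    def test_zero_spectrum_amplitude(self, grid):
        s = Spectrum(grid, np.zeros_like(grid))
        assert read_response(s, ResponseDescriptor("amplitude_at", 0, 304)) == 0.0

    def test_peak_to_peak_antisymmetry(self, grid):
        s = gaussian(grid, 260, 12)
        fwd = read_response(s, ResponseDescriptor("peak_to_peak", 0, 250, 270))
        rev = read_response(s, ResponseDescriptor("peak_to_peak", 0, 270, 250))
        assert fwd == -rev

    def test_equal_wavelengths_forbidden(self):
        with pytest.raises(SpectrumError):
            ResponseDescriptor("peak_to_peak", 0, 250, 250)

    def test_out_of_scan_wavelength_forbidden(self):
        with pytest.raises(SpectrumError):
            ResponseDescriptor("amplitude_at", 0, 450)

    def test_order_mismatch_raises(self, grid):
        s = gaussian(grid, 260, 12)
        with pytest.raises(SpectrumError):
            read_response(s, ResponseDescriptor("amplitude_at", 1, 260))

    def test_masked_point_raises(self, grid):
        mask = np.ones(grid.size, dtype=bool)
        mask[grid == 260.0] = False
        s = Spectrum(grid, np.ones_like(grid), mask=mask)
        with pytest.raises(MaskedValueError):
            read_response(s, ResponseDescriptor("amplitude_at", 0, 260))

    def test_off_grid_read_interpolates(self, grid):
        s = line(grid, slope=2.0)
        assert s.value_at(260.25) == pytest.approx(2.0 * 260.25)

    def test_descriptor_parse_roundtrip(self):
        for text in ("D0@304", "D1@228-216", "D1@221"):
            assert ResponseDescriptor.parse(text).key == text


class TestPlateauConstant:
    def test_constant_spectrum(self, grid):
        s = Spectrum(grid, np.full_like(grid, 3.5))
        k = plateau_constant(s, (290, 306))
        assert k.value == 3.5 and k.flatness_rsd == 0.0 and k.flat

    def test_nonflat_region_warns(self, grid):
        s = line(grid, slope=1.0, intercept=-280.0)  # ramps 10 -> 26 over the window
        with pytest.warns(FlatnessWarning):
            k = plateau_constant(s, (290, 306), flatness_tol=2.0)
        assert not k.flat and k.flatness_rsd > 2.0

    def test_too_few_unmasked_points_raises(self, grid):
        mask = np.zeros(grid.size, dtype=bool)
        mask[:2] = True
        s = Spectrum(grid, np.ones_like(grid), mask=mask)
        with pytest.raises(SpectrumError):
            plateau_constant(s, (290, 306))


class TestNormalizeFactorize:
    def test_normalize_identity_at_unit_conc(self, grid):
        s = gaussian(grid, 260, 12)
        np.testing.assert_array_equal(normalize(s, 1.0).values, s.values)

    def test_normalize_scales_amplitudes(self, grid):
        s = gaussian(grid, 260, 12, height=3.0)
        n = normalize(s, 4.0)
        assert n.value_at(260.0) == pytest.approx(s.value_at(260.0) / 4.0)

    def test_factorized_reads_one_at_reference(self, grid):
        s = gaussian(grid, 260, 12, height=0.42)
        assert factorize(s, 260.0).value_at(260.0) == pytest.approx(1.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(c1=st.floats(1.0, 20.0), c2=st.floats(1.0, 20.0))
    def test_factorize_concentration_invariance(self, c1, c2):
        from specres.synthetic import component_spectrum, default_models
        tcb, _ = default_models()
        g = default_grid()
        f1 = factorize(component_spectrum(tcb, c1, g), 304.0)
        f2 = factorize(component_spectrum(tcb, c2, g), 304.0)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_near_zero_reference_raises(self, grid):
        s = gaussian(grid, 220, 8)  # ~0 at 350 nm
        with pytest.raises(SpectrumError):
            factorize(s, 350.0)


class TestCsvIO:
    def test_two_column_roundtrip(self, grid, tmp_path):
        s = gaussian(grid, 260, 12, height=0.123456789)
        path = tmp_path / "s.csv"
        write_spectrum_csv(s, path)
        r = read_spectrum_csv(path)
        np.testing.assert_allclose(r.values, s.values, rtol=1e-8)
        # writers round-trip bit-comparably at 9 significant digits
        write_spectrum_csv(r, tmp_path / "s2.csv")
        assert path.read_text() == (tmp_path / "s2.csv").read_text()

    def test_wide_roundtrip(self, grid, tmp_path):
        spectra = {"a": gaussian(grid, 250, 9), "b": gaussian(grid, 280, 11)}
        path = tmp_path / "wide.csv"
        write_spectra_wide_csv(spectra, path)
        back = read_spectra_wide_csv(path)
        assert set(back) == {"a", "b"}
        np.testing.assert_allclose(back["a"].values, spectra["a"].values, rtol=1e-8)
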