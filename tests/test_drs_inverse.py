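import numpy as np
import pytest

from perfopt.drs_inverse import (
    ExtinctionTable,
    ReflectanceSpectrum,
    TissueModelParams,
    calibrate_scale,
    correct_spectrum,
    fit_spectrum,
    load_extinction_table,
    model_mua,
    model_musp,
    model_spectrum,
    read_spectrum,
    smooth_spectrum,
    write_spectrum,
)
from perfopt.exceptions import CalibrationError
from perfopt.mc_forward import OpticalProperties

WL = np.arange(500.0, 650.0 + 1e-9, 2.0)


def spectrum(values, wl=WL, stage="raw"):
    return ReflectanceSpectrum(wl, np.asarray(values, dtype=float), stage)


class TestCorrectSpectrum:
    def test_self_reference_gives_standard_reflectance(self):
        raw = spectrum(np.full(WL.size, 800.0))
        dark = spectrum(np.zeros(WL.size))
        out = correct_spectrum(raw, dark, raw, reference_reflectance=0.5)
        np.testing.assert_allclose(out.values, 0.5)
        assert out.stage == "reference_corrected"

    def test_raw_equal_dark_gives_zero(self):
        dark = spectrum(np.full(WL.size, 50.0))
        ref = spectrum(np.full(WL.size, 900.0))
        out = correct_spectrum(dark, dark, ref)
        np.testing.assert_allclose(out.values, 0.0)

    def test_fractional_signal(self):
        dark = spectrum(np.full(WL.size, 100.0))
        ref = spectrum(np.full(WL.size, 1100.0))
        raw = spectrum(dark.values + 0.3 * (ref.values - dark.values))
        out = correct_spectrum(raw, dark, ref, reference_reflectance=0.5)
        np.testing.assert_allclose(out.values, 0.15)

    def test_grid_mismatch_rejected(self):
        raw = spectrum(np.ones(WL.size))
        other = ReflectanceSpectrum(WL + 1.0, np.ones(WL.size), "raw")
        with pytest.raises(ValueError, match="grid"):
            correct_spectrum(raw, other, raw)

    def test_nonpositive_reference_rejected(self):
        raw = spectrum(np.ones(WL.size))
        dark = spectrum(np.ones(WL.size))
        with pytest.raises(CalibrationError):
            correct_spectrum(raw, dark, dark)


class TestSmoothing:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        spec = spectrum(rng.random(WL.size), stage="reference_corrected")
        out = smooth_spectrum(spec, 1)
        np.testing.assert_array_equal(out.values, spec.values)

    def test_constant_preserved(self):
        spec = spectrum(np.full(WL.size, 0.3), stage="reference_corrected")
        out = smooth_spectrum(spec, 11)
        np.testing.assert_allclose(out.values, 0.3)

    def test_white_noise_variance_reduced_by_window(self):
        rng = np.random.default_rng(1)
        mid = WL.size // 2
        raw_vals, smooth_vals = [], []
        for _ in range(300):
            noise = rng.standard_normal(WL.size)
            out = smooth_spectrum(spectrum(noise + 10.0), 11)
            raw_vals.append(noise[mid])
            smooth_vals.append(out.values[mid] - 10.0)
        ratio = np.var(raw_vals) / np.var(smooth_vals)
        assert 8.0 < ratio < 15.0  # ~11x for an 11-point average

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_spectrum(spectrum(np.ones(WL.size)), 4)


class TestAbsorptionModel:
    def small_table(self):
        return ExtinctionTable(
            wavelengths_nm=np.array([500.0, 600.0, 700.0]),
            eps_hbo2=np.array([2000.0, 2000.0, 500.0]),
            eps_hb=np.array([1000.0, 2000.0, 1500.0]),
        )

    def test_direct_arithmetic(self):
        eps = self.small_table()
        params = TissueModelParams(hbt_uM=20.0, sto2=0.0, A=10.0, B=1.0)
        mua = model_mua(params, eps, [500.0])
        assert mua[0] == pytest.approx(np.log(10) * 20e-6 * 1000.0, rel=1e-12)

    def test_isosbestic_independence_of_sto2(self):
        eps = self.small_table()  # 600 nm is isosbestic in this table
        vals = [
            model_mua(TissueModelParams(20.0, s, 10.0, 1.0), eps, [600.0])[0]
            for s in (0.0, 0.5, 1.0)
        ]
        assert np.ptp(vals) < 1e-15

    def test_zero_hbt_gives_zero(self):
        eps = self.small_table()
        mua = model_mua(TissueModelParams(0.0, 0.5, 10.0, 1.0), eps, [550.0, 650.0])
        np.testing.assert_array_equal(mua, 0.0)

    def test_affine_in_sto2_linear_in_hbt(self):
        eps = load_extinction_table()
        wl = np.array([520.0, 560.0, 600.0])
        f = lambda hbt, s: model_mua(TissueModelParams(hbt, s, 10, 1), eps, wl)  # noqa: E731
        # affine in StO2: midpoint equals mean of endpoints
        np.testing.assert_allclose(f(20, 0.5), 0.5 * (f(20, 0.0) + f(20, 1.0)), rtol=1e-12)
        # linear in HbT
        np.testing.assert_allclose(f(40, 0.3), 2 * f(20, 0.3), rtol=1e-12)


class TestScatteringModel:
    def test_reference_wavelength_anchor(self):
        params = TissueModelParams(10.0, 0.5, A=17.0, B=1.3, lambda0_nm=600.0)
        assert model_musp(params, [600.0])[0] == pytest.approx(17.0, rel=1e-12)

    def test_zero_power_is_flat(self):
        params = TissueModelParams(10.0, 0.5, A=17.0, B=0.0)
        np.testing.assert_allclose(model_musp(params, WL), 17.0)

    def test_direct_arithmetic(self):
        params = TissueModelParams(10.0, 0.5, A=20.0, B=1.0, lambda0_nm=600.0)
        assert model_musp(params, [650.0])[0] == pytest.approx(20 * 600 / 650, rel=1e-12)


class TestForwardAndCalibration:
    def test_zero_scale_gives_zero_spectrum(self, analytic_lut, eps_table):
        params = TissueModelParams(19.0, 0.68, 20.0, 1.2)
        out = model_spectrum(params, analytic_lut, eps_table, WL, scale=0.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_more_hemoglobin_darkens_every_wavelength(self, analytic_lut, eps_table):
        lo = model_spectrum(TissueModelParams(10.0, 0.68, 20.0, 1.2),
                            analytic_lut, eps_table, WL)
        hi = model_spectrum(TissueModelParams(30.0, 0.68, 20.0, 1.2),
                            analytic_lut, eps_table, WL)
        assert np.all(hi.values < lo.values)

    def test_scale_recovery(self, analytic_lut):
        props = OpticalProperties.from_musp(0.04, 18.0)
        from perfopt.mc_forward import lut_lookup

        model_val = lut_lookup(analytic_lut, props.mua, props.musp)
        measured = spectrum(np.full(WL.size, model_val), stage="reference_corrected")
        assert calibrate_scale(measured, props, analytic_lut) == pytest.approx(1.0)
        doubled = spectrum(np.full(WL.size, 2 * model_val), stage="reference_corrected")
        assert calibrate_scale(doubled, props, analytic_lut) == pytest.approx(2.0)

    def test_scale_recovery_under_noise(self, analytic_lut):
        rng = np.random.default_rng(5)
        props = OpticalProperties.from_musp(0.04, 18.0)
        from perfopt.mc_forward import lut_lookup

        model_val = lut_lookup(analytic_lut, props.mua, props.musp)
        vals = model_val * 1.7 * (1 + 0.01 * rng.standard_normal(WL.size))
        measured = spectrum(vals, stage="reference_corrected")
        assert calibrate_scale(measured, props, analytic_lut) == pytest.approx(1.7, rel=0.01)


class TestInversion:
    TRUTH = TissueModelParams(hbt_uM=19.0, sto2=0.68, A=20.0, B=1.2)

    def test_noise_free_round_trip(self, analytic_lut, eps_table):
        truth_spec = model_spectrum(self.TRUTH, analytic_lut, eps_table, WL)
        fit = fit_spectrum(truth_spec, analytic_lut, eps_table, seed=0)
        assert fit.params.hbt_uM == pytest.approx(19.0, rel=0.05)
        assert abs(fit.params.sto2 - 0.68) < 0.02
        assert fit.objective < 1.0

    def test_active_bound_full_saturation(self, analytic_lut, eps_table):
        truth = TissueModelParams(19.0, 1.0, 20.0, 1.2)
        truth_spec = model_spectrum(truth, analytic_lut, eps_table, WL)
        fit = fit_spectrum(truth_spec, analytic_lut, eps_table, seed=1)
        assert fit.params.sto2 > 0.97
        assert 0.0 <= fit.params.sto2 <= 1.0

    def test_recovery_degrades_monotonically_with_noise(self, analytic_lut, eps_table):
        rng = np.random.default_rng(9)
        truth_spec = model_spectrum(self.TRUTH, analytic_lut, eps_table, WL)
        med_errs = []
        for sigma in (0.0, 0.01, 0.02):
            errs = []
            for _ in range(5):
                vals = truth_spec.values * (1 + sigma * rng.standard_normal(WL.size))
                noisy = ReflectanceSpectrum(WL, np.clip(vals, 1e-9, None),
                                            "reference_corrected")
                fit = fit_spectrum(noisy, analytic_lut, eps_table, seed=2)
                errs.append(abs(fit.params.sto2 - 0.68))
            med_errs.append(np.median(errs))
        assert med_errs[0] <= med_errs[1] + 0.005
        assert med_errs[0] <= med_errs[2] + 0.005

    def test_uncorrected_spectrum_rejected(self, analytic_lut, eps_table):
        raw = spectrum(np.ones(WL.size), stage="raw")
        with pytest.raises(ValueError, match="corrected"):
            fit_spectrum(raw, analytic_lut, eps_table)


def test_extinction_table_shape_and_bands():
    eps = load_extinction_table()
    # deoxyhemoglobin dominates beyond 600 nm
    hbo2, hb = eps.interp(np.arange(610.0, 660.0, 10.0))
    assert np.all(hb > 3 * hbo2)
    # HbO2 dip at 560 between its double peaks
    peaks, _ = eps.interp([540.0, 577.0])
    dip, _ = eps.interp([560.0])
    assert dip < peaks.min()


def test_spectrum_tsv_round_trip(tmp_path):
    spec = ReflectanceSpectrum(WL, np.linspace(0.1, 0.2, WL.size), "smoothed")
    path = tmp_path / "s.tsv"
    write_spectrum(spec, path)
    back = read_spectrum(path)
    assert back.stage == "smoothed"
    np.testing.assert_allclose(back.values, spec.values, rtol=1e-15)
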