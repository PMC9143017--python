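"""Inverse model: calibration, property extraction, fluorescence correction."""

import numpy as np
import pytest

from turbispec import (
    CalibrationFactor,
    OpticalProperties,
    PowerLaw,
    Spectrum,
    calibrate_reference,
    correct_fluorescence,
    fit_reflectance,
    model_fluorescence,
    model_reflectance_spectrum,
    peak_intensity,
    vascular_endpoints,
)
from turbispec.chromophores import LN10
from turbispec.errors import DegenerateInputError, InvalidArgumentError, RangeError
from turbispec.inversion import InversionResult
from turbispec.phantoms import TMRE_EMISSION_GRID, phantom_optical_properties


def props_from(basis, c_oxy, c_deoxy, scatter, grid=None):
    if grid is None:
        grid = np.arange(420.0, 761.0)
    mua = LN10 * (c_oxy * basis.extinction_at("oxyhemoglobin", grid)
                  + c_deoxy * basis.extinction_at("deoxyhemoglobin", grid))
    return OpticalProperties(grid, mua, scatter.musp(grid), anisotropy_g=0.9,
                             refractive_index=1.33)


class TestCalibration:
    def test_identity_closed_loop(self, baseline, basis):
        props = props_from(basis, 30.0, 10.0, PowerLaw(10.0, 1.0))
        measured = model_reflectance_spectrum(props, baseline, 1.0)
        cal = calibrate_reference(measured, props, baseline)
        assert cal.reflectance_scale == pytest.approx(1.0, rel=1e-9)

    def test_doubled_measurement_doubles_scale(self, baseline, basis):
        props = props_from(basis, 30.0, 10.0, PowerLaw(10.0, 1.0))
        measured = model_reflectance_spectrum(props, baseline, 2.0)
        cal = calibrate_reference(measured, props, baseline)
        assert cal.reflectance_scale == pytest.approx(2.0, rel=1e-9)

    def test_median_ratio_robust_to_noise(self, baseline, basis):
        """1% multiplicative noise over ~50 wavelengths keeps the median
        ratio within [0.98, 1.02]."""
        grid = np.arange(450.0, 601.0, 3.0)
        props = props_from(basis, 30.0, 10.0, PowerLaw(10.0, 1.0), grid)
        clean = model_reflectance_spectrum(props, baseline, 1.0)
        rng = np.random.default_rng(12)
        for _ in range(10):
            noisy = clean.with_values(clean.values * (1 + 0.01 * rng.standard_normal(grid.size)))
            cal = calibrate_reference(noisy, props, baseline)
            assert 0.98 <= cal.reflectance_scale <= 1.02

    def test_insufficient_overlap_rejected(self, baseline, basis):
        grid = np.arange(450.0, 456.0)
        props = props_from(basis, 30.0, 10.0, PowerLaw(10.0, 1.0), grid)
        measured = model_reflectance_spectrum(props, baseline, 1.0)
        with pytest.raises(RangeError):
            calibrate_reference(measured, props, baseline)


class TestFitReflectance:
    def test_noiseless_closed_loop_recovery(self, baseline, lut, basis):
        truth = dict(oxy=30.0, deoxy=10.0, a=10.0, b=1.0)
        props = props_from(basis, truth["oxy"], truth["deoxy"], PowerLaw(truth["a"], truth["b"]))
        measured = model_reflectance_spectrum(props, baseline, 1.0)
        res = fit_reflectance(measured, basis, PowerLaw(10.0, 1.0), baseline,
                              CalibrationFactor(1.0), lut=lut)
        assert res.converged
        assert res.concentrations["oxyhemoglobin"] == pytest.approx(truth["oxy"], rel=0.02)
        assert res.concentrations["deoxyhemoglobin"] == pytest.approx(truth["deoxy"], rel=0.02)
        assert res.scatter_params.amplitude == pytest.approx(truth["a"], rel=0.02)

    def test_noisy_recovery_coverage(self, baseline, lut, basis):
        """1% multiplicative noise, 20 seeds: >= 90% of runs recover both
        hemoglobin concentrations within 10%."""
        props = props_from(basis, 30.0, 10.0, PowerLaw(10.0, 1.0))
        clean = model_reflectance_spectrum(props, baseline, 1.0)
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(20):
            noisy = clean.with_values(clean.values * (1 + 0.01 * rng.standard_normal(clean.values.size)))
            res = fit_reflectance(noisy, basis, PowerLaw(10.0, 1.0), baseline,
                                  CalibrationFactor(1.0), lut=lut)
            ok = (abs(res.concentrations["oxyhemoglobin"] - 30.0) / 30.0 < 0.1
                  and abs(res.concentrations["deoxyhemoglobin"] - 10.0) / 10.0 < 0.1)
            hits += ok
        assert hits >= 18

    def test_deterministic_given_input(self, baseline, lut, basis):
        props = props_from(basis, 20.0, 20.0, PowerLaw(12.0, 0.8))
        measured = model_reflectance_spectrum(props, baseline, 1.0)
        r1 = fit_reflectance(measured, basis, PowerLaw(10.0, 1.0), baseline,
                             CalibrationFactor(1.0), lut=lut)
        r2 = fit_reflectance(measured, basis, PowerLaw(10.0, 1.0), baseline,
                             CalibrationFactor(1.0), lut=lut)
        assert r1.concentrations == r2.concentrations
        assert r1.residual_norm == r2.residual_norm

    def test_window_and_degenerate_errors(self, baseline, lut, basis):
        grid = np.arange(470.0, 551.0)
        measured = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(RangeError):
            fit_reflectance(measured, basis, PowerLaw(10.0, 1.0), baseline,
                            CalibrationFactor(1.0), fit_window=(450, 600), lut=lut)
        zero = Spectrum(np.arange(420.0, 761.0), np.zeros(341))
        with pytest.raises(DegenerateInputError):
            fit_reflectance(zero, basis, PowerLaw(10.0, 1.0), baseline,
                            CalibrationFactor(1.0), lut=lut)


class TestVascularEndpoints:
    def _result(self, oxy, deoxy):
        grid = np.arange(450.0, 460.0)
        props = OpticalProperties(grid, np.ones(10), np.ones(10))
        return InversionResult({"oxyhemoglobin": oxy, "deoxyhemoglobin": deoxy},
                               PowerLaw(10.0, 1.0), props, 0.0, True, (450, 600), 3)

    def test_fully_oxygenated(self):
        ve = vascular_endpoints(self._result(10.0, 0.0))
        assert ve.total_hemoglobin == 10.0 and ve.oxygen_saturation == 1.0

    def test_half_saturated(self):
        ve = vascular_endpoints(self._result(5.0, 5.0))
        assert ve.total_hemoglobin == 10.0 and ve.oxygen_saturation == 0.5

    def test_zero_hemoglobin_saturation_undefined(self):
        ve = vascular_endpoints(self._result(0.0, 0.0))
        assert ve.total_hemoglobin == 0.0 and ve.oxygen_saturation is None

    def test_missing_chromophores_rejected(self):
        grid = np.arange(450.0, 460.0)
        props = OpticalProperties(grid, np.ones(10), np.ones(10))
        res = InversionResult({"melanin": 1.0}, PowerLaw(10.0, 1.0), props,
                              0.0, True, (450, 600), 3)
        with pytest.raises(InvalidArgumentError):
            vascular_endpoints(res)


class TestFluorescenceCorrection:
    def test_round_trip_identity(self, baseline, table1, fluorophores, basis):
        props = phantom_optical_properties(table1[0], basis)
        intrinsic = fluorophores[0].intrinsic_spectrum(500.0)
        measured = model_fluorescence(intrinsic, 488.0, props, baseline, 1.0)
        recovered = correct_fluorescence(measured, 488.0, props, baseline,
                                         CalibrationFactor(1.0))
        np.testing.assert_allclose(recovered.values, intrinsic.values, rtol=1e-6)
        assert recovered.unit == "c.u."

    def test_correction_equalizes_scattering_levels(self, baseline, basis, fluorophores):
        """Same fluorophore at musp 10 vs 20: measured magnitudes differ,
        corrected spectra agree."""
        intrinsic = fluorophores[0].intrinsic_spectrum(400.0)
        grid = np.arange(420.0, 761.0)
        flat_mua = np.full(grid.size, 0.3)
        corrected = []
        for musp in (10.0, 20.0):
            props = OpticalProperties(grid, flat_mua, np.full(grid.size, musp),
                                      anisotropy_g=0.9, refractive_index=1.33)
            measured = model_fluorescence(intrinsic, 488.0, props, baseline, 1.0)
            corrected.append(correct_fluorescence(measured, 488.0, props, baseline,
                                                  CalibrationFactor(1.0)).values)
        np.testing.assert_allclose(corrected[0], corrected[1], rtol=1e-9)

    def test_hemoglobin_distortion_shifts_tmre_peak_red_and_back(
            self, baseline, table1, fluorophores, basis):
        """Hemoglobin absorption suppresses the blue side of the TMRE band,
        pushing the measured peak red of 585 nm; correction restores it."""
        props = phantom_optical_properties(table1[9], basis)  # highest [Hb]
        tmre = fluorophores[1]
        intrinsic = tmre.intrinsic_spectrum(10.0)
        measured = model_fluorescence(intrinsic, tmre.excitation, props, baseline, 1.0)
        corrected = correct_fluorescence(measured, tmre.excitation, props, baseline,
                                         CalibrationFactor(1.0))
        peak_measured = TMRE_EMISSION_GRID[np.argmax(measured.values)]
        peak_corrected = TMRE_EMISSION_GRID[np.argmax(corrected.values)]
        assert peak_measured > peak_corrected
        assert peak_corrected == pytest.approx(585.0, abs=1.5)


class TestPeakIntensity:
    def test_constant_spectrum(self):
        s = Spectrum(np.arange(500.0, 521.0), np.full(21, 7.5), unit="c.u.",
                     kind="fluorescence")
        assert peak_intensity(s, 510.0) == 7.5

    def test_hand_computed_window_mean(self):
        grid = np.arange(505.0, 516.0)
        s = Spectrum(grid, grid - 508.0, unit="c.u.", kind="fluorescence")
        # window 507.5..512.5 -> grid points 508..512 -> values 0..4 -> mean 2
        assert peak_intensity(s, 510.0) == pytest.approx(2.0)

    def test_empty_window_rejected(self):
        s = Spectrum(np.arange(505.0, 516.0), np.ones(11))
        with pytest.raises(RangeError):
            peak_intensity(s, 700.0)
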