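"""Shared fixtures: one small baseline simulation and the closed-loop run.

The baseline Monte Carlo is the expensive step, so it is session-scoped and
sized for test speed (1.5e5 photons); statistical assertions in the tests are
calibrated to that ensemble size.
"""

import numpy as np
import pytest

from turbispec import (
    CalibrationFactor,
    ReflectanceLUT,
    calibrate_reference,
    correct_fluorescence,
    default_fluorophores,
    fit_reflectance,
    make_table1_phantoms,
    peak_intensity,
    phantom_geometry,
    run_baseline_mc,
    synthesize_measurement,
    synthetic_hemoglobin_basis,
    vascular_endpoints,
)
from turbispec.inversion import get_lut
from turbispec.phantoms import BODIPY_EXCITATION, BODIPY_PEAK, TMRE_EXCITATION, TMRE_PEAK


@pytest.fixture(scope="session")
def geometry():
    return phantom_geometry()


@pytest.fixture(scope="session")
def baseline(geometry):
    return run_baseline_mc(geometry, reference_scattering=100.0, anisotropy_g=0.9,
                           n_photons=150_000, seed=42)


@pytest.fixture(scope="session")
def lut(baseline):
    return get_lut(baseline)


@pytest.fixture(scope="session")
def basis():
    return synthetic_hemoglobin_basis()


@pytest.fixture(scope="session")
def table1():
    return make_table1_phantoms()


@pytest.fixture(scope="session")
def fluorophores():
    return default_fluorophores()


@pytest.fixture(scope="session")
def closed_loop(baseline, lut, basis, table1, fluorophores):
    """Full Table-1 closed loop: synthesize -> calibrate -> invert -> correct.

    Returns per-phantom expected/extracted mean coefficients, vascular
    endpoints, and corrected fluorescence peak intensities.
    """
    ref = table1[4]
    ref_meas = synthesize_measurement(ref, [], baseline, noise_cv=0.01, seed=999, basis=basis)
    cal = calibrate_reference(ref_meas["reflectance"], ref_meas["props"], baseline)
    out = {
        "calibration": cal,
        "expected_mua": [], "extracted_mua": [],
        "expected_musp": [], "extracted_musp": [],
        "expected_hb": [], "extracted_hb": [], "extracted_so2": [],
        "bodipy_conc": [], "bodipy_peak": [],
        "tmre_conc": [], "tmre_peak": [],
    }
    for i, ph in enumerate(table1):
        m = synthesize_measurement(ph, fluorophores, baseline, noise_cv=0.01,
                                   seed=100 + i, basis=basis)
        res = fit_reflectance(m["reflectance"], basis, ph.scatterer, baseline, cal, lut=lut)
        ve = vascular_endpoints(res)
        out["expected_mua"].append(ph.expected_mua)
        out["extracted_mua"].append(res.mean_mua())
        out["expected_musp"].append(ph.expected_musp)
        out["extracted_musp"].append(res.mean_musp())
        out["expected_hb"].append(ph.hemoglobin)
        out["extracted_hb"].append(ve.total_hemoglobin)
        out["extracted_so2"].append(ve.oxygen_saturation)
        cb = correct_fluorescence(m["bodipy"], BODIPY_EXCITATION, res.props, baseline, cal)
        ct = correct_fluorescence(m["tmre"], TMRE_EXCITATION, res.props, baseline, cal)
        out["bodipy_conc"].append(ph.bodipy)
        out["bodipy_peak"].append(peak_intensity(cb, BODIPY_PEAK))
        out["tmre_conc"].append(ph.tmre)
        out["tmre_peak"].append(peak_intensity(ct, TMRE_PEAK))
    return {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in out.items()}
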