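"""End-to-end pipeline: simulate phantoms -> invert -> correct -> analyze.

Everything is driven by a :class:`RunConfig`; all randomness flows from its
seed, so re-running the same config reproduces every artifact bit-for-bit.
Artifacts land in the output directory with a ``provenance.json`` recording
the config hash and seeds; on a stage failure, partial outputs are kept under
a ``failed/`` marker and a :class:`~turbispec.errors.StageError` names the
stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from ._version import __version__
from .analysis import cluster_endpoints, endpoint_subsets
from .chromophores import synthetic_hemoglobin_basis
from .cohort import mammary_aging_design, synthesize_cohort
from .errors import StageError, TurbispecError
from .geometry import phantom_geometry
from .inversion import (
    CalibrationFactor,
    calibrate_reference,
    correct_fluorescence,
    fit_reflectance,
    get_lut,
    peak_intensity,
    vascular_endpoints,
)
from .io import write_endpoint_table, write_json, write_spectrum
from .montecarlo import run_baseline_mc
from .phantoms import (
    BODIPY_EXCITATION,
    BODIPY_PEAK,
    TMRE_EXCITATION,
    TMRE_PEAK,
    default_fluorophores,
    make_table1_phantoms,
    synthesize_measurement,
)


@dataclass
class RunConfig:
    """Settings for one pipeline run; see docs/methods.md for defaults."""

    seed: int = 0
    n_photons: int = 300_000
    reference_scattering: float = 100.0  # mu_s of the baseline medium, cm^-1
    anisotropy_g: float = 0.9
    noise_cv: float = 0.01
    fit_window: tuple = (450.0, 600.0)
    reference_phantom_index: int = 4  # 0-based; mid-series reference
    cohort_n_per_group: int = 20
    output_dir: str = "turbispec_run"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = {k: doc[k] for k in doc if k in cls.__dataclass_fields__}
        cfg = cls(**kwargs)
        if isinstance(cfg.fit_window, list):
            cfg.fit_window = tuple(cfg.fit_window)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "baseline-mc"
        geometry = phantom_geometry()
        baseline = run_baseline_mc(
            geometry,
            reference_scattering=config.reference_scattering,
            anisotropy_g=config.anisotropy_g,
            n_photons=config.n_photons,
            seed=config.seed,
        )
        baseline.save(out / "baseline" / "baseline.npz")

        stage = "simulate-phantoms"
        basis = synthetic_hemoglobin_basis()
        phantoms = make_table1_phantoms()
        fluors = default_fluorophores()
        measurements = []
        for i, ph in enumerate(phantoms):
            m = synthesize_measurement(
                ph, fluors, baseline, noise_cv=config.noise_cv,
                seed=config.seed * 1000 + i, basis=basis,
            )
            measurements.append(m)
            for key in ("reflectance", "bodipy", "tmre"):
                write_spectrum(m[key], out / "phantoms" / f"{ph.label}_{key}.csv")

        stage = "invert"
        ref = phantoms[config.reference_phantom_index]
        ref_meas = synthesize_measurement(
            ref, [], baseline, noise_cv=config.noise_cv,
            seed=config.seed * 1000 + 999, basis=basis,
        )
        calibration = calibrate_reference(ref_meas["reflectance"], ref_meas["props"], baseline)
        lut = get_lut(baseline)
        inversions = []
        for ph, m in zip(phantoms, measurements):
            res = fit_reflectance(
                m["reflectance"], basis, ph.scatterer, baseline, calibration,
                fit_window=config.fit_window, lut=lut,
            )
            ve = vascular_endpoints(res)
            report = res.report()
            report["vascular"] = {
                "total_hemoglobin_uM": ve.total_hemoglobin,
                "oxygen_saturation": ve.oxygen_saturation,
            }
            report["expected"] = {"mean_mua_cm1": ph.expected_mua,
                                  "mean_musp_cm1": ph.expected_musp,
                                  "hemoglobin_uM": ph.hemoglobin}
            write_json(report, out / "inversions" / f"{ph.label}.json")
            inversions.append((ph, m, res))

        stage = "correct"
        fluor_summary = {}
        for ph, m, res in inversions:
            row = {}
            for name, ex, peak in (("bodipy", BODIPY_EXCITATION, BODIPY_PEAK),
                                   ("tmre", TMRE_EXCITATION, TMRE_PEAK)):
                corrected = correct_fluorescence(m[name], ex, res.props, baseline, calibration)
                write_spectrum(corrected, out / "corrected" / f"{ph.label}_{name}.csv")
                row[name] = peak_intensity(corrected, peak)
            fluor_summary[ph.label] = row
        write_json(fluor_summary, out / "corrected" / "peak_intensities.json")

        stage = "analyze"
        design = mammary_aging_design(n_per_group=config.cohort_n_per_group, seed=config.seed)
        cohort = synthesize_cohort(design)
        write_endpoint_table(cohort, out / "analysis" / "cohort.csv")
        analysis = {
            subsetname(sub): cluster_endpoints(cohort, sub, seed=config.seed).report()
            for sub in endpoint_subsets()
        }
        write_json(analysis, out / "analysis" / "clustering.json")

        write_json(
            {
                "config": asdict(config),
                "config_digest": config.digest(),
                "package_version": __version__,
                "baseline_cache_key": baseline.cache_key(),
            },
            out / "provenance.json",
        )
    except TurbispecError as exc:
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / "stage.txt").write_text(f"{stage}\n{exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    return out


def subsetname(subset) -> str:
    return "+".join(subset)
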