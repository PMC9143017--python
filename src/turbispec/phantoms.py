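"""Tissue-mimicking phantom design and synthetic measurements.

A liquid phantom is hemoglobin (absorber) + monodisperse 1-um polystyrene
spheres (scatterer) + up to two fluorophores (Bodipy FL C16, protein-bound
emission peak 510 nm at 488 nm excitation; TMRE, peak 585 nm at 555 nm
excitation) in water.  The bundled ten-phantom dilution series spans the
breast-tissue optical-property range: mean absorption 0.14-0.49 cm^-1 and
mean reduced scattering 5.97-16.72 cm^-1 over 450-600 nm, with hemoglobin
15.09-53.89 uM and fluorophore dilutions locked to the same series.

Synthetic "measurements" run the phantom recipe through the scaled-baseline
forward Monte Carlo on the instrument acquisition grids (reflectance
420-760 nm; Bodipy emission 505-635 nm; TMRE emission 575-705 nm) and apply
multiplicative Gaussian noise of a chosen coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromophores import ChromophoreBasis, hemoglobin_mua, synthetic_hemoglobin_basis
from .errors import ConfigurationError, InvalidArgumentError
from .forward import model_fluorescence, model_reflectance_spectrum
from .montecarlo import BaselineSimulation
from .scattering import MieSphere, PowerLaw, density_for_musp, mie_musp
from .spectra import OpticalProperties, Spectrum

REFLECTANCE_GRID = np.arange(420.0, 761.0)
BODIPY_EMISSION_GRID = np.arange(505.0, 636.0)
TMRE_EMISSION_GRID = np.arange(575.0, 706.0)
BODIPY_EXCITATION = 488.0
TMRE_EXCITATION = 555.0
BODIPY_PEAK = 510.0
TMRE_PEAK = 585.0

# printed ten-phantom series: (mean mua, mean musp, [Hb] uM, [Bodipy] nM, [TMRE] nM)
_TABLE1 = (
    (0.14, 16.72, 15.09, 1000.0, 15.0),
    (0.23, 13.93, 25.15, 833.33, 12.5),
    (0.29, 11.94, 32.33, 714.29, 10.71),
    (0.34, 10.45, 37.72, 625.0, 9.38),
    (0.38, 9.29, 41.91, 555.56, 8.33),
    (0.41, 8.36, 45.26, 500.0, 7.5),
    (0.44, 7.60, 48.01, 454.55, 6.82),
    (0.46, 6.97, 50.29, 416.67, 6.25),
    (0.48, 6.43, 52.23, 384.62, 5.77),
    (0.49, 5.97, 53.89, 357.14, 5.36),
)


@dataclass(frozen=True)
class PhantomSpec:
    """One liquid-phantom recipe.

    ``expected_mua`` / ``expected_musp`` carry the design's target mean
    coefficients over the 450-600 nm window, when known (the bundled series).
    """

    hemoglobin: float  # uM
    oxygen_fraction: float
    scatterer: object  # MieSphere or PowerLaw
    bodipy: float  # nM
    tmre: float  # nM
    label: str = ""
    expected_mua: float | None = None
    expected_musp: float | None = None

    def __post_init__(self):
        if min(self.hemoglobin, self.bodipy, self.tmre) < 0:
            raise InvalidArgumentError("concentrations must be non-negative")
        if not 0 <= self.oxygen_fraction <= 1:
            raise InvalidArgumentError("oxygen fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FluorophoreSpec:
    """Fluorophore channel: excitation line, emission lineshape, brightness."""

    name: str
    excitation: float  # nm
    emission_peak: float  # nm
    lineshape: Spectrum  # unit-area emission profile on the acquisition grid
    brightness: float = 1.0  # c.u. per nM at unit lineshape height

    def __post_init__(self):
        ls = self.lineshape
        if np.any(ls.values < 0):
            raise InvalidArgumentError("lineshape must be non-negative")
        area = np.trapezoid(ls.values, ls.grid)
        if not np.isclose(area, 1.0, rtol=1e-6):
            raise InvalidArgumentError("lineshape must integrate to 1 on its grid")
        if not ls.grid[0] <= self.emission_peak <= ls.grid[-1]:
            raise InvalidArgumentError("emission peak must lie within the lineshape support")

    def intrinsic_spectrum(self, concentration_nM: float) -> Spectrum:
        if concentration_nM < 0:
            raise InvalidArgumentError("concentration must be non-negative")
        return Spectrum(
            self.lineshape.grid,
            self.brightness * concentration_nM * self.lineshape.values,
            unit="c.u.",
            kind="fluorescence",
        )


def lognormal_lineshape(grid, peak: float, width: float, shape: float = 0.35) -> Spectrum:
    """Asymmetric (log-normal) emission profile with its mode at ``peak``.

    ``width`` sets the peak-to-onset distance in nm; the long-wavelength tail
    follows the log-normal skew typical of dye emission.  Normalized to unit
    area on the supplied grid.
    """
    grid = np.asarray(grid, dtype=float)
    if width <= 0 or shape <= 0:
        raise InvalidArgumentError("width and shape must be positive")
    onset = peak - width
    t = grid - onset
    vals = np.zeros_like(grid)
    pos = t > 0
    median = width * np.exp(shape**2)  # places the mode exactly at `peak`
    vals[pos] = np.exp(-0.5 * ((np.log(t[pos]) - np.log(median)) / shape) ** 2) / t[pos]
    area = np.trapezoid(vals, grid)
    if area <= 0:
        raise InvalidArgumentError("lineshape support does not intersect the grid")
    return Spectrum(grid, vals / area, unit="dimensionless", kind="fluorescence")


def default_fluorophores(bodipy_brightness: float = 1.0, tmre_brightness: float = 1.0) -> list:
    """The two metabolic reporters on their acquisition grids."""
    return [
        FluorophoreSpec(
            "bodipy", BODIPY_EXCITATION, BODIPY_PEAK,
            lognormal_lineshape(BODIPY_EMISSION_GRID, BODIPY_PEAK, width=18.0),
            brightness=bodipy_brightness,
        ),
        FluorophoreSpec(
            "tmre", TMRE_EXCITATION, TMRE_PEAK,
            lognormal_lineshape(TMRE_EMISSION_GRID, TMRE_PEAK, width=22.0),
            brightness=tmre_brightness,
        ),
    ]


def make_table1_phantoms(basis: ChromophoreBasis | None = None) -> list[PhantomSpec]:
    """The bundled ten-phantom dilution series.

    Hemoglobin is fully oxygenated (aerated aqueous stock); the 1-um
    polystyrene number density is solved so musp at 550 nm equals the printed
    mean reduced scattering coefficient.
    """
    del basis  # recipe is basis-independent; kept for interface symmetry
    sphere = MieSphere(diameter=1.0, sphere_index=1.59, medium_index=1.33)
    out = []
    for i, (mua, musp, hb, bodipy, tmre) in enumerate(_TABLE1, start=1):
        out.append(
            PhantomSpec(
                hemoglobin=hb,
                oxygen_fraction=1.0,
                scatterer=density_for_musp(sphere, musp, 550.0),
                bodipy=bodipy,
                tmre=tmre,
                label=f"phantom_{i}",
                expected_mua=mua,
                expected_musp=musp,
            )
        )
    return out


def phantom_optical_properties(
    phantom: PhantomSpec,
    basis: ChromophoreBasis | None = None,
    grid=REFLECTANCE_GRID,
) -> OpticalProperties:
    """Absorption + reduced scattering spectra implied by a phantom recipe."""
    if basis is None:
        basis = synthetic_hemoglobin_basis()
    grid = np.asarray(grid, dtype=float)
    mua = hemoglobin_mua(phantom.hemoglobin, phantom.oxygen_fraction, basis, grid).values
    if isinstance(phantom.scatterer, MieSphere):
        mie = mie_musp(phantom.scatterer, grid)
        musp = mie["musp"].values
        g = float(np.interp(550.0, grid, mie["anisotropy_g"]))
    elif isinstance(phantom.scatterer, PowerLaw):
        musp = phantom.scatterer.musp(grid)
        g = 0.9
    else:
        raise ConfigurationError(f"unknown scatterer {type(phantom.scatterer).__name__}")
    return OpticalProperties(grid, mua, musp, anisotropy_g=g, refractive_index=1.33)


def synthesize_measurement(
    phantom: PhantomSpec,
    fluors: list,
    baseline: BaselineSimulation,
    noise_cv: float = 0.01,
    seed: int = 0,
    basis: ChromophoreBasis | None = None,
    calibration_factor: float = 1.0,
) -> dict:
    """Forward-model one phantom into noisy instrument spectra.

    Returns ``{"reflectance", "bodipy", "tmre", "props"}``; fluorescence keys
    follow the fluorophore names.  Multiplicative Gaussian noise with
    coefficient of variation ``noise_cv`` is applied independently per
    wavelength; the synthesis is a pure function of (inputs, seed).
    """
    if noise_cv < 0:
        raise InvalidArgumentError("noise_cv must be non-negative")
    if basis is None:
        basis = synthetic_hemoglobin_basis()
    rng = np.random.default_rng(seed)
    props = phantom_optical_properties(phantom, basis)
    refl = model_reflectance_spectrum(props, baseline, calibration_factor)
    out = {"props": props}
    out["reflectance"] = refl.with_values(
        refl.values * (1.0 + noise_cv * rng.standard_normal(refl.values.size))
    )
    for fl in fluors:
        if fl.name == "bodipy":
            conc = phantom.bodipy
        elif fl.name == "tmre":
            conc = phantom.tmre
        else:
            raise ConfigurationError(f"phantom has no concentration for channel {fl.name!r}")
        measured = model_fluorescence(
            fl.intrinsic_spectrum(conc), fl.excitation, props, baseline, calibration_factor
        )
        out[fl.name] = measured.with_values(
            measured.values * (1.0 + noise_cv * rng.standard_normal(measured.values.size))
        )
    return out
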