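"""Inverse model: optical properties, vascular endpoints, intrinsic fluorescence.

The extraction chain mirrors reference-phantom-calibrated probe spectroscopy:

1. :func:`calibrate_reference` — one measured phantom of known optical
   properties fixes the instrument scale between measured counts and modeled
   collected reflectance.
2. :func:`fit_reflectance` — bounded nonlinear least squares over
   non-negative chromophore concentrations and scatterer parameters; the
   forward model is the scaled-baseline Monte Carlo.  mua is composed by
   Beer-Lambert (ln 10 * sum eps_i c_i), musp by Mie theory (known sphere,
   free density) or a wavelength power law (tissue).
3. :func:`vascular_endpoints` — [Hb] = c_HbO2 + c_dHb and
   SO2 = c_HbO2 / [Hb] from the fitted concentrations.
4. :func:`correct_fluorescence` — divides the measured emission spectrum by
   the same separable distortion factor used by the forward fluorescence
   model, evaluated at the *extracted* optical properties, yielding intrinsic
   fluorescence in corrected units.  Because forward and inverse share one
   distortion function, the closed loop is an exact round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .chromophores import LN10, ChromophoreBasis
from .errors import DegenerateInputError, InvalidArgumentError, RangeError
from .forward import (
    ReflectanceLUT,
    distortion_factor,
    model_reflectance_spectrum,
)
from .montecarlo import BaselineSimulation
from .scattering import MieSphere, PowerLaw, density_for_musp, mie_musp
from .spectra import OpticalProperties, Spectrum

DEFAULT_FIT_WINDOW = (450.0, 600.0)
_DISTORTION_FLOOR = 1e-12


@dataclass(frozen=True)
class CalibrationFactor:
    """Instrument scale factors linking measured counts to model units."""

    reflectance_scale: float
    fluorescence_scale: float = 1.0

    def __post_init__(self):
        if self.reflectance_scale <= 0 or self.fluorescence_scale <= 0:
            raise InvalidArgumentError("calibration scales must be positive")


@dataclass(frozen=True)
class VascularEndpoints:
    """Total hemoglobin (uM) and oxygen saturation (fraction, None if [Hb]=0)."""

    total_hemoglobin: float
    oxygen_saturation: Optional[float]

    def __post_init__(self):
        if self.total_hemoglobin < 0:
            raise InvalidArgumentError("total hemoglobin must be non-negative")
        if self.oxygen_saturation is not None and not 0 <= self.oxygen_saturation <= 1:
            raise InvalidArgumentError("oxygen saturation must lie in [0, 1]")


@dataclass
class InversionResult:
    """Output of :func:`fit_reflectance`."""

    concentrations: dict  # chromophore name -> uM
    scatter_params: object  # fitted MieSphere or PowerLaw
    props: OpticalProperties  # reconstructed on the basis grid
    residual_norm: float
    converged: bool
    fit_window: tuple
    n_starts: int

    def report(self) -> dict:
        scatter = self.scatter_params
        if isinstance(scatter, PowerLaw):
            sc = {"form": "power_law", "amplitude": scatter.amplitude,
                  "exponent": scatter.exponent,
                  "reference_wavelength": scatter.reference_wavelength}
        else:
            sc = {"form": "mie_sphere", "diameter_um": scatter.diameter,
                  "sphere_index": scatter.sphere_index,
                  "medium_index": scatter.medium_index,
                  "number_density_per_cm3": scatter.number_density}
        return {
            "concentrations_uM": dict(self.concentrations),
            "scatter": sc,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "fit_window_nm": list(self.fit_window),
            "mean_mua_window_cm1": float(self.mean_mua()),
            "mean_musp_window_cm1": float(self.mean_musp()),
        }

    def _window_mask(self):
        lo, hi = self.fit_window
        return (self.props.grid >= lo) & (self.props.grid <= hi)

    def mean_mua(self) -> float:
        """Mean extracted mua over the fit window (cm^-1)."""
        return float(self.props.mua[self._window_mask()].mean())

    def mean_musp(self) -> float:
        """Mean extracted musp over the fit window (cm^-1)."""
        return float(self.props.musp[self._window_mask()].mean())


def get_lut(baseline: BaselineSimulation) -> ReflectanceLUT:
    """Build (once) and cache the reflectance lookup for a baseline."""
    lut = getattr(baseline, "_reflectance_lut", None)
    if lut is None:
        lut = ReflectanceLUT(baseline)
        baseline._reflectance_lut = lut
    return lut


def calibrate_reference(
    measured_reference: Spectrum,
    known_props: OpticalProperties,
    baseline: BaselineSimulation,
    fluorescence_scale: float = 1.0,
) -> CalibrationFactor:
    """Reflectance calibration from a reference phantom of known properties.

    The scale is the median, over overlapping wavelengths, of measured over
    modeled reflectance — robust to a few noisy wavelengths.
    """
    lo = max(measured_reference.grid[0], known_props.grid[0])
    hi = min(measured_reference.grid[-1], known_props.grid[-1])
    overlap = measured_reference.grid[(measured_reference.grid >= lo) & (measured_reference.grid <= hi)]
    if overlap.size < 10:
        raise RangeError("measured and known-property grids overlap on fewer than 10 wavelengths")
    mua = np.interp(overlap, known_props.grid, known_props.mua)
    musp = np.interp(overlap, known_props.grid, known_props.musp)
    modeled = model_reflectance_spectrum(
        OpticalProperties(overlap, mua, musp, known_props.anisotropy_g, known_props.refractive_index),
        baseline,
    ).values
    if np.any(modeled <= 0):
        raise DegenerateInputError("modeled reference reflectance is non-positive")
    ratio = measured_reference.interp(overlap) / modeled
    scale = float(np.median(ratio))
    if scale <= 0:
        raise DegenerateInputError("non-positive reference calibration scale")
    return CalibrationFactor(reflectance_scale=scale, fluorescence_scale=fluorescence_scale)


def _scatter_parameterization(scatter_form):
    """(n_params, bounds, musp_fn, rebuild_fn, start_grid) for the form."""
    if isinstance(scatter_form, PowerLaw):
        lam0 = scatter_form.reference_wavelength

        def musp_fn(p, grid):
            return p[0] * (grid / lam0) ** (-p[1])

        def rebuild(p):
            return PowerLaw(float(p[0]), float(p[1]), lam0)

        bounds = (np.array([1e-3, 0.0]), np.array([100.0, 4.0]))
        starts = [np.array([5.0, 1.0]), np.array([10.0, 1.0]), np.array([20.0, 0.5])]
        return bounds, musp_fn, rebuild, starts
    if isinstance(scatter_form, MieSphere):
        unit_sphere = replace(scatter_form, number_density=1.0)

        def make_musp_cache(grid):
            res = mie_musp(unit_sphere, grid)
            return res["musp"].values  # per unit density

        cache = {}

        def musp_fn(p, grid):
            key = (grid[0], grid[-1], grid.size)
            if key not in cache:
                cache[key] = make_musp_cache(grid)
            return p[0] * cache[key]

        def rebuild(p):
            return replace(scatter_form, number_density=float(p[0]))

        d5 = density_for_musp(scatter_form, 5.0, 550.0).number_density
        d10 = density_for_musp(scatter_form, 10.0, 550.0).number_density
        d20 = density_for_musp(scatter_form, 20.0, 550.0).number_density
        bounds = (np.array([0.0]), np.array([d20 * 10.0]))
        starts = [np.array([d5]), np.array([d10]), np.array([d20])]
        return bounds, musp_fn, rebuild, starts
    raise InvalidArgumentError(f"unsupported scatter form {type(scatter_form).__name__}")


def fit_reflectance(
    measured: Spectrum,
    basis: ChromophoreBasis,
    scatter_form,
    baseline: BaselineSimulation,
    calibration: CalibrationFactor,
    fit_window: tuple = DEFAULT_FIT_WINDOW,
    lut: ReflectanceLUT | None = None,
) -> InversionResult:
    """Extract chromophore concentrations and scatter parameters.

    Bounded trust-region least squares on sum_lam (measured - model)^2 over
    the fit window, restarted from >=3 deterministic initial points; the
    winner is the lowest residual, ties broken by the lexicographically
    smallest parameter vector.
    """
    lo, hi = fit_window
    if lo < measured.grid[0] or hi > measured.grid[-1]:
        raise RangeError(
            f"fit window [{lo:g}, {hi:g}] nm not contained in the measured grid "
            f"[{measured.grid[0]:g}, {measured.grid[-1]:g}] nm"
        )
    win = measured.window(lo, hi)
    if not np.any(win.values != 0):
        raise DegenerateInputError("measured reflectance is identically zero in the fit window")
    grid = win.grid
    y = win.values
    ext = np.vstack([np.interp(grid, basis.grid, e) for e in basis.extinction])
    n_chrom = len(basis.names)
    sc_bounds, musp_fn, rebuild, sc_starts = _scatter_parameterization(scatter_form)
    if lut is None:
        lut = get_lut(baseline)
    scale = calibration.reflectance_scale

    def residual(p):
        c = p[:n_chrom]
        mua = LN10 * (c @ ext)
        musp = musp_fn(p[n_chrom:], grid)
        return scale * lut(mua, musp) - y

    lower = np.concatenate([np.zeros(n_chrom), sc_bounds[0]])
    upper = np.concatenate([np.full(n_chrom, 500.0), sc_bounds[1]])
    conc_starts = [
        np.full(n_chrom, 10.0),
        np.concatenate([[40.0], np.full(n_chrom - 1, 2.0)]) if n_chrom > 1 else np.array([40.0]),
        np.concatenate([[2.0], np.full(n_chrom - 1, 40.0)]) if n_chrom > 1 else np.array([2.0]),
    ]
    best = None
    n_starts = 0
    for cs, ss in zip(conc_starts, sc_starts):
        x0 = np.clip(np.concatenate([cs, ss]), lower, upper + 0.0)
        sol = least_squares(residual, x0, bounds=(lower, upper), method="trf", x_scale="jac")
        n_starts += 1
        key = (sol.cost, tuple(sol.x))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    c = sol.x[:n_chrom]
    fitted_scatter = rebuild(sol.x[n_chrom:])
    full_grid = basis.grid
    mua_full = basis.mua(c)
    if isinstance(fitted_scatter, PowerLaw):
        musp_full = fitted_scatter.musp(full_grid)
        g = baseline.anisotropy_g
    else:
        mie = mie_musp(fitted_scatter, full_grid)
        musp_full = mie["musp"].values
        g = float(np.interp(550.0, full_grid, mie["anisotropy_g"]))
    props = OpticalProperties(
        full_grid, mua_full, np.maximum(musp_full, 0.0), anisotropy_g=g,
        refractive_index=baseline.geometry.medium_refractive_index,
    )
    return InversionResult(
        concentrations={name: float(ci) for name, ci in zip(basis.names, c)},
        scatter_params=fitted_scatter,
        props=props,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
        fit_window=(float(lo), float(hi)),
        n_starts=n_starts,
    )


def vascular_endpoints(result: InversionResult) -> VascularEndpoints:
    """[Hb] and SO2 from the fitted oxy/deoxy concentrations."""
    try:
        oxy = result.concentrations["oxyhemoglobin"]
        deoxy = result.concentrations["deoxyhemoglobin"]
    except KeyError as exc:
        raise InvalidArgumentError("basis must contain oxy- and deoxy-hemoglobin") from exc
    total = oxy + deoxy
    if total == 0:
        return VascularEndpoints(total_hemoglobin=0.0, oxygen_saturation=None)
    return VascularEndpoints(total_hemoglobin=float(total), oxygen_saturation=float(oxy / total))


def correct_fluorescence(
    measured_fluor: Spectrum,
    excitation_wavelength: float,
    props: OpticalProperties,
    baseline: BaselineSimulation,
    calibration: CalibrationFactor,
) -> Spectrum:
    """Divide out the turbidity distortion to recover intrinsic fluorescence."""
    d = distortion_factor(measured_fluor.grid, excitation_wavelength, props, baseline)
    if np.any(d < _DISTORTION_FLOOR):
        raise DegenerateInputError(
            "distortion factor fell below the positivity floor; optical "
            "properties are too extreme for a stable correction"
        )
    return Spectrum(
        measured_fluor.grid,
        measured_fluor.values / (d * calibration.fluorescence_scale),
        unit="c.u.",
        kind="fluorescence",
    )


def peak_intensity(corrected: Spectrum, peak_wavelength: float, halfwidth: float = 2.5) -> float:
    """Average intensity of wavelengths within ``halfwidth`` nm of the peak."""
    if halfwidth < 0:
        raise InvalidArgumentError("halfwidth must be non-negative")
    mask = np.abs(corrected.grid - peak_wavelength) <= halfwidth
    if not mask.any():
        raise RangeError(
            f"no grid points within {halfwidth:g} nm of {peak_wavelength:g} nm"
        )
    return float(corrected.values[mask].mean())
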