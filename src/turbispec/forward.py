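"""Forward predictions from a stored baseline simulation.

Similarity-relation scaling: a scattering-only random walk at reference
coefficient mu_s,ref maps onto a walk at target mu_s by shrinking/stretching
every geometric length by s = mu_s,ref / mu_s (anisotropy held fixed).
Absorption enters analytically as a path-integral weight exp(-mua * L'), which
is exact and variance-free in mua.  Collected diffuse reflectance at arbitrary
(mua, musp) is therefore a deterministic, smooth function of the stored exit
records.

The fluorescence forward operator distorts an intrinsic emission spectrum by a
separable factor D(lx, lm) = R(lx) * R(lm): the collected reflectance at the
excitation wavelength stands in for the excitation fluence delivered to (and
returned from) the sensing volume, and the collected reflectance at each
emission wavelength for the escape-and-collection probability of emitted
photons.  This first-order factorization is what makes the turbidity
correction an exact division in the inverse direction.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .errors import InvalidArgumentError, RangeError
from .montecarlo import BaselineSimulation
from .spectra import OpticalProperties, Spectrum


def scale_reflectance(baseline: BaselineSimulation, target_mua, target_musp) -> float | np.ndarray:
    """Collected reflectance at target optical properties via record rescaling.

    Accepts scalar or equal-length array targets; returns matching shape.
    Exit radii and path lengths scale by mu_s,ref / mu_s,target; each record
    is attenuated by exp(-mua * L_scaled) and re-binned against the detector
    annulus through the analytic source-disk convolution.
    """
    mua = np.atleast_1d(np.asarray(target_mua, dtype=float))
    musp = np.atleast_1d(np.asarray(target_musp, dtype=float))
    if mua.shape != musp.shape:
        raise InvalidArgumentError("target_mua and target_musp must have matching shapes")
    if np.any(musp <= 0):
        raise InvalidArgumentError("target_musp must be positive")
    if np.any(mua < 0):
        raise InvalidArgumentError("target_mua must be non-negative")
    mus_target = musp / (1.0 - baseline.anisotropy_g)
    s = baseline.reference_scattering / mus_target  # per-target geometric scale
    out = np.empty(mua.shape)
    rho = baseline.exit_radius
    plen = baseline.total_path_length
    w = baseline.survival_weight
    n = baseline.n_photons_launched
    for i in range(mua.size):
        rho_s = rho * s.flat[i]
        len_s = plen * s.flat[i]
        coll = baseline.collection_weights(rho_s)
        out.flat[i] = np.sum(w * np.exp(-mua.flat[i] * len_s) * coll) / n
    if np.isscalar(target_mua) and np.isscalar(target_musp):
        return float(out[0])
    return out


class ReflectanceLUT:
    """Smooth spline lookup of scaled reflectance over a (mua, musp) grid.

    Built once per baseline; used by the iterative inversion where thousands
    of forward evaluations are needed.  The underlying function is smooth in
    both arguments (fixed records, analytic weights), so a modest grid
    reproduces the exact record sum to a relative accuracy far below
    measurement noise.
    """

    def __init__(
        self,
        baseline: BaselineSimulation,
        mua_max: float = 4.0,
        musp_range: tuple[float, float] = (1.0, 40.0),
        n_mua: int = 60,
        n_musp: int = 48,
    ):
        self.baseline = baseline
        self.mua_grid = np.linspace(0.0, mua_max, n_mua)
        self.musp_grid = np.geomspace(musp_range[0], musp_range[1], n_musp)
        vals = np.empty((n_mua, n_musp))
        for j, mp in enumerate(self.musp_grid):
            vals[:, j] = scale_reflectance(baseline, self.mua_grid, np.full(n_mua, mp))
        self._spline = RectBivariateSpline(self.mua_grid, np.log(self.musp_grid), vals, kx=3, ky=3)

    def __call__(self, mua, musp):
        mua = np.asarray(mua, dtype=float)
        musp = np.asarray(musp, dtype=float)
        out = self._spline(
            np.clip(mua, self.mua_grid[0], self.mua_grid[-1]),
            np.clip(np.log(musp), np.log(self.musp_grid[0]), np.log(self.musp_grid[-1])),
            grid=False,
        )
        return np.maximum(out, 0.0)


def model_reflectance_spectrum(
    props: OpticalProperties,
    baseline: BaselineSimulation,
    calibration_factor: float = 1.0,
    model: ReflectanceLUT | None = None,
) -> Spectrum:
    """Predicted collected-reflectance spectrum (a.u.) for a medium.

    Uses the exact record sum unless a prebuilt :class:`ReflectanceLUT` is
    supplied.
    """
    if props.grid.size == 0:
        raise InvalidArgumentError("property grid must be nonempty")
    if model is not None:
        refl = model(props.mua, props.musp)
    else:
        refl = scale_reflectance(baseline, props.mua, props.musp)
    return Spectrum(props.grid, calibration_factor * np.asarray(refl), unit="a.u.", kind="reflectance")


def distortion_factor(
    emission_grid: np.ndarray,
    excitation_wavelength: float,
    props: OpticalProperties,
    baseline: BaselineSimulation,
) -> np.ndarray:
    """Separable turbidity distortion D(lx, lm) on the emission grid.

    Strictly positive for finite optical properties; raises RangeError when
    the excitation or emission wavelengths fall outside the property grid.
    """
    emission_grid = np.asarray(emission_grid, dtype=float)
    lam_lo, lam_hi = props.grid[0], props.grid[-1]
    if not lam_lo <= excitation_wavelength <= lam_hi:
        raise RangeError(f"excitation {excitation_wavelength:g} nm outside property grid")
    if emission_grid.min() < lam_lo or emission_grid.max() > lam_hi:
        raise RangeError("emission grid extends outside the property grid")
    mua_x, musp_x = props.at(excitation_wavelength)
    r_x = scale_reflectance(baseline, mua_x, musp_x)
    mua_m = np.interp(emission_grid, props.grid, props.mua)
    musp_m = np.interp(emission_grid, props.grid, props.musp)
    r_m = scale_reflectance(baseline, mua_m, musp_m)
    return float(r_x) * np.asarray(r_m)


def model_fluorescence(
    intrinsic: Spectrum,
    excitation_wavelength: float,
    props: OpticalProperties,
    baseline: BaselineSimulation,
    calibration_factor: float = 1.0,
) -> Spectrum:
    """Distort an intrinsic emission spectrum into a measured one (a.u.)."""
    d = distortion_factor(intrinsic.grid, excitation_wavelength, props, baseline)
    return Spectrum(
        intrinsic.grid,
        calibration_factor * d * intrinsic.values,
        unit="a.u.",
        kind="fluorescence",
    )
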