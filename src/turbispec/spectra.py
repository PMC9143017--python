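"""Wavelength-indexed spectra and optical-property containers.

A :class:`Spectrum` is the universal carrier used throughout the package for
measured diffuse reflectance, fluorescence emission, and coefficient spectra.
Units follow the conventions of fiber-probe spectroscopy: raw instrument
intensities are in arbitrary units (``a.u.``), turbidity-corrected intrinsic
fluorescence in corrected units (``c.u.``), and absorption / reduced
scattering coefficients in ``cm^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, RangeError

VALID_UNITS = ("a.u.", "c.u.", "cm^-1", "dimensionless")
VALID_KINDS = ("reflectance", "fluorescence", "coefficient")


def _as_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise InvalidArgumentError("wavelength grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(g)):
        raise InvalidArgumentError("wavelength grid must be finite")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise InvalidArgumentError("wavelength grid must be strictly increasing")
    return g


@dataclass(frozen=True)
class Spectrum:
    """Values sampled on a strictly increasing wavelength grid (nm)."""

    grid: np.ndarray
    values: np.ndarray
    unit: str = "a.u."
    kind: str = "reflectance"

    def __post_init__(self):
        object.__setattr__(self, "grid", _as_grid(self.grid))
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise InvalidArgumentError("values and grid must have the same length")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("spectrum values must be finite")
        object.__setattr__(self, "values", v)
        if self.unit not in VALID_UNITS:
            raise InvalidArgumentError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.kind not in VALID_KINDS:
            raise InvalidArgumentError(f"unknown kind {self.kind!r}; expected one of {VALID_KINDS}")

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi] (inclusive)."""
        mask = (self.grid >= lo) & (self.grid <= hi)
        if not mask.any():
            raise RangeError(f"window [{lo}, {hi}] nm does not intersect the grid")
        return replace(self, grid=self.grid[mask], values=self.values[mask])

    def interp(self, wavelengths) -> np.ndarray:
        """Linear interpolation; raises outside the grid span."""
        w = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        if w.min() < self.grid[0] or w.max() > self.grid[-1]:
            raise RangeError(
                f"requested wavelengths [{w.min():g}, {w.max():g}] nm outside "
                f"grid span [{self.grid[0]:g}, {self.grid[-1]:g}] nm"
            )
        return np.interp(w, self.grid, self.values)

    def with_values(self, values, unit: str | None = None, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, unit or self.unit, kind or self.kind)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficient spectra of a medium.

    ``mua`` and ``musp`` (cm^-1) are sampled on ``grid`` (nm); ``anisotropy_g``
    is the mean cosine of the single-scattering deflection angle and
    ``refractive_index`` the internal (medium) index.
    """

    grid: np.ndarray
    mua: np.ndarray
    musp: np.ndarray
    anisotropy_g: float = 0.9
    refractive_index: float = 1.37

    def __post_init__(self):
        object.__setattr__(self, "grid", _as_grid(self.grid))
        mua = np.asarray(self.mua, dtype=float)
        musp = np.asarray(self.musp, dtype=float)
        if mua.shape != self.grid.shape or musp.shape != self.grid.shape:
            raise InvalidArgumentError("mua/musp must match grid length")
        if np.any(mua < 0) or np.any(musp < 0):
            raise InvalidArgumentError("mua and musp must be non-negative")
        if not 0 <= self.anisotropy_g < 1:
            raise InvalidArgumentError("anisotropy g must lie in [0, 1)")
        if self.refractive_index < 1:
            raise InvalidArgumentError("refractive index must be >= 1")
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)

    def at(self, wavelength: float) -> tuple[float, float]:
        """(mua, musp) at one wavelength by linear interpolation."""
        lam = float(wavelength)
        if lam < self.grid[0] or lam > self.grid[-1]:
            raise RangeError(f"{lam:g} nm outside property grid span")
        return (
            float(np.interp(lam, self.grid, self.mua)),
            float(np.interp(lam, self.grid, self.musp)),
        )

    def mua_spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.mua, unit="cm^-1", kind="coefficient")

    def musp_spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.musp, unit="cm^-1", kind="coefficient")
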