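"""Chromophore bases and Beer-Lambert absorption composition.

Absorption is composed with the molar-extinction convention

    mua(lam) = ln(10) * sum_i eps_i(lam) * c_i        [cm^-1]

with eps in cm^-1 uM^-1 and concentrations in uM.

The bundled oxy/deoxy hemoglobin basis is **synthetic**: a Gaussian-band
emulation of the visible-band features of hemoglobin (Soret band, the oxy
double Q-band at ~542/577 nm vs the single broad deoxy band at ~556 nm, and a
deoxy-dominated red tail).  It is generated in code, not measured; its only
roles are (i) giving the two oxygenation states distinct, physically shaped
spectra so saturation is identifiable, and (ii) matching the absorber lot of
the bundled phantom series, whose window-averaged extinction it reproduces.
Analyses that need dataset independence should construct their own basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .spectra import Spectrum, _as_grid

LN10 = float(np.log(10.0))

# window-averaged (450-600 nm) oxyhemoglobin extinction implied by the bundled
# phantom series' [Hb] <-> mua design, cm^-1 uM^-1
_PHANTOM_WINDOW_EPS = 0.003958


@dataclass(frozen=True)
class ChromophoreBasis:
    """Named molar-extinction spectra on a shared wavelength grid."""

    names: tuple
    grid: np.ndarray
    extinction: np.ndarray  # shape (n_names, n_wavelengths), cm^-1 uM^-1

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "grid", _as_grid(self.grid))
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (len(self.names), self.grid.size):
            raise InvalidArgumentError("extinction must be (n_names, n_wavelengths)")
        if np.any(ext < 0):
            raise InvalidArgumentError("extinction values must be non-negative")
        object.__setattr__(self, "extinction", ext)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidArgumentError(f"chromophore {name!r} not in basis {self.names}") from None

    def extinction_at(self, name: str, wavelengths) -> np.ndarray:
        return np.interp(np.asarray(wavelengths, dtype=float), self.grid,
                         self.extinction[self.index(name)])

    def mua(self, concentrations, wavelengths=None) -> np.ndarray:
        """Beer-Lambert mua (cm^-1) for per-chromophore concentrations (uM)."""
        c = np.asarray(concentrations, dtype=float)
        if c.shape != (len(self.names),):
            raise InvalidArgumentError("need one concentration per chromophore")
        if np.any(c < 0):
            raise InvalidArgumentError("concentrations must be non-negative")
        if wavelengths is None:
            ext = self.extinction
        else:
            w = np.asarray(wavelengths, dtype=float)
            ext = np.vstack([np.interp(w, self.grid, e) for e in self.extinction])
        return LN10 * (c @ ext)


def _gauss(grid, center, sigma):
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def synthetic_hemoglobin_basis(grid=None) -> ChromophoreBasis:
    """Synthetic oxy/deoxy hemoglobin extinction basis (see module docstring).

    Returns a two-entry basis ("oxyhemoglobin", "deoxyhemoglobin") on ``grid``
    (default 400-800 nm at 1 nm), normalized so the 450-600 nm mean of the
    oxy spectrum equals the bundled phantom series' implied extinction.
    """
    if grid is None:
        grid = np.arange(400.0, 801.0)
    grid = np.asarray(grid, dtype=float)

    oxy = (
        28.0 * _gauss(grid, 414.0, 12.0)
        + 1.00 * _gauss(grid, 542.0, 11.0)
        + 1.05 * _gauss(grid, 577.0, 9.0)
        + 0.12 * _gauss(grid, 480.0, 40.0)
        + 0.012 * np.exp(-(grid - 600.0) / 60.0) * (grid >= 600.0)
        + 0.012 * (grid < 600.0)
    )
    deoxy = (
        24.0 * _gauss(grid, 432.0, 14.0)
        + 1.35 * _gauss(grid, 556.0, 16.0)
        + 0.16 * _gauss(grid, 490.0, 45.0)
        + 0.10 * np.exp(-(grid - 600.0) / 90.0) * (grid >= 600.0)
        + 0.10 * (grid < 600.0)
    )
    window = (grid >= 450.0) & (grid <= 600.0)
    oxy *= _PHANTOM_WINDOW_EPS / oxy[window].mean()
    deoxy *= (_PHANTOM_WINDOW_EPS * 1.12) / deoxy[window].mean()
    return ChromophoreBasis(("oxyhemoglobin", "deoxyhemoglobin"), grid, np.vstack([oxy, deoxy]))


def hemoglobin_mua(hb_total: float, oxygen_fraction: float, basis: ChromophoreBasis, grid) -> Spectrum:
    """Absorption spectrum of a hemoglobin solution.

    mua(lam) = ln(10) * [eps_oxy(lam) * f * C + eps_deoxy(lam) * (1-f) * C].
    """
    if hb_total < 0:
        raise InvalidArgumentError("hemoglobin concentration must be non-negative")
    if not 0.0 <= oxygen_fraction <= 1.0:
        raise InvalidArgumentError("oxygen fraction must lie in [0, 1]")
    grid = np.asarray(grid, dtype=float)
    eps_o = basis.extinction_at("oxyhemoglobin", grid)
    eps_d = basis.extinction_at("deoxyhemoglobin", grid)
    mua = LN10 * hb_total * (oxygen_fraction * eps_o + (1.0 - oxygen_fraction) * eps_d)
    return Spectrum(grid, mua, unit="cm^-1", kind="coefficient")
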