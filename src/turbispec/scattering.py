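"""Scatterer models: Mie theory for monodisperse spheres and a power law.

The Mie series follows the standard Riccati-Bessel formulation with the
logarithmic derivative computed by downward recurrence (numerically stable for
the size parameters of micron-scale polystyrene beads in the visible).  The
reduced scattering coefficient of a sphere suspension is

    musp(lam) = N * Qsca(lam) * pi * r^2 * (1 - g(lam))

with N the number density (cm^-3), r the sphere radius (cm), Qsca the
scattering efficiency and g the asymmetry parameter (mean cosine).

For tissue, where no sphere geometry exists, scattering is parameterized as
the usual wavelength power law musp(lam) = a * (lam / lam0)^(-b).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError
from .spectra import Spectrum


@dataclass(frozen=True)
class MieSphere:
    """Monodisperse spherical scatterer suspension.

    diameter in um; refractive indices absolute; number_density in cm^-3.
    """

    diameter: float = 1.0
    sphere_index: float = 1.59
    medium_index: float = 1.33
    number_density: float = 0.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidArgumentError("sphere diameter must be positive")
        if self.sphere_index < 1 or self.medium_index < 1:
            raise InvalidArgumentError("refractive indices must be >= 1")
        if self.number_density < 0:
            raise InvalidArgumentError("number density must be non-negative")


@dataclass(frozen=True)
class PowerLaw:
    """musp(lam) = amplitude * (lam / reference_wavelength)^(-exponent)."""

    amplitude: float
    exponent: float
    reference_wavelength: float = 550.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidArgumentError("power-law amplitude must be non-negative")
        if self.reference_wavelength <= 0:
            raise InvalidArgumentError("reference wavelength must be positive")

    def musp(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        return self.amplitude * (grid / self.reference_wavelength) ** (-self.exponent)


def mie_efficiencies(size_parameter: float, relative_index: float) -> tuple[float, float, float]:
    """(Qsca, Qext, g) for a homogeneous sphere, real relative index.

    Logarithmic-derivative downward recurrence for D_n(mx); Riccati-Bessel
    psi/chi by upward recurrence in the (stable) argument x.
    """
    x = float(size_parameter)
    m = float(relative_index)
    if x <= 0:
        raise InvalidArgumentError("size parameter must be positive")
    nmax = int(np.round(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = max(nmax, int(np.ceil(abs(m * x)))) + 16

    # downward recurrence for the logarithmic derivative at mx
    d = np.zeros(nmx + 1, dtype=np.complex128)
    mx = m * x
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi0 = -np.sin(x), np.cos(x)
    a = np.empty(nmax, dtype=np.complex128)
    b = np.empty(nmax, dtype=np.complex128)
    psi_nm1, chi_nm1 = psi0, chi0
    psi_nm2, chi_nm2 = psi_m1, chi_m1
    for n in range(1, nmax + 1):
        psi_n = (2 * n - 1) / x * psi_nm1 - psi_nm2
        chi_n = (2 * n - 1) / x * chi_nm1 - chi_nm2
        xi_n = psi_n - 1j * chi_n
        xi_nm1 = psi_nm1 - 1j * chi_nm1
        da = d[n] / m + n / x
        db = d[n] * m + n / x
        a[n - 1] = (da * psi_n - psi_nm1) / (da * xi_n - xi_nm1)
        b[n - 1] = (db * psi_n - psi_nm1) / (db * xi_n - xi_nm1)
        psi_nm2, chi_nm2 = psi_nm1, chi_nm1
        psi_nm1, chi_nm1 = psi_n, chi_n

    n = np.arange(1, nmax + 1)
    two_n_plus1 = 2 * n + 1
    qsca = 2.0 / x**2 * np.sum(two_n_plus1 * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qext = 2.0 / x**2 * np.sum(two_n_plus1 * (a + b).real)
    cross = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    mixed = np.sum(two_n_plus1 / (n * (n + 1)) * (a * np.conj(b)).real)
    g = 4.0 / (x**2 * qsca) * (cross + mixed)
    return float(qsca), float(qext), float(g)


def mie_musp(scatterer: MieSphere, grid) -> dict:
    """Reduced scattering spectrum and asymmetry for a sphere suspension.

    Returns ``{"musp": Spectrum (cm^-1), "anisotropy_g": array, "qsca": array}``
    on the wavelength grid (nm).
    """
    grid = np.asarray(grid, dtype=float)
    radius_cm = scatterer.diameter / 2.0 * 1e-4
    m = scatterer.sphere_index / scatterer.medium_index
    qsca = np.empty(grid.shape)
    g = np.empty(grid.shape)
    for i, lam_nm in enumerate(grid):
        lam_um = lam_nm * 1e-3
        x = np.pi * scatterer.diameter * scatterer.medium_index / lam_um
        qsca[i], _, g[i] = mie_efficiencies(x, m)
    musp = scatterer.number_density * qsca * np.pi * radius_cm**2 * (1.0 - g)
    return {
        "musp": Spectrum(grid, musp, unit="cm^-1", kind="coefficient"),
        "anisotropy_g": g,
        "qsca": qsca,
    }


def density_for_musp(scatterer: MieSphere, target_musp: float, wavelength: float) -> MieSphere:
    """Return the scatterer with number density set so musp(wavelength) hits target.

    musp is exactly linear in number density, so this is a single division.
    """
    if target_musp < 0:
        raise InvalidArgumentError("target musp must be non-negative")
    probe = replace(scatterer, number_density=1.0)
    unit = mie_musp(probe, np.array([wavelength]))["musp"].values[0]
    return replace(scatterer, number_density=target_musp / unit)
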