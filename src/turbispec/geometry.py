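"""Fiber-probe collection geometry.

The physical probe (a bundle of illumination and detection fibers pressed
against the tissue) is abstracted as a coaxial source disk plus a detector
annulus with an NA-limited angular acceptance.  Photon exits are recorded as
radial displacements from their launch point; the probability that a given
displacement lands on the detector annulus, averaged over a uniformly
illuminated source disk and a uniformly random exit azimuth, is the analytic
convolution computed by :func:`collection_probability`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

# Default dimensions (cm) chosen so the modeled sensing depth of the probe is
# about 1.5 mm in the tissue optical-property range; see docs/methods.md.
DEFAULT_SOURCE_RADIUS = 0.1
DEFAULT_DETECTOR_INNER = 0.0
DEFAULT_DETECTOR_OUTER = 0.16
DEFAULT_NA = 0.22


@dataclass(frozen=True)
class ProbeGeometry:
    """Coaxial disk source / annulus detector with NA-limited acceptance.

    All lengths in cm.  ``numerical_aperture`` is the in-air NA of the fibers;
    a photon reaching the surface with internal polar angle theta is
    collectable when ``n_medium * sin(theta) <= NA`` (invariant under the
    refraction at the exit face).
    """

    source_radius: float = DEFAULT_SOURCE_RADIUS
    detector_inner_radius: float = DEFAULT_DETECTOR_INNER
    detector_outer_radius: float = DEFAULT_DETECTOR_OUTER
    numerical_aperture: float = DEFAULT_NA
    medium_refractive_index: float = 1.37
    external_refractive_index: float = 1.45

    def __post_init__(self):
        if self.source_radius <= 0:
            raise InvalidArgumentError("source_radius must be positive")
        if not 0 <= self.detector_inner_radius < self.detector_outer_radius:
            raise InvalidArgumentError("need 0 <= detector_inner_radius < detector_outer_radius")
        if not 0 < self.numerical_aperture <= 1:
            raise InvalidArgumentError("numerical aperture must lie in (0, 1]")
        if self.medium_refractive_index < 1 or self.external_refractive_index < 1:
            raise InvalidArgumentError("refractive indices must be >= 1")

    @property
    def acceptance_sin(self) -> float:
        """Maximum internal sin(theta) accepted by the detection fibers."""
        return min(1.0, self.numerical_aperture / self.medium_refractive_index)

    def metadata(self) -> dict:
        return {
            "source_radius": self.source_radius,
            "detector_inner_radius": self.detector_inner_radius,
            "detector_outer_radius": self.detector_outer_radius,
            "numerical_aperture": self.numerical_aperture,
            "medium_refractive_index": self.medium_refractive_index,
            "external_refractive_index": self.external_refractive_index,
        }


def phantom_geometry(**overrides) -> ProbeGeometry:
    """Probe pressed into an aqueous phantom (medium index 1.33)."""
    kw = dict(medium_refractive_index=1.33, external_refractive_index=1.45)
    kw.update(overrides)
    return ProbeGeometry(**kw)


def tissue_geometry(**overrides) -> ProbeGeometry:
    """Probe in contact with soft tissue (medium index 1.37)."""
    kw = dict(medium_refractive_index=1.37, external_refractive_index=1.45)
    kw.update(overrides)
    return ProbeGeometry(**kw)


def _angular_fraction(r0: np.ndarray, rho: np.ndarray, radius: float) -> np.ndarray:
    """P(endpoint within `radius` of axis | launch radius r0, displacement rho).

    The endpoint distance is d^2 = r0^2 + rho^2 + 2 r0 rho cos(phi) with phi
    uniform on [0, pi); the fraction of azimuths with d <= radius is
    arccos(clip((r0^2 + rho^2 - radius^2) / (2 r0 rho))) / pi.
    """
    denom = 2.0 * r0 * rho
    num = r0**2 + rho**2 - radius**2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    frac = np.arccos(np.clip(c, -1.0, 1.0)) / np.pi
    # degenerate azimuth (r0 == 0 or rho == 0): endpoint distance is r0 + rho
    degenerate = denom == 0
    frac = np.where(degenerate, (r0 + rho <= radius).astype(float), frac)
    return frac


def collection_probability(rho, geometry: ProbeGeometry, n_quad: int = 96) -> np.ndarray:
    """Probability that an exit displaced by ``rho`` lands on the annulus.

    Averages over a uniformly distributed launch point on the source disk
    (Gauss-Legendre quadrature in the launch radius) and a uniform exit
    azimuth.  Purely geometric; the NA acceptance is applied separately.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho < 0):
        raise InvalidArgumentError("displacement rho must be non-negative")
    rs = geometry.source_radius
    # nodes for integral over r0 with density 2 r0 / rs^2 on [0, rs]
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r0 = 0.5 * rs * (x + 1.0)
    wq = 0.5 * rs * w * (2.0 * r0 / rs**2)
    R0, RHO = np.meshgrid(r0, rho, indexing="ij")
    inside_outer = _angular_fraction(R0, RHO, geometry.detector_outer_radius)
    if geometry.detector_inner_radius > 0:
        inside_inner = _angular_fraction(R0, RHO, geometry.detector_inner_radius)
    else:
        inside_inner = 0.0
    frac = inside_outer - inside_inner
    return np.einsum("q,qr->r", wq, frac)
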