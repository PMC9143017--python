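"""Photon-transport Monte Carlo in a semi-infinite homogeneous turbid medium.

Two entry points share one random-walk core:

* :func:`run_baseline_mc` — the *scalable* route.  Photons random-walk in an
  absorption-free medium at a reference scattering coefficient
  (Henyey-Greenstein phase function, unpolarized Fresnel boundary).  Every
  photon exiting the top surface within the fiber NA acceptance is stored as
  an (exit radius, path length, exit angle cosine, weight) record.  Because a
  scattering-only trajectory's geometry scales exactly as 1/mu_s at fixed
  anisotropy, and absorption can be applied analytically as exp(-mua * L),
  one stored ensemble predicts reflectance at arbitrary (mua, musp) — see
  :mod:`turbispec.forward`.

* :func:`direct_reflectance` — an independent conventional estimator used as
  the validation oracle.  It samples steps from the full interaction
  coefficient mu_t = mua + mus, de-weights by the single-scattering albedo at
  every collision, applies Russian-roulette termination, and tallies the
  weight collected by the detector annulus directly.  It shares no scaling
  machinery with the baseline route.

All randomness is driven by an explicit integer seed; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .errors import InvalidArgumentError
from .geometry import ProbeGeometry, collection_probability

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
# Hard cap on scattering events per photon.  In the absorption-free baseline
# the walk-length distribution is heavy-tailed (half-space recurrence); paths
# longer than the cap would contribute exp(-mua*L) ~ 0 for tissue-range
# absorption, so truncation is negligible wherever the records are used, and
# the cap can be raised explicitly for absorption-free energy audits.
MAX_EVENTS = 20_000


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if g < 1e-6:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


@njit(cache=True, inline="always")
def _fresnel_reflectance(cos_i, n1, n2):
    """Unpolarized Fresnel reflectance for internal incidence cosine cos_i."""
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        temp = np.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / temp + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / temp + uy * cos_t
        nuz = -sin_t * cos_p * temp + uz * cos_t
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _baseline_kernel(n_photons, mus, g, n_med, n_ext, accept_sin, max_events, seed):
    """Scattering-only walks; returns NA-accepted exit records and a tally of
    (total exit weight incl. NA-rejected, truncated photon count)."""
    np.random.seed(seed)
    out_rho = np.empty(n_photons)
    out_len = np.empty(n_photons)
    out_mu = np.empty(n_photons)
    out_w = np.empty(n_photons)
    n_rec = 0
    total_exit_w = 0.0
    n_truncated = 0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        events = 0
        alive = True
        while alive:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            s = -np.log(u) / mus
            while s > 0.0 and alive:
                if uz < 0.0 and z + uz * s < 0.0:
                    s1 = -z / uz
                    x += ux * s1
                    y += uy * s1
                    z = 0.0
                    path += s1
                    s -= s1
                    cos_i = -uz
                    if np.random.random() > _fresnel_reflectance(cos_i, n_med, n_ext):
                        total_exit_w += 1.0
                        sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                        if sin_i <= accept_sin:
                            out_rho[n_rec] = np.sqrt(x * x + y * y)
                            out_len[n_rec] = path
                            out_mu[n_rec] = cos_i
                            out_w[n_rec] = 1.0
                            n_rec += 1
                        alive = False
                    else:
                        uz = -uz
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    path += s
                    s = 0.0
            if not alive:
                break
            cos_t = _hg_cos(g, np.random.random())
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, cos_t, phi)
            events += 1
            if events >= max_events:
                n_truncated += 1
                alive = False
    return out_rho[:n_rec], out_len[:n_rec], out_mu[:n_rec], out_w[:n_rec], total_exit_w, n_truncated


@njit(cache=True)
def _direct_kernel(n_photons, mua, mus, g, n_med, n_ext, accept_sin,
                   src_radius, det_inner, det_outer,
                   roulette_threshold, roulette_survival, max_events, seed):
    """Conventional albedo-weighted walk; tallies annulus-collected weight."""
    np.random.seed(seed)
    mut = mua + mus
    albedo = mus / mut
    col_w = 0.0
    col_w2 = 0.0
    n_col = 0
    for _ in range(n_photons):
        r0 = src_radius * np.sqrt(np.random.random())
        phi0 = 2.0 * np.pi * np.random.random()
        x = r0 * np.cos(phi0)
        y = r0 * np.sin(phi0)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        events = 0
        alive = True
        while alive:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            s = -np.log(u) / mut
            while s > 0.0 and alive:
                if uz < 0.0 and z + uz * s < 0.0:
                    s1 = -z / uz
                    x += ux * s1
                    y += uy * s1
                    z = 0.0
                    s -= s1
                    cos_i = -uz
                    if np.random.random() > _fresnel_reflectance(cos_i, n_med, n_ext):
                        sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                        r = np.sqrt(x * x + y * y)
                        if sin_i <= accept_sin and det_inner <= r <= det_outer:
                            col_w += w
                            col_w2 += w * w
                            n_col += 1
                        alive = False
                    else:
                        uz = -uz
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    s = 0.0
            if not alive:
                break
            w *= albedo
            if w < roulette_threshold:
                if np.random.random() < roulette_survival:
                    w /= roulette_survival
                else:
                    alive = False
                    break
            cos_t = _hg_cos(g, np.random.random())
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, cos_t, phi)
            events += 1
            if events >= max_events:
                alive = False
    return col_w, col_w2, n_col


@dataclass
class BaselineSimulation:
    """Stored photon exit records from one reference Monte Carlo run.

    ``reference_scattering`` is the (un-reduced) scattering coefficient mu_s
    of the baseline medium in cm^-1.  Records hold, per NA-accepted exiting
    photon, the radial exit displacement from its launch point (cm), the
    cumulative geometric path length (cm), the exit polar-angle cosine inside
    the medium, and the surviving weight.
    """

    reference_scattering: float
    anisotropy_g: float
    n_photons_launched: int
    exit_radius: np.ndarray
    total_path_length: np.ndarray
    exit_angle_cosine: np.ndarray
    survival_weight: np.ndarray
    geometry: ProbeGeometry
    rng_seed: int
    total_exit_weight: float = 0.0
    n_truncated: int = 0
    _collection_grid: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.exit_radius)
        if not (len(self.total_path_length) == len(self.exit_angle_cosine)
                == len(self.survival_weight) == n):
            raise InvalidArgumentError("record arrays must have equal length")
        if self.n_photons_launched < n:
            raise InvalidArgumentError("more records than launched photons")
        if n and (np.any(self.exit_radius < 0) or np.any(self.total_path_length <= 0)):
            raise InvalidArgumentError("invalid exit records")

    @property
    def reference_musp(self) -> float:
        return self.reference_scattering * (1.0 - self.anisotropy_g)

    def collection_weights(self, rho: np.ndarray) -> np.ndarray:
        """Annulus-collection probability for displacements ``rho``, via a
        cached log-spaced interpolation table of the analytic convolution."""
        if self._collection_grid is None:
            lo, hi = 1e-7, 1e4
            grid = np.geomspace(lo, hi, 4000)
            grid = np.concatenate(([0.0], grid))
            vals = collection_probability(grid, self.geometry)
            self._collection_grid = (grid, vals)
        grid, vals = self._collection_grid
        return np.interp(rho, grid, vals, left=vals[0], right=0.0)

    # --- cache I/O (runtime artifact: .npz columns + JSON sidecar) ---

    def _meta(self) -> dict:
        return {
            "reference_scattering": self.reference_scattering,
            "anisotropy_g": self.anisotropy_g,
            "n_photons_launched": self.n_photons_launched,
            "rng_seed": self.rng_seed,
            "n_records": int(len(self.exit_radius)),
            "geometry": self.geometry.metadata(),
        }

    def cache_key(self) -> str:
        return hashlib.sha256(
            json.dumps(self._meta(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            exit_radius=self.exit_radius,
            total_path_length=self.total_path_length,
            exit_angle_cosine=self.exit_angle_cosine,
            survival_weight=self.survival_weight,
            total_exit_weight=self.total_exit_weight,
            n_truncated=self.n_truncated,
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self._meta(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path, geometry: ProbeGeometry) -> "BaselineSimulation":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path)
        sim = cls(
            reference_scattering=meta["reference_scattering"],
            anisotropy_g=meta["anisotropy_g"],
            n_photons_launched=meta["n_photons_launched"],
            exit_radius=data["exit_radius"],
            total_path_length=data["total_path_length"],
            exit_angle_cosine=data["exit_angle_cosine"],
            survival_weight=data["survival_weight"],
            geometry=geometry,
            rng_seed=meta["rng_seed"],
            total_exit_weight=float(data["total_exit_weight"]),
            n_truncated=int(data["n_truncated"]),
        )
        if sim._meta() != meta:
            raise InvalidArgumentError("baseline cache does not match requested settings")
        return sim


def run_baseline_mc(
    geometry: ProbeGeometry,
    reference_scattering: float,
    anisotropy_g: float = 0.9,
    n_photons: int = 1_000_000,
    seed: int = 0,
    max_events: int = MAX_EVENTS,
) -> BaselineSimulation:
    """Run the absorption-free reference simulation and store exit records.

    Absorption is deliberately absent (mua = 0): it is applied analytically
    and variance-free at scaling time via exp(-mua * L).
    """
    if n_photons < 1:
        raise InvalidArgumentError("n_photons must be >= 1")
    if reference_scattering <= 0:
        raise InvalidArgumentError("reference_scattering must be positive")
    if not 0 <= anisotropy_g < 1:
        raise InvalidArgumentError("anisotropy g must lie in [0, 1)")
    rho, plen, mu, w, total_w, n_trunc = _baseline_kernel(
        int(n_photons),
        float(reference_scattering),
        float(anisotropy_g),
        geometry.medium_refractive_index,
        geometry.external_refractive_index,
        geometry.acceptance_sin,
        int(max_events),
        int(seed) & 0x7FFFFFFF,
    )
    return BaselineSimulation(
        reference_scattering=float(reference_scattering),
        anisotropy_g=float(anisotropy_g),
        n_photons_launched=int(n_photons),
        exit_radius=rho,
        total_path_length=plen,
        exit_angle_cosine=mu,
        survival_weight=w,
        geometry=geometry,
        rng_seed=int(seed),
        total_exit_weight=float(total_w),
        n_truncated=int(n_trunc),
    )


def direct_reflectance(
    geometry: ProbeGeometry,
    mua: float,
    musp: float,
    anisotropy_g: float = 0.9,
    n_photons: int = 100_000,
    seed: int = 0,
    max_events: int = MAX_EVENTS,
) -> tuple[float, float]:
    """Oracle estimator: (collected reflectance, Monte Carlo standard error).

    Simulates the exact target medium with interaction sampling at
    mu_t = mua + mus, albedo de-weighting and Russian roulette; no scaling.
    """
    if n_photons < 1:
        raise InvalidArgumentError("n_photons must be >= 1")
    if musp <= 0:
        raise InvalidArgumentError("musp must be positive")
    if mua < 0:
        raise InvalidArgumentError("mua must be non-negative")
    mus = musp / (1.0 - anisotropy_g)
    col_w, col_w2, _ = _direct_kernel(
        int(n_photons),
        float(mua),
        float(mus),
        float(anisotropy_g),
        geometry.medium_refractive_index,
        geometry.external_refractive_index,
        geometry.acceptance_sin,
        geometry.source_radius,
        geometry.detector_inner_radius,
        geometry.detector_outer_radius,
        ROULETTE_THRESHOLD,
        ROULETTE_SURVIVAL,
        int(max_events),
        int(seed) & 0x7FFFFFFF,
    )
    n = float(n_photons)
    mean = col_w / n
    var = max(0.0, col_w2 / n - mean * mean) / n
    return mean, float(np.sqrt(var))
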