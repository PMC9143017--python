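"""Synthetic in-vivo cohorts: uptake kinetics and endpoint tables.

Each subject carries four endpoints measured at the 60-minute post-injection
plateau: TMRE intensity (mitochondrial membrane potential surrogate, c.u.),
Bodipy FL C16 intensity (fatty-acid uptake surrogate, c.u.), hemoglobin
oxygen saturation SO2 (fraction) and total hemoglobin [Hb] (uM).  Group
means/covariances encode the study structure reported for murine mammary
tissue and tumors: older mammary groups sit ~1.5 pooled SD below younger ones
in TMRE and [Hb] with Bodipy and SO2 unchanged; 4T1 tumors differ from
mammary in Bodipy, TMRE and [Hb]; 67NR tumors overlap mammary.

Probe delivery follows saturating first-order kinetics
v(t) = plateau * (1 - exp(-k t)), sampled at the standard post-injection
schedule 2, 4, 6, 8, 10, 20, 30, 40, 50, 60 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError

ENDPOINTS = ("tmre", "bodipy", "so2", "hb")
DEFAULT_TIMEPOINTS = (2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, endpoint means and covariance."""

    label: str
    n_subjects: int
    mean: tuple  # (tmre, bodipy, so2, hb)
    covariance: np.ndarray  # 4x4, PSD
    timepoint: float = 0.0  # age in weeks or study day, for time trends

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        mean = tuple(float(m) for m in self.mean)
        if len(mean) != 4:
            raise InvalidArgumentError("mean must have one entry per endpoint (tmre, bodipy, so2, hb)")
        if not 0 <= mean[2] <= 1:
            raise InvalidArgumentError("SO2 mean must lie in [0, 1]")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (4, 4):
            raise ConfigurationError("covariance must be 4x4")
        if not np.allclose(cov, cov.T):
            raise ConfigurationError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ConfigurationError("covariance must be positive semi-definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class UptakeKinetics:
    """First-order delivery: rate constant (1/min), plateau fraction at 60 min."""

    rate_constant: float = 0.1
    plateau_fraction: float = 1.0

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise InvalidArgumentError("rate constant must be positive")
        if not 0 < self.plateau_fraction <= 1:
            raise InvalidArgumentError("plateau fraction must lie in (0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    """Groups + measurement schedule + uptake kinetics + seed."""

    groups: tuple
    timepoints: tuple = DEFAULT_TIMEPOINTS
    uptake: UptakeKinetics = field(default_factory=UptakeKinetics)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        tps = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tps):
            raise InvalidArgumentError("timepoints must be non-negative")
        object.__setattr__(self, "timepoints", tps)


def _cov(tmre_sd, bodipy_sd, so2_sd, hb_sd):
    return np.diag(np.array([tmre_sd, bodipy_sd, so2_sd, hb_sd], dtype=float) ** 2)

# pooled SDs shared by all default groups
_SD = dict(tmre_sd=0.20, bodipy_sd=0.25, so2_sd=0.08, hb_sd=6.0)


def mammary_aging_design(n_per_group: int = 20, seed: int = 0) -> CohortDesign:
    """Default aging cohort: young (7-8 wk) vs old (9-15 wk) mammary tissue.

    Old groups sit 1.5 pooled SD below young in TMRE and [Hb]; Bodipy and SO2
    are unchanged.
    """
    cov = _cov(**_SD)
    return CohortDesign(
        groups=(
            GroupSpec("mammary_young", n_per_group, (1.00, 1.00, 0.55, 30.0), cov, timepoint=7.5),
            GroupSpec("mammary_old", n_per_group, (0.70, 1.00, 0.55, 21.0), cov, timepoint=12.0),
        ),
        seed=seed,
    )


def tumor_design(line: str = "4T1", n_per_group: int = 20, seed: int = 0) -> CohortDesign:
    """Tumor-vs-mammary cohort for the 4T1 or 67NR line.

    4T1 differs from age-matched mammary in Bodipy, TMRE and [Hb]; 67NR
    overlaps mammary.
    """
    cov = _cov(**_SD)
    mammary = GroupSpec("mammary_young", n_per_group, (1.00, 1.00, 0.55, 30.0), cov, timepoint=7.5)
    if line == "4T1":
        tumor = GroupSpec("4T1", n_per_group, (1.25, 1.35, 0.55, 38.0), cov, timepoint=7.5)
    elif line == "67NR":
        tumor = GroupSpec("67NR", n_per_group, (1.00, 1.00, 0.55, 30.0), cov, timepoint=7.5)
    else:
        raise ConfigurationError(f"unknown tumor line {line!r}")
    return CohortDesign(groups=(mammary, tumor), seed=seed)


def uptake_curve(design: CohortDesign, plateau_value: float) -> pd.Series:
    """Noise-free delivery curve v(t) = plateau * (1 - exp(-k t)) at the
    design timepoints (index = minutes post-injection)."""
    k = design.uptake.rate_constant
    t = np.asarray(design.timepoints)
    return pd.Series(plateau_value * (1.0 - np.exp(-k * t)), index=t, name="intensity")


def synthesize_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw the per-subject endpoint table for a cohort design.

    Columns: subject_id, group, timepoint, tmre, bodipy, so2, hb.  SO2 is
    truncated to [0, 1] and the non-negative endpoints floored at 0; a pure
    function of (design, design.seed).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in design.groups:
        draws = rng.multivariate_normal(group.mean, group.covariance,
                                        size=group.n_subjects, method="svd")
        draws[:, 0] = np.maximum(draws[:, 0], 0.0)  # tmre
        draws[:, 1] = np.maximum(draws[:, 1], 0.0)  # bodipy
        draws[:, 2] = np.clip(draws[:, 2], 0.0, 1.0)  # so2
        draws[:, 3] = np.maximum(draws[:, 3], 0.0)  # hb
        for j, vec in enumerate(draws):
            rows.append({
                "subject_id": f"{group.label}_s{j:02d}",
                "group": group.label,
                "timepoint": group.timepoint,
                "tmre": vec[0],
                "bodipy": vec[1],
                "so2": vec[2],
                "hb": vec[3],
            })
    return pd.DataFrame(rows)


def synthesize_uptake_trial(
    arms: dict,
    n_subjects: int = 9,
    timepoints=DEFAULT_TIMEPOINTS,
    subject_sd: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject delivery curves for one or more injection arms.

    ``arms`` maps arm label -> (rate_constant, plateau).  Each subject gets a
    Gaussian random plateau offset (between-subject variance) and i.i.d.
    Gaussian residual noise per timepoint.  Long format: columns arm,
    subject, timepoint, intensity.
    """
    if any(t < 0 for t in timepoints):
        raise InvalidArgumentError("timepoints must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    rows = []
    for arm, (k, plateau) in arms.items():
        if k <= 0:
            raise InvalidArgumentError("rate constant must be positive")
        for s in range(n_subjects):
            offset = rng.normal(0.0, subject_sd)
            curve = plateau * (1.0 - np.exp(-k * t)) + offset + rng.normal(0.0, noise_sd, t.size)
            for tp, v in zip(t, curve):
                rows.append({"arm": arm, "subject": f"{arm}_s{s:02d}",
                             "timepoint": tp, "intensity": v})
    return pd.DataFrame(rows)
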