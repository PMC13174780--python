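"""Synthetic data generators for both study designs.

The longitudinal generator draws, for each subject i, timepoint j and
replicate k,

    y_ijk = clip( [ (M + b_i) + A * cos(2*pi*(t_j - phi)/24) + u_ij ] * f_ijk )

with b_i ~ N(0, between_subject_sd^2), u_ij ~ N(0, tod_extra_sd^2) and
f_ijk a mean-one lognormal factor whose coefficient of variation is
``assay_cv_pct`` percent. ``t_j`` is the clock hour of draw j. Values below a
small positive floor are clipped (events are counted in the panel metadata).

The cross-sectional generator draws ages from a two-component normal
mixture, sampling times from a per-hour probability table with uniform
minutes-within-hour jitter, couples the two marginals through a Gaussian
copula to hit a target Spearman correlation, and builds per-analyte ln
titers as baseline + age trend + planted age-band x time-of-day effects +
Gaussian noise.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_SCHEDULE,
    DEFAULT_START_HOUR,
    CohortTable,
    TiterPanel,
    hours_to_clock_string,
    round_time_to_hour,
)
from .errors import ConfigError

# ---------------------------------------------------------------------------
# longitudinal panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelAnalyteParams:
    """Cosinor-structured generative parameters for one analyte."""

    mesor: float
    amplitude: float
    acrophase_h: float
    between_subject_sd: float = 0.0
    tod_extra_sd: float = 0.0
    assay_cv_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.between_subject_sd < 0 or self.tod_extra_sd < 0 or self.assay_cv_pct < 0:
            raise ConfigError("standard deviations and CVs must be >= 0")
        if not 0.0 <= self.acrophase_h < 24.0:
            raise ConfigError("acrophase_h must lie in [0, 24)")


DEFAULT_PANEL_ANALYTES: dict[str, PanelAnalyteParams] = {
    "GADA": PanelAnalyteParams(200.0, 25.0, 10.0, 150.0, 10.0, 8.0),
    "IA": PanelAnalyteParams(60.0, 12.0, 11.0, 40.0, 5.0, 8.0),
    "IA2A": PanelAnalyteParams(120.0, 10.0, 12.0, 90.0, 6.0, 8.0),
    "ZnT8RA": PanelAnalyteParams(15.0, 3.0, 13.0, 10.0, 1.0, 8.0),
    "ZnT8WA": PanelAnalyteParams(12.0, 2.5, 13.0, 8.0, 1.0, 8.0),
}


@dataclass(frozen=True)
class PanelSimConfig:
    n_subjects: int = 10
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    n_replicates: int = 2
    start_hour: float = DEFAULT_START_HOUR
    analytes: Mapping[str, PanelAnalyteParams] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_ANALYTES)
    )
    clip_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ConfigError("n_subjects and n_replicates must be >= 1")
        if len(self.schedule) < 1:
            raise ConfigError("schedule must contain at least one draw")
        if self.clip_floor <= 0:
            raise ConfigError("clip_floor must be > 0")


def _lognormal_factors(rng: np.random.Generator, cv_pct: float, size: tuple[int, ...]) -> np.ndarray:
    """Mean-one multiplicative noise with the requested percent CV."""
    if cv_pct == 0:
        return np.ones(size)
    cv = cv_pct / 100.0
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def gen_panel(config: PanelSimConfig, rng: np.random.Generator | None = None) -> TiterPanel:
    """Generate a longitudinal duplicate-assay panel.

    Deterministic given ``config.seed`` (or an explicitly supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sched = np.asarray(config.schedule, dtype=float)
    clock = (config.start_hour + sched) % 24.0
    nsub, nt, nrep = config.n_subjects, len(sched), config.n_replicates
    omega = 2.0 * math.pi / 24.0

    frames = []
    clip_count = 0
    pids = [f"S{i + 1:02d}" for i in range(nsub)]
    for analyte in sorted(config.analytes):
        p = config.analytes[analyte]
        b = rng.normal(0.0, p.between_subject_sd, size=nsub)
        u = rng.normal(0.0, p.tod_extra_sd, size=(nsub, nt))
        f = _lognormal_factors(rng, p.assay_cv_pct, (nsub, nt, nrep))
        mean = (
            p.mesor
            + b[:, None]
            + p.amplitude * np.cos(omega * (clock[None, :] - p.acrophase_h))
            + u
        )
        y = mean[:, :, None] * f
        below = y < config.clip_floor
        clip_count += int(below.sum())
        y = np.where(below, config.clip_floor, y)
        idx = pd.MultiIndex.from_product(
            [pids, sched, range(1, nrep + 1)],
            names=["participant_id", "elapsed_h", "replicate"],
        )
        df = pd.DataFrame({"titer": y.reshape(-1)}, index=idx).reset_index()
        df["analyte"] = analyte
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    data = data.loc[:, ["participant_id", "analyte", "elapsed_h", "replicate", "titer"]]
    return TiterPanel(
        data=data,
        schedule=config.schedule,
        n_replicates=nrep,
        start_hour=config.start_hour,
        meta={"seed": config.seed, "clip_events": clip_count},
    )


# ---------------------------------------------------------------------------
# cross-sectional cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """Additive ln-titer shift applied where age_lo <= age <= age_hi and
    tod_hour <= tod_cut. ``exp(delta_ln)`` is the designed fold change."""

    age_lo: float
    age_hi: float
    tod_cut: int
    delta_ln: float


@dataclass(frozen=True)
class CohortAnalyteParams:
    baseline_ln: float
    age_slope: float = 0.0
    noise_sd: float = 1.0
    threshold: float = 1.0
    planted: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")


#: hour -> probability; median hour 11, extra mass at/before 08:00.
DEFAULT_TOD_PMF: dict[int, float] = {
    7: 0.12,
    8: 0.18,
    9: 0.08,
    10: 0.07,
    11: 0.10,
    12: 0.12,
    13: 0.10,
    14: 0.08,
    15: 0.08,
    16: 0.07,
}

DEFAULT_COHORT_ANALYTES: dict[str, CohortAnalyteParams] = {
    "IA2A": CohortAnalyteParams(
        baseline_ln=5.5,
        age_slope=-0.05,
        noise_sd=2.0,
        threshold=5.0,
        planted=(PlantedEffect(0.0, 16.0, 8, 1.25),),
    ),
    "GADA": CohortAnalyteParams(baseline_ln=4.5, age_slope=-0.02, noise_sd=2.5, threshold=20.0),
    "IA": CohortAnalyteParams(
        baseline_ln=-0.5,
        age_slope=-0.03,
        noise_sd=1.5,
        threshold=0.1,
        planted=(PlantedEffect(14.0, 19.0, 14, 0.97),),
    ),
    "ZnT8A": CohortAnalyteParams(
        baseline_ln=-2.5,
        age_slope=-0.04,
        noise_sd=2.0,
        threshold=0.05,
        planted=(PlantedEffect(0.0, 15.0, 9, 0.70),),
    ),
}


@dataclass(frozen=True)
class CohortSimConfig:
    n: int = 705
    young_frac: float = 0.5
    young_mean: float = 13.0
    young_sd: float = 5.0
    adult_mean: float = 33.0
    adult_sd: float = 10.0
    age_min: float = 3.0
    age_max: float = 76.0
    tod_pmf: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_TOD_PMF))
    age_time_rho: float = -0.12
    duration_mean: float = 6.0
    duration_sd: float = 5.0
    analytes: Mapping[str, CohortAnalyteParams] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_ANALYTES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be >= 2")
        if abs(self.age_time_rho) > 0.9:
            raise ConfigError(
                "age_time_rho beyond +/-0.9 is infeasible with hour-discretized times"
            )
        total = sum(self.tod_pmf.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigError(f"tod_pmf probabilities sum to {total}, expected 1")
        if not all(0 <= h <= 23 for h in self.tod_pmf):
            raise ConfigError("tod_pmf hours must be valid clock hours")


def _truncated_mixture_ages(config: CohortSimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample ages by rejection from the two-component mixture."""
    out = np.empty(0)
    while out.size < n:
        m = 2 * (n - out.size) + 16
        young = rng.random(m) < config.young_frac
        x = np.where(
            young,
            rng.normal(config.young_mean, config.young_sd, m),
            rng.normal(config.adult_mean, config.adult_sd, m),
        )
        x = x[(x >= config.age_min) & (x <= config.age_max)]
        out = np.concatenate([out, x])
    return out[:n]


def _sample_times(config: CohortSimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Continuous sampling times (decimal hours) that round back to the drawn hour."""
    hours = np.array(sorted(config.tod_pmf), dtype=float)
    probs = np.array([config.tod_pmf[int(h)] for h in hours])
    h = rng.choice(hours, size=n, p=probs)
    lo_hour, hi_hour = hours.min(), hours.max()
    # minute-resolution jitter within +/-29 min, so rounding returns the hour
    jitter = rng.integers(-29, 30, size=n) / 60.0
    t = np.clip(h + jitter, lo_hour, hi_hour)
    return t


def gen_cohort(config: CohortSimConfig, rng: np.random.Generator | None = None) -> CohortTable:
    """Generate a single-draw cross-sectional cohort.

    Age and sampling-time marginals are preserved exactly; their joint
    dependence is induced by rank-coupling both samples to a bivariate
    normal whose correlation is the Gaussian-copula transform of the target
    Spearman rho.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n

    ages = _truncated_mixture_ages(config, rng, n)
    times = _sample_times(config, rng, n)

    # Gaussian copula: pair sorted marginals through ranks of correlated normals
    rho_g = 2.0 * math.sin(math.pi * config.age_time_rho / 6.0)
    cov = np.array([[1.0, rho_g], [rho_g, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    age_rank = np.argsort(np.argsort(z[:, 0]))
    time_rank = np.argsort(np.argsort(z[:, 1]))
    ages = np.sort(ages)[age_rank]
    times = np.sort(times)[time_rank]

    tod_hours = np.array([round_time_to_hour(float(t)) for t in times])
    sample_times = [hours_to_clock_string(float(t)) for t in times]
    durations = np.clip(rng.normal(config.duration_mean, config.duration_sd, n), 0.0, None)

    frames = []
    for analyte in sorted(config.analytes):
        p = config.analytes[analyte]
        ln_y = p.baseline_ln + p.age_slope * ages
        for eff in p.planted:
            mask = (ages >= eff.age_lo) & (ages <= eff.age_hi) & (tod_hours <= eff.tod_cut)
            ln_y = ln_y + eff.delta_ln * mask
        ln_y = ln_y + rng.normal(0.0, p.noise_sd, n)
        titer = np.exp(ln_y)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"P{i + 1:04d}" for i in range(n)],
                    "age_years": ages,
                    "sample_time": sample_times,
                    "tod_hour": tod_hours,
                    "analyte": analyte,
                    "titer": titer,
                    "threshold": p.threshold,
                    "detected": titer > p.threshold,
                    "duration_years": durations,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data=data)


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------


def panel_config_from_dict(raw: Mapping | None, seed: int | None = None) -> PanelSimConfig:
    raw = dict(raw or {})
    if "analytes" in raw:
        raw["analytes"] = {
            name: PanelAnalyteParams(**params) for name, params in raw["analytes"].items()
        }
    if "schedule" in raw:
        raw["schedule"] = tuple(float(t) for t in raw["schedule"])
    if seed is not None:
        raw["seed"] = seed
    try:
        return PanelSimConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid panel simulation config: {exc}") from exc


def cohort_config_from_dict(raw: Mapping | None, seed: int | None = None) -> CohortSimConfig:
    raw = dict(raw or {})
    if "analytes" in raw:
        analytes = {}
        for name, params in raw["analytes"].items():
            params = dict(params)
            if "planted" in params:
                params["planted"] = tuple(
                    PlantedEffect(**eff) for eff in params["planted"]
                )
            analytes[name] = CohortAnalyteParams(**params)
        raw["analytes"] = analytes
    if "tod_pmf" in raw:
        raw["tod_pmf"] = {int(k): float(v) for k, v in raw["tod_pmf"].items()}
    if seed is not None:
        raw["seed"] = seed
    try:
        return CohortSimConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid cohort simulation config: {exc}") from exc
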