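"""Single-component, fixed 24-h-period cosinor rhythmometry.

The model is Y(t) = M + A * cos(2*pi*(t - phi)/24), fit by least squares via
the linearization Y = M + beta*cos(w t) + gamma*sin(w t), w = 2*pi/24, with

    A   = sqrt(beta^2 + gamma^2)
    phi = (atan2(gamma, beta) / w) mod 24      (clock time of the fitted peak)

Significance of the rhythm is the two-parameter F-test of beta = gamma = 0;
the acrophase confidence interval comes from the delta method on the
(beta, gamma) covariance, with a subject-cluster bootstrap as an alternative
robust to within-subject correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TiterPanel, hours_to_clock_string
from .diurnal import zscore_standardize
from .errors import DataError

PERIOD_H = 24.0
OMEGA = 2.0 * math.pi / PERIOD_H

#: RSS below this fraction of total variation counts as a perfect fit.
_PERFECT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float | None  # clock hours in [0, 24); None when amplitude == 0
    beta: float
    gamma: float
    p_zero_amplitude: float | None
    perfect_fit: bool
    n_obs: int
    n_subjects: int
    rss0: float
    rss1: float
    df_resid: int
    cov: tuple[tuple[float, ...], ...]  # 3x3 covariance of (M, beta, gamma)
    analyte: str | None = None

    @property
    def se_amplitude(self) -> float:
        if self.amplitude == 0:
            return float("nan")
        c = np.asarray(self.cov)
        g = np.array([self.beta, self.gamma]) / self.amplitude
        return float(math.sqrt(max(g @ c[1:, 1:] @ g, 0.0)))


@dataclass(frozen=True)
class AcrophaseCI:
    lower: float
    upper: float
    level: float
    wraps_midnight: bool
    unreliable: bool
    method: str


def hours_to_clock(h: float) -> str:
    """Format decimal hours in [0, 24) as ``H:MM``."""
    return hours_to_clock_string(h)


def _as_obs(observations: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations
        for col in ("time_h", "value"):
            if col not in df.columns:
                raise DataError(f"cosinor observations missing column {col!r}")
        if "participant_id" not in df.columns:
            df = df.assign(participant_id="_pooled")
        return df
    arr = np.asarray(observations, dtype=float)
    return pd.DataFrame(
        {"participant_id": "_pooled", "time_h": arr[:, 0], "value": arr[:, 1]}
    )


def fit_cosinor(
    observations: pd.DataFrame | np.ndarray, analyte: str | None = None
) -> CosinorFit:
    """Fit the 24-h cosinor to pooled observations.

    ``observations``: DataFrame with columns ``time_h``, ``value`` and
    optionally ``participant_id``, or an (n, 2) array of (time, value).
    Times may be on any reference (elapsed or clock hours); the acrophase is
    reported modulo 24 on the same reference.
    """
    df = _as_obs(observations)
    t = df["time_h"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    n = y.size
    if np.unique(np.mod(t, PERIOD_H)).size < 3:
        raise DataError("cosinor needs >= 3 distinct timepoints (mod 24 h)")
    X = np.column_stack([np.ones(n), np.cos(OMEGA * t), np.sin(OMEGA * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise DataError("rank-deficient cosinor design (degenerate timepoints)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = math.hypot(beta, gamma)
    # snap numerically-zero amplitudes (constant input) to an exact zero
    if amplitude <= 1e-12 * max(1.0, abs(mesor), float(np.abs(y).max())):
        amplitude, beta, gamma = 0.0, 0.0, 0.0
    if amplitude > 0:
        acrophase = (math.atan2(gamma, beta) / OMEGA) % PERIOD_H
        if acrophase >= PERIOD_H:  # float rounding at the wrap point
            acrophase = 0.0
    else:
        acrophase = None

    df_resid = n - 3
    scale = max(rss0, 1.0)
    perfect = rss1 <= _PERFECT_FIT_RTOL * scale
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss1 / df_resid if df_resid > 0 else 0.0
    cov = sigma2 * xtx_inv

    p: float | None
    if df_resid <= 0:
        p = None
    elif perfect:
        p = 0.0
    else:
        f = ((rss0 - rss1) / 2.0) / (rss1 / df_resid)
        p = float(stats.f.sf(f, 2, df_resid))

    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        beta=beta,
        gamma=gamma,
        p_zero_amplitude=p,
        perfect_fit=perfect,
        n_obs=n,
        n_subjects=int(df["participant_id"].nunique()),
        rss0=rss0,
        rss1=rss1,
        df_resid=df_resid,
        cov=tuple(tuple(float(v) for v in row) for row in cov),
        analyte=analyte,
    )


def zero_amplitude_test(fit: CosinorFit) -> float:
    """P-value of the F-test that the rhythm amplitude is zero."""
    if fit.df_resid <= 0:
        raise DataError("zero-amplitude test needs n > 3 observations")
    assert fit.p_zero_amplitude is not None
    return fit.p_zero_amplitude


def acrophase_ci(fit: CosinorFit, level: float = 0.95) -> AcrophaseCI:
    """Delta-method confidence interval for the acrophase, in clock hours.

    The interval may wrap midnight, in which case ``lower > upper`` and
    ``wraps_midnight`` is set. When the amplitude is within 2 standard
    errors of zero the acrophase is barely identifiable and the interval is
    flagged ``unreliable``.
    """
    if fit.acrophase is None or fit.amplitude <= 0:
        raise DataError("acrophase CI undefined for zero amplitude")
    phi = fit.acrophase
    if fit.perfect_fit:
        return AcrophaseCI(phi, phi, level, False, False, "delta")
    c = np.asarray(fit.cov)[1:, 1:]
    a2 = fit.amplitude**2
    grad = np.array([-fit.gamma / a2, fit.beta / a2]) / OMEGA
    var_phi = float(grad @ c @ grad)
    se = math.sqrt(max(var_phi, 0.0))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, fit.df_resid))
    half = min(se * tcrit, PERIOD_H / 2.0)
    unreliable = fit.amplitude < 2.0 * fit.se_amplitude or half >= PERIOD_H / 2.0
    lower = (phi - half) % PERIOD_H
    upper = (phi + half) % PERIOD_H
    return AcrophaseCI(lower, upper, level, lower > upper, unreliable, "delta")


def acrophase_ci_bootstrap(
    observations: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> AcrophaseCI:
    """Subject-cluster percentile bootstrap interval for the acrophase.

    Participants are resampled with replacement; phases are recentered on
    the point estimate modulo 24 before taking percentiles, so intervals
    straddling midnight are handled.
    """
    df = _as_obs(observations)
    fit = fit_cosinor(df)
    if fit.acrophase is None:
        raise DataError("acrophase CI undefined for zero amplitude")
    pids = df["participant_id"].unique()
    if pids.size < 2:
        raise DataError("subject bootstrap needs >= 2 participants")
    groups = {pid: sub for pid, sub in df.groupby("participant_id")}
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_boot):
        chosen = rng.choice(pids, size=pids.size, replace=True)
        sample = pd.concat([groups[pid] for pid in chosen], ignore_index=True)
        try:
            bfit = fit_cosinor(sample)
        except DataError:
            continue
        if bfit.acrophase is None:
            continue
        d = (bfit.acrophase - fit.acrophase + PERIOD_H / 2.0) % PERIOD_H - PERIOD_H / 2.0
        deltas.append(d)
    if len(deltas) < max(10, n_boot // 10):
        raise DataError("too many degenerate bootstrap refits")
    alpha = 1.0 - level
    qlo, qhi = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    lower = (fit.acrophase + qlo) % PERIOD_H
    upper = (fit.acrophase + qhi) % PERIOD_H
    unreliable = fit.amplitude < 2.0 * fit.se_amplitude
    return AcrophaseCI(lower, upper, level, lower > upper, unreliable, "bootstrap")


def panel_observations(
    panel: TiterPanel, analyte: str, zscore: bool = True
) -> pd.DataFrame:
    """Replicate-averaged (and optionally per-participant z-scored) series
    ready for :func:`fit_cosinor`, with ``time_h`` on the clock-hour reference
    (start hour + elapsed, not folded) so the acrophase is a clock time."""
    means = panel.replicate_means(analyte)
    means = means.assign(time_h=panel.start_hour + means["elapsed_h"])
    if zscore:
        parts = []
        for pid, grp in means.groupby("participant_id", sort=True):
            grp = grp.sort_values("elapsed_h").copy()
            grp["value"] = zscore_standardize(grp["titer"].to_numpy())
            parts.append(grp)
        means = pd.concat(parts, ignore_index=True)
    else:
        means = means.rename(columns={"titer": "value"})
    return means.loc[:, ["participant_id", "time_h", "value"]]


def fit_report(fit: CosinorFit, ci: AcrophaseCI | None = None) -> dict:
    """JSON-ready summary, with clock-formatted acrophase."""
    rep = {
        "analyte": fit.analyte,
        "mesor": fit.mesor,
        "amplitude": fit.amplitude,
        "acrophase_h": fit.acrophase,
        "acrophase_clock": hours_to_clock(fit.acrophase) if fit.acrophase is not None else None,
        "p_zero_amplitude": fit.p_zero_amplitude,
        "perfect_fit": fit.perfect_fit,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
    }
    if ci is not None:
        rep["acrophase_ci"] = {
            "lower_h": ci.lower,
            "upper_h": ci.upper,
            "lower_clock": hours_to_clock(ci.lower),
            "upper_clock": hours_to_clock(ci.upper),
            "level": ci.level,
            "wraps_midnight": ci.wraps_midnight,
            "unreliable": ci.unreliable,
            "method": ci.method,
        }
    return rep
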