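"""Variance-components decomposition for the balanced nested duplicate design.

Model: y_ijk = mu + b_i + u_ij + e_ijk for subject i, timepoint j, replicate
k, all effects independent. For a balanced design with t timepoints and r
replicates the expected-mean-squares (method-of-moments) estimators are

    sigma^2_assay   = MS_error
    sigma^2_tod     = (MS_time(subject) - MS_error) / r
    sigma^2_between = (MS_subject - MS_time(subject)) / (t * r)

computed on raw titers (not z-scores). Negative moment estimates are
truncated to zero and flagged. A REML alternative (via a linear mixed model)
is available for robustness comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import TiterPanel
from .errors import ConfigError, DataError


@dataclass(frozen=True)
class VarianceComponents:
    analyte: str
    var_between: float
    var_tod: float
    var_assay: float
    pct_between: float
    pct_tod: float
    pct_assay: float
    truncated: tuple[str, ...]  # components clipped from negative MoM estimates
    degenerate: bool  # all variation zero; percentages by convention
    method: str = "ems"


def _panel_cube(panel: TiterPanel, analyte: str) -> np.ndarray:
    """Return titers as an (n_subjects, t, r) array; errors if unbalanced."""
    df = panel.data[panel.data["analyte"] == analyte]
    if df.empty:
        raise DataError(f"analyte {analyte!r} not present in panel")
    subs = sorted(df["participant_id"].unique())
    times = sorted(df["elapsed_h"].unique())
    reps = sorted(df["replicate"].unique())
    cube = np.full((len(subs), len(times), len(reps)), np.nan)
    si = {s: i for i, s in enumerate(subs)}
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(reps)}
    for row in df.itertuples(index=False):
        cube[si[row.participant_id], ti[row.elapsed_h], ri[row.replicate]] = row.titer
    if np.isnan(cube).any():
        raise DataError(
            "unbalanced panel: every subject needs every timepoint and replicate; "
            "subset to a balanced design first"
        )
    return cube


def variance_components(
    panel: TiterPanel, analyte: str, method: str = "ems"
) -> VarianceComponents:
    """Decompose titer variance into between-subject, TOD and assay components."""
    if method not in ("ems", "reml"):
        raise ConfigError(f"unknown variance-components method {method!r}")
    cube = _panel_cube(panel, analyte)
    n, t, r = cube.shape
    if r < 2:
        raise DataError("assay component is inestimable with a single replicate")
    if n < 2 or t < 2:
        raise DataError("need >= 2 subjects and >= 2 timepoints")

    if method == "reml":
        vb, vt, va = _reml_components(cube)
        truncated: tuple[str, ...] = ()
    else:
        grand = cube.mean()
        sub_means = cube.mean(axis=(1, 2))
        cell_means = cube.mean(axis=2)
        ms_subject = t * r * ((sub_means - grand) ** 2).sum() / (n - 1)
        ms_time_in_sub = (
            r * ((cell_means - sub_means[:, None]) ** 2).sum() / (n * (t - 1))
        )
        ms_error = ((cube - cell_means[:, :, None]) ** 2).sum() / (n * t * (r - 1))
        va = float(ms_error)
        vt = float((ms_time_in_sub - ms_error) / r)
        vb = float((ms_subject - ms_time_in_sub) / (t * r))
        trunc = []
        if vt < 0:
            vt = 0.0
            trunc.append("tod")
        if vb < 0:
            vb = 0.0
            trunc.append("between")
        truncated = tuple(trunc)
        # clamp float-epsilon components so exact-zero cases report cleanly
        tol = 1e-12 * max(vb, vt, va, 0.0)
        vb, vt, va = (0.0 if v <= tol else v for v in (vb, vt, va))

    total = vb + vt + va
    if total == 0:
        return VarianceComponents(
            analyte, 0.0, 0.0, 0.0, 100.0, 0.0, 0.0, truncated, True, method
        )
    return VarianceComponents(
        analyte,
        vb,
        vt,
        va,
        100.0 * vb / total,
        100.0 * vt / total,
        100.0 * va / total,
        truncated,
        False,
        method,
    )


def _reml_components(cube: np.ndarray) -> tuple[float, float, float]:
    """REML fit of the two-level nested model via statsmodels MixedLM."""
    import pandas as pd
    import statsmodels.formula.api as smf

    n, t, r = cube.shape
    df = pd.DataFrame(
        {
            "y": cube.reshape(-1),
            "subject": np.repeat(np.arange(n), t * r).astype(str),
            "tp": np.tile(np.repeat(np.arange(t), r), n).astype(str),
        }
    )
    md = smf.mixedlm(
        "y ~ 1", df, groups="subject", re_formula="1", vc_formula={"tp": "0 + C(tp)"}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=True)
    vb = float(res.cov_re.iloc[0, 0])
    vt = float(res.vcomp[0])
    va = float(res.scale)
    return max(vb, 0.0), max(vt, 0.0), max(va, 0.0)
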