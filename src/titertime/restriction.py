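"""Bootstrap precision comparison: fixed-time vs random clinical-day sampling.

Each bootstrap replicate resamples subjects with replacement (the default
exchangeable unit) and forms two arms from the replicate-averaged titers at
the clinical-day draws (clock hours 9, 13 and 17 by default):

* restricted arm — every resampled subject's titer at the fixed time;
* random arm — per resampled subject, the titer at one of the clinical-day
  times drawn uniformly.

The statistic is SD_restricted / SD_random (sample SD across subjects,
ddof=1). Replicates with SD_random == 0 are discarded and counted. The
summary is the median ratio with a percentile 95% interval over retained
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import TiterPanel
from .errors import DataError

CLINICAL_TIMES: tuple[float, ...] = (9.0, 13.0, 17.0)


@dataclass(frozen=True)
class RestrictionResult:
    analyte: str
    fixed_time: float  # clock hour
    n_boot: int
    sd_ratio_median: float
    sd_ratio_ci: tuple[float, float]
    pct_sd_reduction: float
    n_discarded: int
    n_subjects: int
    seed: int
    resample_subjects: bool


def _clinical_matrix(
    panel: TiterPanel, analyte: str, clinical_times: tuple[float, ...]
) -> np.ndarray:
    """Subjects x clinical-times matrix of replicate-mean titers.

    Clock times are matched to the earliest scheduled elapsed hour with that
    clock time (the duplicated start-of-schedule draw maps to day 0).
    """
    means = panel.replicate_means(analyte)
    clock_of = {e: (panel.start_hour + e) % 24.0 for e in panel.schedule}
    elapsed_for: dict[float, float] = {}
    for e in sorted(clock_of):
        c = clock_of[e]
        if c in clinical_times and c not in elapsed_for:
            elapsed_for[c] = e
    missing = [c for c in clinical_times if c not in elapsed_for]
    if missing:
        raise DataError(f"panel schedule lacks clinical-day clock times {missing}")
    wide = means.pivot(index="participant_id", columns="elapsed_h", values="titer")
    cols = [elapsed_for[c] for c in clinical_times]
    return wide.loc[:, cols].to_numpy(dtype=float)


def bootstrap_sd_ratio(
    panel: TiterPanel,
    analyte: str,
    fixed_time: float,
    n_boot: int = 10_000,
    seed: int = 0,
    clinical_times: tuple[float, ...] = CLINICAL_TIMES,
    resample_subjects: bool = True,
) -> RestrictionResult:
    """Bootstrap the restricted/random SD ratio for one analyte and fixed time."""
    if fixed_time not in clinical_times:
        raise DataError(f"fixed_time {fixed_time} not among clinical times {clinical_times}")
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    values = _clinical_matrix(panel, analyte, clinical_times)
    n = values.shape[0]
    if n < 2:
        raise DataError("bootstrap needs >= 2 subjects")
    j_fixed = clinical_times.index(fixed_time)
    rng = np.random.default_rng(seed)

    if resample_subjects:
        idx = rng.integers(0, n, size=(n_boot, n))
    else:
        idx = np.tile(np.arange(n), (n_boot, 1))
    time_choice = rng.integers(0, len(clinical_times), size=(n_boot, n))

    restricted = values[idx, j_fixed]
    random_arm = values[idx, time_choice]
    sd_r = restricted.std(axis=1, ddof=1)
    sd_rand = random_arm.std(axis=1, ddof=1)
    keep = sd_rand > 0
    n_discarded = int((~keep).sum())
    if n_discarded > n_boot / 2:
        raise DataError(
            f"{n_discarded}/{n_boot} bootstrap replicates had zero random-arm SD; "
            "data too degenerate for a ratio summary"
        )
    ratios = sd_r[keep] / sd_rand[keep]
    median = float(np.median(ratios))
    lo, hi = (float(q) for q in np.quantile(ratios, [0.025, 0.975]))
    return RestrictionResult(
        analyte=analyte,
        fixed_time=float(fixed_time),
        n_boot=n_boot,
        sd_ratio_median=median,
        sd_ratio_ci=(lo, hi),
        pct_sd_reduction=100.0 * (1.0 - median),
        n_discarded=n_discarded,
        n_subjects=n,
        seed=seed,
        resample_subjects=resample_subjects,
    )
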