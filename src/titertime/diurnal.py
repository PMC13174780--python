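"""Per-participant descriptive diurnal statistics.

All descriptive statistics operate on the within-timepoint replicate mean
(the duplicate assays are averaged before anything else); the repeated
start-of-schedule draw (elapsed hours 0 and 24) contributes two values, one
per day.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .datamodel import AnalyteConfig, TiterPanel
from .errors import DataError


def zscore_standardize(series: Sequence[float]) -> np.ndarray:
    """Participant-specific z-scores: sample mean 0, sample SD (ddof=1) 1.

    A constant series (SD = 0) maps to all zeros.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise DataError("z-scoring needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def daily_range(series: Sequence[float]) -> float:
    """Daily maximum minus daily minimum."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DataError("daily_range of an empty series")
    return float(x.max() - x.min())


def diurnal_cv(series: Sequence[float]) -> float:
    """Percent coefficient of variation over the day: 100 * SD(ddof=1) / mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise DataError("diurnal_cv needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise DataError(f"diurnal_cv undefined for nonpositive mean {mean}")
    return float(100.0 * x.std(ddof=1) / mean)


def cv_fold_vs_interassay(diurnal_cv_pct: float, interassay_cv_pct: float) -> float:
    """How many fold the diurnal CV exceeds the laboratory inter-assay CV."""
    if interassay_cv_pct <= 0:
        raise DataError("inter-assay CV must be > 0")
    if diurnal_cv_pct < 0:
        raise DataError("diurnal CV must be >= 0")
    return diurnal_cv_pct / interassay_cv_pct


def detection_changed(series: Sequence[float], threshold: float) -> bool:
    """True iff detection status (strict titer > threshold) differs across the day."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DataError("detection_changed of an empty series")
    detected = x > threshold
    return bool(detected.any() and not detected.all())


@dataclass(frozen=True)
class SubjectDaySummary:
    participant_id: str
    analyte: str
    daily_range: float
    diurnal_cv_pct: float
    cv_fold_vs_interassay: float
    detection_changed: bool


def summarize_panel(
    panel: TiterPanel, configs: Mapping[str, AnalyteConfig]
) -> list[SubjectDaySummary]:
    """One :class:`SubjectDaySummary` per participant x analyte.

    Only analytes present in ``configs`` are summarized (the inter-assay CV
    and detection threshold come from there).
    """
    means = panel.replicate_means()
    out: list[SubjectDaySummary] = []
    for (pid, analyte), grp in means.groupby(["participant_id", "analyte"], sort=True):
        if analyte not in configs:
            continue
        cfg = configs[analyte]
        series = grp.sort_values("elapsed_h")["titer"].to_numpy()
        cv = diurnal_cv(series)
        out.append(
            SubjectDaySummary(
                participant_id=str(pid),
                analyte=str(analyte),
                daily_range=daily_range(series),
                diurnal_cv_pct=cv,
                cv_fold_vs_interassay=cv_fold_vs_interassay(cv, cfg.interassay_cv_pct),
                detection_changed=detection_changed(series, cfg.detection_threshold),
            )
        )
    return out
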