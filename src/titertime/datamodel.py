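"""Core data structures and table input/output.

Two tables drive every analysis:

* :class:`TiterPanel` — the longitudinal study: duplicate-assay titers per
  participant x analyte x timepoint, sampled on a fixed schedule of elapsed
  hours (default: 7 draws at 4-h spacing starting 09:00, so elapsed hours
  0, 4, ..., 24; the first and last draw are both 09:00, one day apart).
* :class:`CohortTable` — the cross-sectional study: one record per
  participant per analyte, with age, a clock sampling time, the sampling
  time rounded to the nearest hour, the titer, the detection threshold and
  the detection flag (strict ``titer > threshold``).

Both tables round-trip losslessly through plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, IntegrityError, SchemaError

DEFAULT_SCHEDULE: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
DEFAULT_START_HOUR = 9.0
PANEL_COLUMNS = ("participant_id", "analyte", "elapsed_h", "replicate", "titer")
COHORT_COLUMNS = (
    "participant_id",
    "age_years",
    "sample_time",
    "tod_hour",
    "analyte",
    "titer",
    "threshold",
    "detected",
)

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})\s*$")


def parse_clock(sample_time: str) -> float:
    """Parse an ``hh:mm`` clock string to decimal hours in [0, 24)."""
    m = _CLOCK_RE.match(str(sample_time))
    if not m:
        raise DataError(f"invalid clock time {sample_time!r}: expected hh:mm")
    hh, mm = int(m.group(1)), int(m.group(2))
    if not (0 <= hh <= 23 and 0 <= mm <= 59):
        raise DataError(f"clock time {sample_time!r} outside 00:00-23:59")
    return hh + mm / 60.0


def round_time_to_hour(sample_time: str | float) -> int:
    """Round a clock time to the nearest integer hour (half-up: :30 rounds up).

    Accepts an ``hh:mm`` string or decimal hours. 23:30 and later wrap to 0.
    """
    h = parse_clock(sample_time) if isinstance(sample_time, str) else float(sample_time)
    if not 0.0 <= h < 24.0:
        raise DataError(f"decimal hour {h} outside [0, 24)")
    return int(np.floor(h + 0.5)) % 24


def hours_to_clock_string(h: float) -> str:
    """Format decimal hours as ``H:MM`` (e.g. 9.8 -> ``9:48``)."""
    if not 0.0 <= h < 24.0:
        raise DataError(f"hour {h} outside [0, 24)")
    minutes = int(round((h - int(h)) * 60.0))
    hh = int(h)
    if minutes == 60:
        hh, minutes = (hh + 1) % 24, 0
    return f"{hh}:{minutes:02d}"


# ---------------------------------------------------------------------------
# analyte configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteConfig:
    """Per-analyte assay constants supplied as configuration, never computed."""

    analyte: str
    detection_threshold: float
    interassay_cv_pct: float
    intraassay_cv_pct: float | None = None

    def __post_init__(self) -> None:
        if self.detection_threshold <= 0:
            raise ConfigError(f"{self.analyte}: detection_threshold must be > 0")
        if self.interassay_cv_pct <= 0:
            raise ConfigError(f"{self.analyte}: interassay_cv_pct must be > 0")
        if self.intraassay_cv_pct is not None and self.intraassay_cv_pct <= 0:
            raise ConfigError(f"{self.analyte}: intraassay_cv_pct must be > 0")


def load_analyte_configs(path: str | Path) -> dict[str, AnalyteConfig]:
    """Load a YAML mapping ``analyte -> {detection_threshold, interassay_cv_pct, ...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping of analyte -> config")
    out: dict[str, AnalyteConfig] = {}
    for name, cfg in raw.items():
        out[name] = AnalyteConfig(analyte=name, **cfg)
    return out


# ---------------------------------------------------------------------------
# longitudinal panel
# ---------------------------------------------------------------------------


@dataclass
class TiterPanel:
    """Long-format longitudinal titer table with a fixed sampling schedule.

    ``data`` columns: participant_id, analyte, elapsed_h, replicate, titer.
    ``elapsed_h`` is hours since the first draw; clock time of a draw is
    ``(start_hour + elapsed_h) % 24``.
    """

    data: pd.DataFrame
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    n_replicates: int = 2
    start_hour: float = DEFAULT_START_HOUR
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.schedule = tuple(float(t) for t in self.schedule)
        self.validate()

    # -- queries ------------------------------------------------------------

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant_id"].unique())

    def clock_hours(self) -> pd.Series:
        return (self.start_hour + self.data["elapsed_h"]) % 24.0

    def replicate_means(self, analyte: str | None = None) -> pd.DataFrame:
        """Average replicates within (participant, analyte, timepoint)."""
        df = self.data if analyte is None else self.data[self.data["analyte"] == analyte]
        if analyte is not None and df.empty:
            raise DataError(f"analyte {analyte!r} not present in panel")
        out = (
            df.groupby(["participant_id", "analyte", "elapsed_h"], as_index=False)["titer"]
            .mean()
            .sort_values(["participant_id", "analyte", "elapsed_h"], kind="mergesort")
            .reset_index(drop=True)
        )
        return out

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        for col in PANEL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"panel is missing required column {col!r}")
        if df["titer"].isna().any():
            raise IntegrityError("panel contains missing titers")
        if (df["titer"] < 0).any():
            bad = df.loc[df["titer"] < 0].iloc[0]
            raise DataError(
                f"negative titer for participant {bad['participant_id']!r}, "
                f"analyte {bad['analyte']!r}"
            )
        key = ["participant_id", "analyte", "elapsed_h", "replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            bad = df.loc[dup, key].iloc[0].to_dict()
            raise IntegrityError(f"duplicate record for key {bad}")
        expected_reps = set(range(1, self.n_replicates + 1))
        counts = df.groupby(["participant_id", "analyte", "elapsed_h"])["replicate"]
        for keyval, reps in counts:
            if set(reps) != expected_reps:
                raise IntegrityError(
                    f"(participant, analyte, time)={keyval} has replicates "
                    f"{sorted(set(reps))}, expected {sorted(expected_reps)}"
                )
        sched = set(self.schedule)
        times = df.groupby(["participant_id", "analyte"])["elapsed_h"]
        for keyval, ts in times:
            if set(ts) != sched:
                raise IntegrityError(
                    f"(participant, analyte)={keyval} has timepoints "
                    f"{sorted(set(ts))}, expected schedule {sorted(sched)}"
                )


def read_panel(
    path: str | Path,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    n_replicates: int = 2,
    start_hour: float = DEFAULT_START_HOUR,
) -> TiterPanel:
    """Read and validate a long-format panel CSV.

    Accepts either an ``elapsed_h`` column or the pair ``time_h`` (clock
    hours) + ``day`` (0-based day index), from which elapsed hours are
    reconstructed relative to ``start_hour``.
    """
    df = pd.read_csv(path)
    if "elapsed_h" not in df.columns:
        if {"time_h", "day"}.issubset(df.columns):
            df["elapsed_h"] = df["day"] * 24.0 + df["time_h"] - start_hour
            df = df.drop(columns=["time_h", "day"])
        else:
            raise SchemaError(
                "panel is missing required column 'elapsed_h' (or 'time_h' + 'day')"
            )
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"panel is missing required column {col!r}")
    df = df.loc[:, list(PANEL_COLUMNS)].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["analyte"] = df["analyte"].astype(str)
    df["elapsed_h"] = df["elapsed_h"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["titer"] = df["titer"].astype(float)
    return TiterPanel(
        data=df,
        schedule=tuple(schedule),
        n_replicates=n_replicates,
        start_hour=start_hour,
    )


def write_panel(panel: TiterPanel, path: str | Path) -> None:
    """Write a panel as CSV (comma, header, '.' decimal, UTF-8)."""
    df = panel.data.loc[:, list(PANEL_COLUMNS)]
    df = df.sort_values(
        ["participant_id", "analyte", "elapsed_h", "replicate"], kind="mergesort"
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-sectional cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """One record per participant per analyte, with TOD hour and detection flag.

    ``exclusions`` records rows dropped before the ln transform (nonpositive
    titers), each as a dict with participant_id, analyte and titer.
    """

    data: pd.DataFrame
    exclusions: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def for_analyte(self, analyte: str) -> pd.DataFrame:
        df = self.data[self.data["analyte"] == analyte]
        if df.empty:
            raise DataError(f"analyte {analyte!r} not present in cohort")
        return df.reset_index(drop=True)

    def validate(self) -> None:
        df = self.data
        for col in COHORT_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cohort is missing required column {col!r}")
        if (df["age_years"] < 0).any():
            raise DataError("negative age in cohort")
        if (df["titer"] <= 0).any():
            raise DataError("nonpositive titer in cohort (should have been excluded)")
        dup = df.duplicated(subset=["participant_id", "analyte"])
        if dup.any():
            bad = df.loc[dup, ["participant_id", "analyte"]].iloc[0].to_dict()
            raise IntegrityError(f"more than one record per participant/analyte: {bad}")
        for _, row in df.iterrows():
            if row["tod_hour"] != round_time_to_hour(row["sample_time"]):
                raise IntegrityError(
                    f"tod_hour {row['tod_hour']} inconsistent with "
                    f"sample_time {row['sample_time']!r}"
                )
            if bool(row["detected"]) != (row["titer"] > row["threshold"]):
                raise IntegrityError(
                    f"detected flag inconsistent with titer/threshold for "
                    f"{row['participant_id']!r}/{row['analyte']!r}"
                )


def _cohort_from_long(
    df: pd.DataFrame, thresholds: Mapping[str, float] | None
) -> tuple[pd.DataFrame, list[dict[str, Any]]]:
    records = []
    exclusions: list[dict[str, Any]] = []
    has_duration = "duration_years" in df.columns
    for _, row in df.iterrows():
        titer = float(row["titer"])
        analyte = str(row["analyte"])
        if "threshold" in df.columns and not pd.isna(row.get("threshold", np.nan)):
            threshold = float(row["threshold"])
        elif thresholds is not None and analyte in thresholds:
            threshold = float(thresholds[analyte])
        else:
            raise ConfigError(f"no detection threshold available for analyte {analyte!r}")
        if titer <= 0:
            exclusions.append(
                {"participant_id": str(row["participant_id"]), "analyte": analyte, "titer": titer}
            )
            continue
        t = parse_clock(row["sample_time"])
        rec = {
            "participant_id": str(row["participant_id"]),
            "age_years": float(row["age_years"]),
            "sample_time": hours_to_clock_string(t),
            "tod_hour": round_time_to_hour(t),
            "analyte": analyte,
            "titer": titer,
            "threshold": threshold,
            "detected": titer > threshold,
        }
        if has_duration:
            rec["duration_years"] = float(row["duration_years"])
        records.append(rec)
    return pd.DataFrame(records), exclusions


def read_cohort(
    path: str | Path, thresholds: Mapping[str, float] | None = None
) -> CohortTable:
    """Read and validate a cohort CSV.

    Long format (columns participant_id, age[_years], sample_time, analyte,
    titer[, threshold, duration_years]) is detected by the presence of an
    ``analyte`` column; otherwise the file is treated as wide, with one titer
    column per analyte named in ``thresholds``. Nonpositive titers are
    excluded (logged in ``exclusions``), since downstream analyses use ln
    titers.
    """
    df = pd.read_csv(path)
    if "age" in df.columns and "age_years" not in df.columns:
        df = df.rename(columns={"age": "age_years"})
    for col in ("participant_id", "age_years", "sample_time"):
        if col not in df.columns:
            raise SchemaError(f"cohort is missing required column {col!r}")
    if "analyte" in df.columns:
        if "titer" not in df.columns:
            raise SchemaError("long-format cohort is missing required column 'titer'")
        long_df = df
    else:
        if thresholds is None:
            raise ConfigError("wide-format cohort requires a thresholds mapping")
        value_cols = [c for c in thresholds if c in df.columns]
        if not value_cols:
            raise SchemaError(
                f"no per-analyte titer column found; expected one of {sorted(thresholds)}"
            )
        id_cols = [c for c in df.columns if c not in value_cols]
        long_df = df.melt(
            id_vars=id_cols, value_vars=value_cols, var_name="analyte", value_name="titer"
        )
    data, exclusions = _cohort_from_long(long_df, thresholds)
    return CohortTable(data=data, exclusions=exclusions)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as long-format CSV."""
    cols = list(COHORT_COLUMNS)
    if "duration_years" in cohort.data.columns:
        cols.append("duration_years")
    df = cohort.data.loc[:, cols].sort_values(
        ["analyte", "participant_id"], kind="mergesort"
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON result serialization
# ---------------------------------------------------------------------------


class _ResultEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:  # noqa: D102
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> None:
    """Serialize a result object (dataclasses allowed) to pretty JSON."""
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_ResultEncoder, indent=2, sort_keys=True)
        fh.write("\n")
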