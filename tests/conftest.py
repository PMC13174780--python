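import numpy as np
import pandas as pd
import pytest

from titertime.datamodel import CohortTable, TiterPanel
from titertime.simulate import (
    CohortAnalyteParams,
    CohortSimConfig,
    PanelAnalyteParams,
    PanelSimConfig,
    PlantedEffect,
    gen_cohort,
    gen_panel,
)


def make_panel(values, schedule=(0.0, 4.0, 8.0), n_replicates=1, analyte="X", start_hour=9.0):
    """Panel from an (n_subjects, n_times[, n_reps]) array of titers."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    nsub, nt, nrep = arr.shape
    assert nt == len(schedule)
    rows = []
    for i in range(nsub):
        for j, t in enumerate(schedule):
            for k in range(nrep):
                rows.append(
                    {
                        "participant_id": f"S{i + 1:02d}",
                        "analyte": analyte,
                        "elapsed_h": float(t),
                        "replicate": k + 1,
                        "titer": arr[i, j, k],
                    }
                )
    return TiterPanel(
        data=pd.DataFrame(rows),
        schedule=tuple(schedule),
        n_replicates=nrep,
        start_hour=start_hour,
    )


def make_cohort(ages, tod_hours, titers, threshold=1.0, analyte="A", durations=None):
    """Cohort from parallel arrays; sample_time set to tod_hour:00."""
    n = len(ages)
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "age_years": np.asarray(ages, dtype=float),
            "sample_time": [f"{int(h)}:00" for h in tod_hours],
            "tod_hour": np.asarray(tod_hours, dtype=int),
            "analyte": analyte,
            "titer": np.asarray(titers, dtype=float),
            "threshold": float(threshold),
        }
    )
    df["detected"] = df["titer"] > df["threshold"]
    if durations is not None:
        df["duration_years"] = np.asarray(durations, dtype=float)
    return CohortTable(data=df)


@pytest.fixture
def small_panel():
    cfg = PanelSimConfig(
        n_subjects=6,
        analytes={"GADA": PanelAnalyteParams(100.0, 20.0, 12.0, 30.0, 5.0, 8.0)},
        seed=123,
    )
    return gen_panel(cfg)


@pytest.fixture
def default_cohort():
    return gen_cohort(CohortSimConfig(seed=7))


__all__ = [
    "make_panel",
    "make_cohort",
    "CohortAnalyteParams",
    "CohortSimConfig",
    "PanelAnalyteParams",
    "PanelSimConfig",
    "PlantedEffect",
]
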