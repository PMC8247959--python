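"""CSV and JSON I/O for profiles, series, time courses and fit reports.

CSV dialects (UTF-8, comma-separated, one header row):

- pH-rate profile: ``pH,k_obs_per_s,se_per_s``
- concentration series: ``cat_conc_M,k_obs_per_s,se_per_s``
- time course: ``time_s,frac_4,frac_5,frac_6,frac_cAMP,frac_AMP,frac_Ado``

Ground-truth parameters used by the synthetic generator travel in a
sidecar JSON next to the data so recovery can be scored later.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from rnacleave.fitting import ConcSeries, PHProfile
from rnacleave.kinetic_network import TimeCourse

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "read_series_csv",
    "write_series_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "write_json",
    "read_json",
]

PROFILE_COLUMNS = ["pH", "k_obs_per_s", "se_per_s"]
SERIES_COLUMNS = ["cat_conc_M", "k_obs_per_s", "se_per_s"]
TIMECOURSE_COLUMNS = [
    "time_s", "frac_4", "frac_5", "frac_6", "frac_cAMP", "frac_AMP", "frac_Ado"
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns: list[str], path: PathLike) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def write_profile_csv(profile: PHProfile, path: PathLike) -> None:
    pd.DataFrame({
        "pH": profile.pH,
        "k_obs_per_s": profile.k_obs,
        "se_per_s": profile.se,
    }).to_csv(path, index=False)


def read_profile_csv(path: PathLike, cat_conc: float = 0.0) -> PHProfile:
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    return PHProfile(
        pH=df["pH"].to_numpy(),
        k_obs=df["k_obs_per_s"].to_numpy(),
        se=df["se_per_s"].to_numpy(),
        cat_conc=cat_conc,
        meta={"source": str(path)},
    )


def write_series_csv(series: ConcSeries, path: PathLike) -> None:
    pd.DataFrame({
        "cat_conc_M": series.cat_conc,
        "k_obs_per_s": series.k_obs,
        "se_per_s": series.se,
    }).to_csv(path, index=False)


def read_series_csv(path: PathLike, pH: float = 7.0) -> ConcSeries:
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, path)
    return ConcSeries(
        cat_conc=df["cat_conc_M"].to_numpy(),
        k_obs=df["k_obs_per_s"].to_numpy(),
        se=df["se_per_s"].to_numpy(),
        pH=pH,
        meta={"source": str(path)},
    )


def write_timecourse_csv(tc: TimeCourse, path: PathLike) -> None:
    data = {"time_s": tc.times}
    for name, col in zip(TIMECOURSE_COLUMNS[1:], tc.fractions.T):
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_timecourse_csv(path: PathLike, noisy: bool = True) -> TimeCourse:
    df = pd.read_csv(path)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    return TimeCourse(
        times=df["time_s"].to_numpy(),
        fractions=np.column_stack(
            [df[c].to_numpy() for c in TIMECOURSE_COLUMNS[1:]]
        ),
        noisy=noisy,
        meta={"source": str(path)},
    )


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
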