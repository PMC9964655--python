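"""Plain-text serialization: recordings, envelopes, gesture series, results.

All artifacts are CSV (with a mandatory header row) or JSON so that trial
records can be archived, inspected and re-analyzed without the simulator:

* raw recordings       ``t_sec, emg_ed_mv, emg_fds_mv``  (200 Hz)
* normalized envelopes ``t_sec, nemg_ed, nemg_fds``      (20 Hz)
* gesture series       ``t_sec, gesture``                (20 Hz, codes -1/0/+1)
* cohort scores        ``subject, test, order, d_l2``    (long format, ANOVA input)

Target and recognized gesture series use the identical dialect, so the
evaluation stage is agnostic to where a series came from.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gesture import GESTURE_CODES, GestureSeries
from .signal import NormalizedEMG
from .synthetic import RawRecording

_FLOAT_FMT = "%.6f"


def write_recording_csv(recording: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_sec": recording.times,
            "emg_ed_mv": recording.channels["ED"],
            "emg_fds_mv": recording.channels["FDS"],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording_csv(
    path: str | Path, kind: str = "trial", sampling_rate: float = 200.0
) -> RawRecording:
    df = pd.read_csv(path)
    required = {"t_sec", "emg_ed_mv", "emg_fds_mv"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: recording CSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    n = len(df)
    return RawRecording(
        channels={
            "ED": df["emg_ed_mv"].to_numpy(float),
            "FDS": df["emg_fds_mv"].to_numpy(float),
        },
        sampling_rate=sampling_rate,
        duration=n / sampling_rate,
        kind=kind,  # type: ignore[arg-type]
    )


def write_normalized_csv(nemg: NormalizedEMG, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_sec": nemg.times,
            "nemg_ed": nemg.channels["ED"],
            "nemg_fds": nemg.channels["FDS"],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_normalized_csv(path: str | Path, sampling_rate: float = 20.0) -> NormalizedEMG:
    df = pd.read_csv(path)
    required = {"t_sec", "nemg_ed", "nemg_fds"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: normalized-EMG CSV must have columns {sorted(required)}"
        )
    return NormalizedEMG(
        {"ED": df["nemg_ed"].to_numpy(float), "FDS": df["nemg_fds"].to_numpy(float)},
        sampling_rate=sampling_rate,
    )


def write_gesture_csv(series: GestureSeries, path: str | Path) -> None:
    df = pd.DataFrame({"t_sec": series.times, "gesture": series.values.astype(int)})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gesture_csv(path: str | Path, role: str = "recognized") -> GestureSeries:
    df = pd.read_csv(path)
    required = {"t_sec", "gesture"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: gesture CSV must have columns {sorted(required)}")
    values = df["gesture"].to_numpy()
    bad = ~np.isin(values, GESTURE_CODES)
    if bad.any():
        rows = np.nonzero(bad)[0][:10] + 2  # 1-based, after the header line
        raise ValueError(
            f"{path}: invalid gesture codes at CSV line(s) {rows.tolist()} "
            f"(values {np.unique(values[bad]).tolist()}); codes must be -1, 0 or 1"
        )
    return GestureSeries(values, role=role)  # type: ignore[arg-type]


def write_results_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject", "test", "order", "d_l2"]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "test", "order", "d_l2"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: results CSV must have columns {sorted(required)}")
    return df


def write_trial_json(
    path: str | Path, subject: int, test: str, order: int, t_d: float, d_l2: float
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "subject": int(subject),
                "test": test,
                "order": int(order),
                "t_d_seconds": float(t_d),
                "d_l2": float(d_l2),
            },
            indent=2,
        )
    )
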