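"""Calibration: MVC values and muscular-deactivation thresholds.

The 24 s calibration trace (8 s rest, 8 s maximal flexion, 8 s maximal
extension) yields, per channel,

* MVC — the maximum of the rectified envelope (rEMG) over the whole
  calibration, the unit for all subsequent normalization; and
* a deactivation threshold — the minimum of the normalized envelope (nEMG)
  during the relaxation phase plus a constant 0.1: epsilon for the extensor
  (ED), mu for the flexor (FDS).

Because rest-phase minima are non-negative the thresholds never fall below
0.1.  A noisy rest phase can push a threshold to 1 or above; that is
reported as a calibration-quality warning, not an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal import NormalizedEMG, RectifiedEMG, normalize

THRESHOLD_OFFSET = 0.1
REST_PHASE_S = (0.0, 8.0)  # relaxation comes first in the calibration
PHASE_BOUNDS_S = ((0.0, 8.0), (8.0, 16.0), (16.0, 24.0))


@dataclass
class CalibrationParams:
    """MVC amplitudes (mV) and deactivation thresholds (MVC units)."""

    mvc_ed: float
    mvc_fds: float
    epsilon: float
    mu: float
    phase_bounds: tuple = PHASE_BOUNDS_S

    def __post_init__(self) -> None:
        if not (self.mvc_ed > 0 and self.mvc_fds > 0):
            raise ValueError("MVC values must be positive")
        if self.epsilon < THRESHOLD_OFFSET or self.mu < THRESHOLD_OFFSET:
            raise ValueError(f"thresholds cannot fall below {THRESHOLD_OFFSET}")
        if self.epsilon >= 1 or self.mu >= 1:
            warnings.warn(
                "calibration quality: a deactivation threshold is >= 1 MVC; "
                "the rest phase was probably not at rest",
                stacklevel=2,
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mvc_ed": self.mvc_ed,
                    "mvc_fds": self.mvc_fds,
                    "epsilon": self.epsilon,
                    "mu": self.mu,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationParams":
        d = json.loads(Path(path).read_text())
        return cls(d["mvc_ed"], d["mvc_fds"], d["epsilon"], d["mu"])


def compute_mvc(calib_rectified: RectifiedEMG) -> tuple[float, float]:
    """Per-channel maximum of rEMG over the whole calibration trace."""
    out = []
    for name in ("ED", "FDS"):
        arr = np.asarray(calib_rectified.channels[name], dtype=float)
        if arr.size == 0:
            raise ValueError(f"channel {name}: empty calibration envelope")
        m = float(arr.max())
        if m <= 0:
            raise ValueError(
                f"calibration failure: channel {name} is flat (max rEMG = {m})"
            )
        out.append(m)
    return out[0], out[1]


def compute_thresholds(
    calib_normalized: NormalizedEMG,
    rest_phase: tuple[float, float] = REST_PHASE_S,
) -> tuple[float, float]:
    """Rest-phase nEMG minimum plus 0.1, per channel (epsilon for ED, mu for FDS)."""
    t0, t1 = rest_phase
    if t1 <= t0:
        raise ValueError("rest phase interval is empty")
    times = calib_normalized.times
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError("rest phase contains no samples")
    eps = float(np.asarray(calib_normalized.channels["ED"])[mask].min()) + THRESHOLD_OFFSET
    mu = float(np.asarray(calib_normalized.channels["FDS"])[mask].min()) + THRESHOLD_OFFSET
    return eps, mu


def calibrate(calib_rectified: RectifiedEMG) -> CalibrationParams:
    """MVCs from the full trace, thresholds from the rest phase of the same trace."""
    mvc_ed, mvc_fds = compute_mvc(calib_rectified)
    interim = CalibrationParams(mvc_ed, mvc_fds, epsilon=0.5, mu=0.5)
    nemg = normalize(calib_rectified, interim)
    eps, mu = compute_thresholds(nemg)
    return CalibrationParams(mvc_ed, mvc_fds, epsilon=eps, mu=mu)
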