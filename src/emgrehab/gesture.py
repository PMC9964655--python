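"""Three-state threshold gesture classifier.

A hand gesture is recognized from the two normalized EMG channels
(extensor digitorum, ED, and flexor digitorum superficialis, FDS) by a
Boolean threshold rule.  With

* ``A`` true when ``nEMG_ED > epsilon`` (extensor active),
* ``B`` true when ``nEMG_FDS > mu`` (flexor active),
* ``C`` true when ``nEMG_ED > nEMG_FDS`` (extensor dominant),

the three mutually exclusive outputs are::

    REST  = !A & !B
    OPEN  = A & (!B | C)
    CLOSE = B & (!A | !C)

Gestures are coded Open = -1, Rest = 0, Close = +1, so that the distance
between Open and Close is twice the distance between either and Rest.
All comparisons are strict: a sample exactly at a threshold counts as
inactive, and an exact tie between the two channels (both active) makes
``C`` false and yields CLOSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import CalibrationParams
    from .signal import NormalizedEMG

OPEN: int = -1
REST: int = 0
CLOSE: int = 1

GESTURE_CODES = (OPEN, REST, CLOSE)

GESTURE_RATE_HZ = 20.0
SAMPLING_PERIOD_S = 1.0 / GESTURE_RATE_HZ  # T_s = 0.05 s


@dataclass
class GestureSeries:
    """Discrete-event gesture series at 20 Hz, coded -1 / 0 / +1.

    ``role`` records whether the series is the instructed target or the
    recognizer's output; both use the identical coding so downstream
    scoring is source-agnostic.
    """

    values: np.ndarray
    sampling_rate: float = GESTURE_RATE_HZ
    role: Literal["target", "recognized"] = "recognized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("gesture series must be one-dimensional")
        bad = ~np.isin(self.values, GESTURE_CODES)
        if bad.any():
            raise ValueError(
                f"gesture codes must be in {GESTURE_CODES}; "
                f"found {np.unique(self.values[bad])}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based origin."""
        return np.arange(len(self.values)) / self.sampling_rate


def classify_sample(
    nemg_ed: float, nemg_fds: float, epsilon: float, mu: float
) -> int:
    """Classify a single pair of normalized EMG samples.

    Parameters
    ----------
    nemg_ed, nemg_fds
        Normalized (MVC-unit) EMG amplitudes, finite and >= 0.
    epsilon, mu
        Deactivation thresholds for the ED and FDS channels (> 0).

    Returns
    -------
    int
        One of ``OPEN`` (-1), ``REST`` (0), ``CLOSE`` (+1).
    """
    if not (np.isfinite(nemg_ed) and np.isfinite(nemg_fds)):
        raise ValueError("nEMG inputs must be finite (no NaN/inf)")
    if not (epsilon > 0 and mu > 0):
        raise ValueError("thresholds must be positive")
    a = nemg_ed > epsilon
    b = nemg_fds > mu
    c = nemg_ed > nemg_fds
    if not a and not b:
        return REST
    if a and (not b or c):
        return OPEN
    return CLOSE


def classify_series(nemg: "NormalizedEMG", params: "CalibrationParams") -> GestureSeries:
    """Apply the threshold rule sample-wise to a normalized recording.

    No smoothing, hysteresis or debouncing is applied; the output has one
    gesture per input sample.
    """
    ed = np.asarray(nemg.channels["ED"], dtype=float)
    fds = np.asarray(nemg.channels["FDS"], dtype=float)
    if ed.shape != fds.shape:
        raise ValueError(
            f"channel length mismatch: ED has {ed.shape}, FDS has {fds.shape}"
        )
    if np.isnan(ed).any() or np.isnan(fds).any():
        raise ValueError("nEMG contains NaN")
    eps, mu = params.epsilon, params.mu
    if not (eps > 0 and mu > 0):
        raise ValueError("thresholds must be positive")

    a = ed > eps
    b = fds > mu
    c = ed > fds
    out = np.zeros(ed.shape, dtype=np.int8)
    out[a & (~b | c)] = OPEN
    out[b & (~a | ~c)] = CLOSE
    return GestureSeries(out, sampling_rate=nemg.sampling_rate, role="recognized")
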