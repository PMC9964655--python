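"""sEMG conditioning chain: notch, high-pass, RMS envelope, normalization.

The raw 200 Hz recording is conditioned exactly as the embedded controller
does it, causally (forward-only filtering — zero-phase filtering would
misrepresent the real-time latency):

1. 50 Hz IIR notch (Q = 30) to remove mains interference;
2. 2nd-order Butterworth high-pass at 10 Hz to remove drift and motion
   artifact;
3. trailing root-mean-square over a 50 ms window (10 samples at 200 Hz);
4. 2nd-order Butterworth low-pass at 2 Hz;
5. decimation by 10, keeping every 10th sample, giving the 20 Hz rectified
   envelope (rEMG);
6. division by the per-channel maximal-voluntary-contraction value, giving
   the normalized envelope (nEMG) in MVC units.

nEMG is not clipped at 1: trial contractions can exceed the calibration
maximum, and the recognition thresholds are defined near the resting floor,
so clipping would only destroy information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

from .synthetic import RAW_RATE_HZ, RawRecording

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import CalibrationParams

NOTCH_HZ = 50.0
NOTCH_Q = 30.0
HIGHPASS_HZ = 10.0
RMS_WINDOW_MS = 50.0
LOWPASS_HZ = 2.0
DECIMATION = 10
PROCESSED_RATE_HZ = RAW_RATE_HZ / DECIMATION  # 20 Hz


@dataclass
class RectifiedEMG:
    """Two-channel RMS envelope (rEMG) at 20 Hz, in mV, all samples >= 0."""

    channels: dict[str, np.ndarray]
    sampling_rate: float = PROCESSED_RATE_HZ

    @property
    def times(self) -> np.ndarray:
        n = len(next(iter(self.channels.values())))
        return np.arange(n) / self.sampling_rate


@dataclass
class NormalizedEMG:
    """Two-channel MVC-normalized envelope (nEMG) at 20 Hz; >= 0, unclipped."""

    channels: dict[str, np.ndarray]
    sampling_rate: float = PROCESSED_RATE_HZ

    @property
    def times(self) -> np.ndarray:
        n = len(next(iter(self.channels.values())))
        return np.arange(n) / self.sampling_rate


def _check_channel(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        raise ValueError(f"channel {name} is empty")
    if np.isnan(arr).any():
        raise ValueError(f"channel {name} contains NaN")
    return arr


def filter_raw(recording: RawRecording) -> dict[str, np.ndarray]:
    """Causal 50 Hz notch then 10 Hz high-pass, per channel, length preserved."""
    fs = recording.sampling_rate
    if fs != RAW_RATE_HZ:
        raise ValueError(f"expected a {RAW_RATE_HZ:g} Hz recording, got {fs:g} Hz")
    b_notch, a_notch = sps.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs)
    sos_hp = sps.butter(2, HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")
    out: dict[str, np.ndarray] = {}
    for name, arr in recording.channels.items():
        arr = _check_channel(name, arr)
        if len(arr) < fs:  # need at least ~1 s for filter warm-up
            raise ValueError(f"channel {name}: need >= 1 s of data, got {len(arr)/fs:g} s")
        y = sps.lfilter(b_notch, a_notch, arr)
        out[name] = sps.sosfilt(sos_hp, y)
    return out


def rectify_rms(
    filtered: dict[str, np.ndarray],
    window_ms: float = RMS_WINDOW_MS,
    lowpass_hz: float = LOWPASS_HZ,
    decim: int = DECIMATION,
    sampling_rate: float = RAW_RATE_HZ,
) -> RectifiedEMG:
    """Trailing RMS, 2 Hz low-pass, then keep every ``decim``-th sample.

    The 50 ms window is 10 samples at 200 Hz.  Edge handling: the first
    samples use a shortened (causal) window.  The low-pass already limits
    the bandwidth well below the 10 Hz post-decimation Nyquist, so plain
    sample-keeping is used for the rate reduction.
    """
    win = int(round(window_ms * 1e-3 * sampling_rate))
    if win < 1:
        raise ValueError(f"RMS window of {window_ms} ms is shorter than one sample")
    sos_lp = sps.butter(2, lowpass_hz, btype="lowpass", fs=sampling_rate, output="sos")
    out: dict[str, np.ndarray] = {}
    for name, arr in filtered.items():
        arr = _check_channel(name, arr)
        # trailing mean of x^2 with shortened windows at the start
        csum = np.cumsum(arr**2)
        ms = np.empty_like(csum)
        k = min(win, len(arr))
        ms[:k] = csum[:k] / np.arange(1, k + 1)
        if len(arr) > win:
            ms[win:] = (csum[win:] - csum[:-win]) / win
        rms = np.sqrt(np.maximum(ms, 0.0))
        # start the low-pass at steady state for the first RMS value so the
        # warm-up transient does not masquerade as a near-zero resting level
        zi = sps.sosfilt_zi(sos_lp) * rms[0]
        smoothed, _ = sps.sosfilt(sos_lp, rms, zi=zi)
        # a causal low-pass of a non-negative signal can undershoot slightly
        out[name] = np.maximum(smoothed[::decim], 0.0)
    return RectifiedEMG(out, sampling_rate=sampling_rate / decim)


def normalize(rectified: RectifiedEMG, params: "CalibrationParams") -> NormalizedEMG:
    """nEMG = rEMG / MVC per channel, in MVC units; no clipping."""
    mvc = {"ED": params.mvc_ed, "FDS": params.mvc_fds}
    for name, value in mvc.items():
        if not value > 0:
            raise ValueError(
                f"calibration failure: MVC_{name} = {value}; must be positive"
            )
    return NormalizedEMG(
        {name: arr / mvc[name] for name, arr in rectified.channels.items()},
        sampling_rate=rectified.sampling_rate,
    )


def process_recording(recording: RawRecording, params: "CalibrationParams") -> NormalizedEMG:
    """Full chain: filter -> RMS envelope -> normalize."""
    return normalize(rectify_rms(filter_raw(recording), sampling_rate=recording.sampling_rate), params)
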