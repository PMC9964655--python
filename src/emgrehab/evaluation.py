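"""Performance scoring: cross-correlation synchronization and L2 distance.

The recognized gesture series lags the instructed target by the user's
response time plus the device's processing chain.  The lag is estimated
once per test as the non-negative lag maximizing the raw (un-normalized)
cross-correlation

    r_xy(h) = sum_n x(n + h) * y(n),    0 <= h <= N - 1,

between target (x) and recognized (y); the maximizing lag times the
sampling period T_s = 0.05 s is the delay time T_d.  The recognized series
is shifted back by that lag and the target is truncated at the end to the
common length, so the aligned pair spans about (60 - T_d) seconds.

Performance is then the squared Euclidean distance between the aligned
coded series scaled by the sampling period,

    d_L2 = sum_i (x*_i - x_i)^2 * T_s,

in gesture^2 * s.  With the coding Open = -1 / Rest = 0 / Close = +1 a
confusion between open and close costs four times a confusion of either
with rest, which is the intended asymmetry: opposite-direction errors are
the serious ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gesture import SAMPLING_PERIOD_S, GestureSeries

DEFAULT_MAX_LAG_S = 2.0


@dataclass
class SyncResult:
    """Alignment of a recognized series to its target."""

    delay_samples: int
    delay_seconds: float
    aligned_target: GestureSeries
    aligned_recognized: GestureSeries


@dataclass
class PerformanceScore:
    """L2 score for one aligned trial (lower is better)."""

    d_l2: float
    n_samples: int
    t_s: float = SAMPLING_PERIOD_S


def cross_correlate(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw cross-correlation r_xy(h) for non-negative lags h = 0..N-1.

    Out-of-range samples are implicit zeros (the sum simply has fewer
    terms at large lags).  Real inputs, so conjugation is the identity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cannot correlate empty series")
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    # np.correlate(x, y, 'full')[k] = sum_n x[n + k - (N-1)] y[n]
    return np.correlate(x, y, mode="full")[n - 1 :]


def synchronize(
    target: GestureSeries,
    recognized: GestureSeries,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
) -> SyncResult:
    """Align recognized to target at the best non-negative lag.

    The search is restricted to lags in [0, max_lag_s]: recognition
    physically lags the instruction, and delays beyond ~2 s would exceed
    plausible reaction plus processing time.  Ties are broken toward the
    smallest lag.  If the correlation is flat over the whole window (e.g.
    an all-rest trial) the delay falls back to 0 with a warning.
    """
    if target.sampling_rate != recognized.sampling_rate:
        raise ValueError("target and recognized series must share a sampling rate")
    if len(target) != len(recognized):
        raise ValueError("target and recognized series must have equal length")
    fs = target.sampling_rate
    max_lag = int(round(max_lag_s * fs))
    # r_xy(h) = sum x(n+h) y(n): with x = recognized (the delayed series) and
    # y = target, the maximizing non-negative lag is the recognition delay.
    r = cross_correlate(recognized.values, target.values)[: max_lag + 1]
    if np.ptp(r) == 0:
        warnings.warn(
            "flat cross-correlation (constant series?); using delay 0",
            stacklevel=2,
        )
        h = 0
    else:
        h = int(np.argmax(r))  # argmax returns the first (smallest) maximizer
    n = len(target)
    aligned_rec = GestureSeries(
        recognized.values[h:], sampling_rate=fs, role="recognized"
    )
    aligned_tgt = GestureSeries(
        target.values[: n - h], sampling_rate=fs, role="target"
    )
    return SyncResult(
        delay_samples=h,
        delay_seconds=h / fs,
        aligned_target=aligned_tgt,
        aligned_recognized=aligned_rec,
    )


def l2_distance(sync: SyncResult) -> PerformanceScore:
    """d_L2 = sum of squared coded differences times the sampling period."""
    x = np.asarray(sync.aligned_target.values, dtype=float)
    y = np.asarray(sync.aligned_recognized.values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("aligned series length mismatch")
    t_s = 1.0 / sync.aligned_target.sampling_rate
    d = float(np.sum((y - x) ** 2) * t_s)
    return PerformanceScore(d_l2=d, n_samples=len(x), t_s=t_s)


def score_trial(
    target: GestureSeries,
    recognized: GestureSeries,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
) -> tuple[SyncResult, PerformanceScore]:
    """Synchronize then score; the per-trial evaluation in one call."""
    sync = synchronize(target, recognized, max_lag_s)
    return sync, l2_distance(sync)
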