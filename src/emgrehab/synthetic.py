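"""Seeded synthetic sEMG cohorts for bilateral hand-rehabilitation trials.

Emulates what the experimental protocol records: two-channel forearm
surface EMG (extensor digitorum, ED, and flexor digitorum superficialis,
FDS) sampled at 200 Hz, for

* a 24 s calibration trace (8 s rest, 8 s maximal flexion, 8 s maximal
  extension), and
* 60 s trials in which a subject follows a random target sequence of
  20 gestures (open / rest / close), each held for 3 s, under one of four
  feedback conditions A-D.

The signal model is deliberately minimal but exercises every stage of the
conditioning chain: a zero-mean Gaussian carrier band-passed to 20-90 Hz
is amplitude-modulated by trapezoidal activation envelopes (100 ms causal
rise/fall), then 50 Hz mains interference and slow baseline drift are
added.  Subject behavior (response delays, occasional control errors) is
generated once per trial by a behavioral event model shared between the
raw-EMG renderer and a fast gesture-series renderer, so cohort-scale
Monte-Carlo runs and full-chain runs simulate the same subjects.

All randomness flows through an explicitly passed ``numpy.random.Generator``
(or an integer seed); there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .gesture import CLOSE, GESTURE_RATE_HZ, OPEN, REST, GestureSeries

# ---------------------------------------------------------------------------
# Signal-model constants
# ---------------------------------------------------------------------------

RAW_RATE_HZ = 200.0            # acquisition rate
CARRIER_BAND_HZ = (20.0, 90.0)  # sEMG power band (within the 100 Hz Nyquist)
ENVELOPE_RAMP_S = 0.100        # trapezoidal rise/fall of activation bursts
MAINS_HZ = 50.0
MAINS_FRACTION = 0.10          # 50 Hz interference amplitude, fraction of MVC
DRIFT_HZ = 0.5
DRIFT_FRACTION = 0.05          # baseline drift amplitude, fraction of MVC

CALIBRATION_DURATION_S = 24.0
CALIBRATION_PHASE_S = 8.0      # rest, max flexion, max extension

GESTURE_DURATION_S = 3.0
N_GESTURES = 20
TEST_DURATION_S = GESTURE_DURATION_S * N_GESTURES

#: device latency emulated by the fast path: muscle-activity onset to
#: recognized-gesture update (motion-selection time plus signal chain).
RECOGNITION_LATENCY_S = 0.45

_WEAK_FRACTION = 0.07          # sub-threshold activation level (below the 0.1 floor)
_CONTRACTION_RANGE = (0.70, 1.00)   # per-gesture voluntary effort, fraction of MVC
_ERROR_EPISODE_S = (0.3, 0.7)  # duration of an error before self-correction
_FLICKER_PERIOD_SAMPLES = 2    # co-contraction instability at 20 Hz

ERROR_KINDS = ("wrong_muscle", "cocontraction", "weak_activation")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SubjectProfile:
    """Per-subject physiology and behavior parameters.

    ``mvc_*`` are the true maximal-contraction amplitudes in mV; ``rest_level_*``
    are tonic baseline activations as fractions of MVC and must stay strictly
    below 0.1, the floor of the deactivation thresholds, so a resting subject
    is always classifiable as REST.  ``skill`` in [0, 1] scales the baseline
    control-error rate (1 = never errs beyond the condition's floor).
    """

    subject_id: int
    mvc_ed: float = 1.2
    mvc_fds: float = 1.2
    rest_level_ed: float = 0.05
    rest_level_fds: float = 0.05
    response_delay_mean: float = 0.4
    response_delay_sd: float = 0.1
    skill: float = 0.5

    def __post_init__(self) -> None:
        if self.mvc_ed <= 0 or self.mvc_fds <= 0:
            raise ValueError("MVC amplitudes must be positive")
        for lvl in (self.rest_level_ed, self.rest_level_fds):
            if not 0 <= lvl < 0.1:
                raise ValueError(
                    "rest levels must lie in [0, 0.1), below the threshold floor"
                )
        if self.response_delay_mean <= 0 or self.response_delay_sd < 0:
            raise ValueError("response delay mean must be > 0 and sd >= 0")
        if self.response_delay_mean + RECOGNITION_LATENCY_S >= GESTURE_DURATION_S:
            raise ValueError(
                "response delay plus device latency must stay below the 3 s "
                "gesture duration"
            )
        if not 0 <= self.skill <= 1:
            raise ValueError("skill must lie in [0, 1]")


@dataclass
class ConditionEffect:
    """Behavioral effect of one feedback condition.

    ``error_prob`` is the per-gesture probability of an incorrect or unstable
    activation for a median-skill subject; ``extra_delay`` is added to the
    subject's response-delay mean.  The default condition set orders expected
    error as C < D < A = B: EMG-based visual feedback alone (C) yields the
    best control, kinesthetic feedback (A, B) the worst.
    """

    condition: str
    error_prob: float = 0.05
    extra_delay: float = 0.0
    error_kinds: tuple[str, ...] = ERROR_KINDS

    def __post_init__(self) -> None:
        if not 0 <= self.error_prob <= 1:
            raise ValueError("error_prob must lie in [0, 1]")
        if self.extra_delay < 0:
            raise ValueError("extra_delay must be >= 0")
        bad = set(self.error_kinds) - set(ERROR_KINDS)
        if bad or not self.error_kinds:
            raise ValueError(f"error_kinds must be a non-empty subset of {ERROR_KINDS}")


def default_conditions() -> dict[str, ConditionEffect]:
    """The four feedback conditions with default effect sizes (C < D < A = B)."""
    return {
        "A": ConditionEffect("A", error_prob=0.08),
        "B": ConditionEffect("B", error_prob=0.08),
        "C": ConditionEffect("C", error_prob=0.03),
        "D": ConditionEffect("D", error_prob=0.055),
    }


@dataclass
class TargetSequence:
    """Instructed gesture sequence for one test: 20 gestures x 3 s = 60 s."""

    gestures: np.ndarray
    gesture_duration: float = GESTURE_DURATION_S

    def __post_init__(self) -> None:
        self.gestures = np.asarray(self.gestures, dtype=np.int8)
        if self.gestures.ndim != 1 or len(self.gestures) < 1:
            raise ValueError("gestures must be a non-empty 1-D sequence")
        if not np.isin(self.gestures, (OPEN, REST, CLOSE)).all():
            raise ValueError("gesture codes must be -1, 0 or +1")
        if self.gesture_duration <= 0:
            raise ValueError("gesture_duration must be positive")

    @property
    def test_duration(self) -> float:
        return len(self.gestures) * self.gesture_duration

    def as_series(self, sampling_rate: float = GESTURE_RATE_HZ) -> GestureSeries:
        """Expand to a sample-wise target series (role='target')."""
        per = int(round(self.gesture_duration * sampling_rate))
        return GestureSeries(
            np.repeat(self.gestures, per), sampling_rate=sampling_rate, role="target"
        )


@dataclass
class RawRecording:
    """Two-channel raw sEMG at 200 Hz."""

    channels: dict[str, np.ndarray]
    sampling_rate: float = RAW_RATE_HZ
    duration: float = 0.0
    kind: Literal["calibration", "trial"] = "trial"

    def __post_init__(self) -> None:
        if set(self.channels) != {"ED", "FDS"}:
            raise ValueError("channels must be exactly {'ED', 'FDS'}")
        n = int(round(self.duration * self.sampling_rate))
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            self.channels[name] = arr
            if len(arr) != n:
                raise ValueError(
                    f"channel {name}: expected {n} samples for "
                    f"{self.duration} s at {self.sampling_rate} Hz, got {len(arr)}"
                )

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate))
        return np.arange(n) / self.sampling_rate


# ---------------------------------------------------------------------------
# Target sequences
# ---------------------------------------------------------------------------


def generate_target_sequence(
    rng_seed: int | np.random.Generator,
    n_gestures: int = N_GESTURES,
    gesture_duration: float = GESTURE_DURATION_S,
) -> TargetSequence:
    """Draw a uniformly random i.i.d. gesture sequence.

    Each gesture is drawn uniformly from {open, rest, close}; with the
    defaults the sequence spans 20 x 3 s = 60 s.
    """
    if n_gestures < 1:
        raise ValueError("n_gestures must be >= 1")
    if gesture_duration <= 0:
        raise ValueError("gesture_duration must be positive")
    rng = _as_rng(rng_seed)
    gestures = rng.choice(np.array([OPEN, REST, CLOSE], dtype=np.int8), size=n_gestures)
    return TargetSequence(gestures, gesture_duration)


# ---------------------------------------------------------------------------
# Behavioral event model (shared by the raw and fast renderers)
# ---------------------------------------------------------------------------


@dataclass
class _Event:
    """A span of produced muscle activity starting at ``t0``."""

    t0: float
    kind: str          # "normal" | one of ERROR_KINDS
    gesture: int       # the target gesture the span belongs to
    amplitude: float   # voluntary effort, fraction of MVC


def _truncnorm_delay(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Response delay: normal truncated to [0.05, 1.5] s by redrawing."""
    if sd == 0:
        return float(np.clip(mean, 0.05, 1.5))
    for _ in range(100):
        d = rng.normal(mean, sd)
        if 0.05 <= d <= 1.5:
            return float(d)
    return float(np.clip(mean, 0.05, 1.5))


def behavior_events(
    target: TargetSequence,
    profile: SubjectProfile,
    effect: ConditionEffect,
    rng: np.random.Generator,
) -> list[_Event]:
    """Simulate one trial's produced-activity timeline as a list of events.

    The subject reacts to each instructed gesture after a truncated-normal
    response delay (mean shifted by the condition's ``extra_delay``).  With
    per-gesture probability ``error_prob`` scaled by the subject's skill, an
    error episode (wrong muscle, co-contraction, or sub-threshold activation,
    chosen uniformly) precedes self-correction.
    """
    err_p = float(np.clip(2.0 * (1.0 - profile.skill) * effect.error_prob, 0.0, 1.0))
    delay_mean = profile.response_delay_mean + effect.extra_delay
    events: list[_Event] = [_Event(0.0, "normal", REST, 0.0)]
    prev_state = REST
    dur = target.gesture_duration
    for k, g in enumerate(np.asarray(target.gestures, dtype=int)):
        t_nom = k * dur
        delay = _truncnorm_delay(rng, delay_mean, profile.response_delay_sd)
        amp = rng.uniform(*_CONTRACTION_RANGE)
        is_err = rng.random() < err_p
        if is_err:
            kind = effect.error_kinds[rng.integers(len(effect.error_kinds))]
            episode = rng.uniform(*_ERROR_EPISODE_S)
            t_err = t_nom + delay
            events.append(_Event(t_err, kind, int(g), amp))
            events.append(_Event(t_err + episode, "normal", int(g), amp))
            prev_state = int(g)
        else:
            if int(g) != prev_state:
                events.append(_Event(t_nom + delay, "normal", int(g), amp))
                prev_state = int(g)
    return events


# ---------------------------------------------------------------------------
# Fast renderer: recognized gesture series at 20 Hz
# ---------------------------------------------------------------------------


def _event_states(
    events: list[_Event],
    n_samples: int,
    fs: float,
    latency_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produced gesture state per sample, as the classifier would see it.

    Event onsets map to sample indices with an epsilon-guarded ceiling so
    that a transition landing exactly on a sample instant claims that
    sample, immune to float rounding of the time grid.
    """
    out = np.zeros(n_samples, dtype=np.int8)
    starts = [
        min(max(int(np.ceil((ev.t0 + latency_s) * fs - 1e-9)), 0), n_samples)
        for ev in events
    ]
    starts.append(n_samples)
    for i, ev in enumerate(events):
        lo, hi = starts[i], starts[i + 1]
        if hi <= lo:
            continue
        if ev.kind == "normal":
            out[lo:hi] = ev.gesture
        elif ev.kind == "wrong_muscle":
            out[lo:hi] = -ev.gesture
        elif ev.kind == "weak_activation":
            out[lo:hi] = REST
        elif ev.kind == "cocontraction":
            # unstable dominance: alternate open/close while both muscles fire
            start = -ev.gesture if ev.gesture != REST else (OPEN, CLOSE)[rng.integers(2)]
            blocks = (np.arange(hi - lo) // _FLICKER_PERIOD_SAMPLES) % 2
            out[lo:hi] = np.where(blocks == 0, start, -start)
    return out


def simulate_recognized_series(
    profile: SubjectProfile,
    target: TargetSequence,
    effect: ConditionEffect,
    rng_seed: int | np.random.Generator,
    latency_s: float = RECOGNITION_LATENCY_S,
) -> GestureSeries:
    """Behavioral fast path: the recognized gesture series the device would log.

    Skips raw-EMG synthesis and the conditioning chain: the produced-activity
    timeline is mapped directly to recognized gestures, shifted by the fixed
    device latency.  Suitable for cohort-scale Monte-Carlo; the raw path
    (:func:`generate_trial_recording` plus the conditioning chain) realizes
    the same behavioral events through the full signal model.
    """
    rng = _as_rng(rng_seed)
    events = behavior_events(target, profile, effect, rng)
    n = int(round(target.test_duration * GESTURE_RATE_HZ))
    values = _event_states(events, n, GESTURE_RATE_HZ, latency_s, rng)
    return GestureSeries(values, sampling_rate=GESTURE_RATE_HZ, role="recognized")


# ---------------------------------------------------------------------------
# Raw-EMG renderer
# ---------------------------------------------------------------------------


def _bandlimited_carrier(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the sEMG carrier band."""
    lo, hi = CARRIER_BAND_HZ
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=RAW_RATE_HZ, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _activation_levels(
    events: list[_Event],
    times: np.ndarray,
    profile: SubjectProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle activation levels (fraction of MVC) over time."""
    ed = np.full(len(times), profile.rest_level_ed)
    fds = np.full(len(times), profile.rest_level_fds)
    bounds = [ev.t0 for ev in events] + [np.inf]
    for i, ev in enumerate(events):
        m = (times >= bounds[i]) & (times < bounds[i + 1])
        if not m.any():
            continue
        g, a = ev.gesture, ev.amplitude
        if ev.kind == "normal":
            if g == OPEN:
                ed[m] = np.maximum(ed[m], a)
            elif g == CLOSE:
                fds[m] = np.maximum(fds[m], a)
        elif ev.kind == "wrong_muscle":
            if g == OPEN:
                fds[m] = np.maximum(fds[m], a)
            elif g == CLOSE:
                ed[m] = np.maximum(ed[m], a)
        elif ev.kind == "weak_activation":
            if g == OPEN:
                ed[m] = np.maximum(ed[m], _WEAK_FRACTION)
            elif g == CLOSE:
                fds[m] = np.maximum(fds[m], _WEAK_FRACTION)
        elif ev.kind == "cocontraction":
            ed[m] = np.maximum(ed[m], a)
            fds[m] = np.maximum(fds[m], a)
    return ed, fds


def _render_channel(
    level: np.ndarray,
    mvc: float,
    rng: np.random.Generator,
    interference_fraction: float,
    drift_fraction: float,
) -> np.ndarray:
    """Envelope-modulated carrier plus mains interference and drift, in mV."""
    ramp_n = max(int(round(ENVELOPE_RAMP_S * RAW_RATE_HZ)), 1)
    # causal moving average -> trapezoidal 100 ms rise/fall, onset at the event
    envelope = sps.lfilter(np.ones(ramp_n) / ramp_n, [1.0], level)
    carrier = _bandlimited_carrier(len(level), rng)
    t = np.arange(len(level)) / RAW_RATE_HZ
    out = mvc * envelope * carrier
    if interference_fraction > 0:
        out = out + interference_fraction * mvc * np.sin(
            2 * np.pi * MAINS_HZ * t + rng.uniform(0, 2 * np.pi)
        )
    if drift_fraction > 0:
        out = out + drift_fraction * mvc * np.sin(
            2 * np.pi * DRIFT_HZ * t + rng.uniform(0, 2 * np.pi)
        )
    return out


def generate_calibration_recording(
    profile: SubjectProfile,
    rng_seed: int | np.random.Generator,
    interference_fraction: float = MAINS_FRACTION,
    drift_fraction: float = DRIFT_FRACTION,
) -> RawRecording:
    """24 s calibration: 8 s rest, 8 s maximal flexion (FDS), 8 s maximal
    extension (ED), as the calibration procedure instructs."""
    rng = _as_rng(rng_seed)
    n = int(round(CALIBRATION_DURATION_S * RAW_RATE_HZ))
    times = np.arange(n) / RAW_RATE_HZ
    ed = np.full(n, profile.rest_level_ed)
    fds = np.full(n, profile.rest_level_fds)
    flex = (times >= CALIBRATION_PHASE_S) & (times < 2 * CALIBRATION_PHASE_S)
    ext = times >= 2 * CALIBRATION_PHASE_S
    fds[flex] = 1.0
    ed[ext] = 1.0
    return RawRecording(
        channels={
            "ED": _render_channel(ed, profile.mvc_ed, rng, interference_fraction, drift_fraction),
            "FDS": _render_channel(fds, profile.mvc_fds, rng, interference_fraction, drift_fraction),
        },
        sampling_rate=RAW_RATE_HZ,
        duration=CALIBRATION_DURATION_S,
        kind="calibration",
    )


def generate_trial_recording(
    profile: SubjectProfile,
    target: TargetSequence,
    effect: ConditionEffect,
    rng_seed: int | np.random.Generator,
    duration: float | None = None,
    interference_fraction: float = MAINS_FRACTION,
    drift_fraction: float = DRIFT_FRACTION,
) -> RawRecording:
    """Raw two-channel sEMG for one trial driven by the behavioral model."""
    if duration is None:
        duration = target.test_duration
    elif abs(duration - target.test_duration) > 1e-9:
        raise ValueError(
            f"target spans {target.test_duration} s but recording duration "
            f"is {duration} s"
        )
    rng = _as_rng(rng_seed)
    events = behavior_events(target, profile, effect, rng)
    n = int(round(duration * RAW_RATE_HZ))
    times = np.arange(n) / RAW_RATE_HZ
    ed_level, fds_level = _activation_levels(events, times, profile)
    return RawRecording(
        channels={
            "ED": _render_channel(ed_level, profile.mvc_ed, rng, interference_fraction, drift_fraction),
            "FDS": _render_channel(fds_level, profile.mvc_fds, rng, interference_fraction, drift_fraction),
        },
        sampling_rate=RAW_RATE_HZ,
        duration=duration,
        kind="trial",
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_subject_profile(
    subject_id: int, rng_seed: int | np.random.Generator
) -> SubjectProfile:
    """Draw a plausible subject: MVCs, rest tone, reaction time, skill."""
    rng = _as_rng(rng_seed)
    return SubjectProfile(
        subject_id=subject_id,
        mvc_ed=rng.uniform(0.8, 1.6),
        mvc_fds=rng.uniform(0.8, 1.6),
        rest_level_ed=rng.uniform(0.02, 0.07),
        rest_level_fds=rng.uniform(0.02, 0.07),
        response_delay_mean=float(np.clip(rng.normal(0.4, 0.05), 0.25, 0.6)),
        response_delay_sd=rng.uniform(0.07, 0.15),
        skill=rng.uniform(0.25, 0.75),
    )
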