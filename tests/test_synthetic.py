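"""Synthetic cohort generator: sequences, recordings, behavior model."""

import numpy as np
import pytest
from scipy import signal as sps

from emgrehab import (
    ConditionEffect,
    SubjectProfile,
    calibrate,
    classify_series,
    filter_raw,
    generate_calibration_recording,
    generate_target_sequence,
    generate_trial_recording,
    process_recording,
    rectify_rms,
    score_trial,
    simulate_recognized_series,
)
from emgrehab.synthetic import RECOGNITION_LATENCY_S


def test_target_sequence_shape_and_duration():
    seq = generate_target_sequence(123)
    assert len(seq.gestures) == 20
    assert seq.gesture_duration == 3.0
    assert seq.test_duration == 60.0
    series = seq.as_series()
    assert len(series) == 1200 and series.role == "target"


def test_target_sequence_seeded_determinism():
    a = generate_target_sequence(99)
    b = generate_target_sequence(99)
    np.testing.assert_array_equal(a.gestures, b.gestures)


def test_target_sequence_is_uniform():
    """Empirical state frequencies within 3 binomial SE of 1/3 at n = 10000."""
    seq = generate_target_sequence(7, n_gestures=10_000)
    se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
    for code in (-1, 0, 1):
        freq = np.mean(seq.gestures == code)
        assert abs(freq - 1 / 3) < 3 * se


def test_target_sequence_rejects_bad_args():
    with pytest.raises(ValueError, match="n_gestures"):
        generate_target_sequence(1, n_gestures=0)
    with pytest.raises(ValueError, match="duration"):
        generate_target_sequence(1, gesture_duration=-1.0)


def test_calibration_recording_length_and_phases(profile):
    rec = generate_calibration_recording(profile, 3)
    assert rec.kind == "calibration"
    assert len(rec.channels["ED"]) == 24 * 200 == 4800
    assert len(rec.channels["FDS"]) == 4800


def test_calibration_rest_phase_exactly_zero_without_noise(quiet_profile):
    """Zero rest tone, interference and drift: the rest phase is silent."""
    rec = generate_calibration_recording(
        quiet_profile, 3, interference_fraction=0.0, drift_fraction=0.0
    )
    rest = rec.times < 8.0
    assert np.all(rec.channels["ED"][rest] == 0.0)
    assert np.all(rec.channels["FDS"][rest] == 0.0)


def test_recordings_are_bit_identical_under_same_seed(profile):
    target = generate_target_sequence(5)
    eff = ConditionEffect("A", error_prob=0.1)
    r1 = generate_trial_recording(profile, target, eff, 77)
    r2 = generate_trial_recording(profile, target, eff, 77)
    np.testing.assert_array_equal(r1.channels["ED"], r2.channels["ED"])
    np.testing.assert_array_equal(r1.channels["FDS"], r2.channels["FDS"])


def test_spectral_sanity_mains_line_present_then_notched(profile):
    """The 50 Hz line is visible in the raw periodogram and >= 20 dB down
    after the notch stage."""
    rec = generate_calibration_recording(profile, 13)
    x = rec.channels["ED"]
    f, pxx = sps.periodogram(x, fs=200.0)
    mains_bin = int(np.argmin(np.abs(f - 50.0)))
    rest = (f > 20) & (f < 45)
    assert pxx[mains_bin] > 10 * np.median(pxx[rest])  # line stands out

    y = filter_raw(rec)["ED"]
    _, pyy = sps.periodogram(y, fs=200.0)
    assert 10 * np.log10(pxx[mains_bin] / pyy[mains_bin]) >= 20.0


def test_carrier_power_concentrated_in_band(quiet_profile):
    """Without interference/drift, activation power sits in the 20-90 Hz band."""
    rec = generate_calibration_recording(
        quiet_profile, 17, interference_fraction=0.0, drift_fraction=0.0
    )
    x = rec.channels["FDS"][int(9 * 200) : int(15 * 200)]  # inside flexion
    f, pxx = sps.periodogram(x, fs=200.0)
    inband = pxx[(f >= 18) & (f <= 92)].sum()
    assert inband / pxx.sum() > 0.95


def test_trial_duration_mismatch_rejected(profile):
    target = generate_target_sequence(5)
    with pytest.raises(ValueError, match="duration"):
        generate_trial_recording(profile, target, ConditionEffect("A"), 1, duration=30.0)


def test_perfect_subject_fast_path_matches_target_exactly():
    """No errors, deterministic delay: after synchronization the recognized
    series equals the target at every sample."""
    prof = SubjectProfile(subject_id=1, response_delay_sd=0.0)
    target = generate_target_sequence(31)
    eff = ConditionEffect("C", error_prob=0.0)
    rec = simulate_recognized_series(prof, target, eff, 8)
    sync, score = score_trial(target.as_series(), rec)
    assert score.d_l2 == 0.0
    assert sync.delay_seconds == pytest.approx(
        prof.response_delay_mean + RECOGNITION_LATENCY_S, abs=0.05
    )


def test_perfect_subject_raw_chain_recovers_target(quiet_profile):
    """Raw path, clean signals: the full chain recovers the target almost
    everywhere (transition edges excepted, filter rise/fall is asymmetric)."""
    prof = SubjectProfile(
        subject_id=1, rest_level_ed=0.0, rest_level_fds=0.0, response_delay_sd=0.0
    )
    target = generate_target_sequence(31)
    eff = ConditionEffect("C", error_prob=0.0)
    raw = generate_trial_recording(
        prof, target, eff, 8, interference_fraction=0.0, drift_fraction=0.0
    )
    calib = generate_calibration_recording(
        prof, 9, interference_fraction=0.0, drift_fraction=0.0
    )
    params = calibrate(rectify_rms(filter_raw(calib)))
    recognized = classify_series(process_recording(raw, params), params)
    sync, score = score_trial(target.as_series(), recognized)
    agreement = np.mean(
        sync.aligned_recognized.values == sync.aligned_target.values
    )
    assert agreement > 0.95
    assert 0.2 <= sync.delay_seconds <= 1.5


def test_wrong_muscle_errors_touch_every_active_gesture():
    """error_prob = 1 with wrong-muscle errors only: every non-rest gesture
    contains samples disagreeing with the target."""
    prof = SubjectProfile(subject_id=1, response_delay_sd=0.0, skill=0.5)
    target = generate_target_sequence(41)
    eff = ConditionEffect("A", error_prob=1.0, error_kinds=("wrong_muscle",))
    rec = simulate_recognized_series(prof, target, eff, 4)
    t = rec.times
    lag = prof.response_delay_mean + RECOGNITION_LATENCY_S
    for k, g in enumerate(target.gestures):
        if g == 0:
            continue
        window = (t >= 3 * k + lag) & (t < 3 * k + lag + 0.3)
        assert np.any(rec.values[window] != g), f"gesture {k} had no error"


def test_mean_l2_monotone_in_error_prob():
    """Expected d_L2 is non-decreasing in error_prob (3 levels, fixed seeds)."""
    levels = [0.0, 0.05, 0.30]
    means = []
    for p in levels:
        eff = ConditionEffect("X", error_prob=p)
        scores = []
        for sid in range(1, 19):
            rng = np.random.default_rng([200 + sid, int(p * 1000)])
            prof = SubjectProfile(subject_id=sid)
            for _ in range(4):
                target = generate_target_sequence(rng)
                rec = simulate_recognized_series(prof, target, eff, rng)
                _, score = score_trial(target.as_series(), rec)
                scores.append(score.d_l2)
        means.append(np.mean(scores))
    assert means[0] < means[1] < means[2]


def test_profile_validation():
    with pytest.raises(ValueError, match="rest levels"):
        SubjectProfile(subject_id=1, rest_level_ed=0.2)
    with pytest.raises(ValueError, match="MVC"):
        SubjectProfile(subject_id=1, mvc_ed=-1.0)
    with pytest.raises(ValueError, match="3 s"):
        SubjectProfile(subject_id=1, response_delay_mean=2.9)
    with pytest.raises(ValueError, match="error_prob"):
        ConditionEffect("A", error_prob=1.5)
    with pytest.raises(ValueError, match="error_kinds"):
        ConditionEffect("A", error_kinds=("typo",))
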