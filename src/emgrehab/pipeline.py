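"""End-to-end experiment orchestration.

``run_experiment`` reproduces the study design: a cohort of subjects
(default 18), each calibrated once and then run through the four feedback
conditions A-D in a per-subject random order (or a balanced Latin square),
one 60 s test of 20 random gestures per condition.  Each trial is scored
by synchronizing the recognized series to the target and computing the L2
distance; the cohort table then feeds the ANOVA, Duncan's multiple range
test and the homoscedasticity check.

Two simulation modes share one behavioral subject model:

* ``mode="raw"`` synthesizes 200 Hz two-channel sEMG and runs the full
  conditioning chain and threshold classifier (the default; slower);
* ``mode="behavioral"`` renders the recognized gesture series directly at
  20 Hz (an idealized device), suitable for cohort-scale Monte-Carlo.

Determinism: every subject draws from a generator seeded with
``SeedSequence([master_seed, subject_id])``, so runs are reproducible and
independent of subject iteration order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import io as eio
from .calibration import CalibrationParams, calibrate
from .evaluation import score_trial
from .gesture import classify_series
from .signal import filter_raw, process_recording, rectify_rms
from .stats import (
    AnovaTable,
    DuncanResult,
    HomoscedasticityResult,
    check_homoscedasticity,
    duncan_mrt,
    fit_additive_anova,
    validate_results_table,
)
from .synthetic import (
    ConditionEffect,
    SubjectProfile,
    default_conditions,
    generate_calibration_recording,
    generate_subject_profile,
    generate_target_sequence,
    generate_trial_recording,
    simulate_recognized_series,
)

logger = logging.getLogger("emgrehab")

N_SUBJECTS_DEFAULT = 18


@dataclass
class RunConfig:
    """One experiment run: cohort size, condition effects, seeding, output."""

    seed: int = 0
    n_subjects: int = N_SUBJECTS_DEFAULT
    conditions: dict[str, ConditionEffect] = field(default_factory=default_conditions)
    order_mode: Literal["random", "latin"] = "random"
    mode: Literal["raw", "behavioral"] = "raw"
    alpha: float = 0.05
    outdir: Path | None = None
    n_gestures: int = 20
    gesture_duration: float = 3.0
    interference_fraction: float = 0.10
    drift_fraction: float = 0.05
    ideal_subjects: bool = False  # deterministic response delays (for diagnostics)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.conditions:
            raise ValueError("need at least one condition")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "conditions" in d:
            d["conditions"] = {
                name: ConditionEffect(name, **eff)
                for name, eff in d["conditions"].items()
            }
        if d.get("outdir"):
            d["outdir"] = Path(d["outdir"])
        return cls(**d)


@dataclass
class ExperimentResult:
    results: pd.DataFrame        # subject, test, order, t_d_seconds, d_l2
    anova: AnovaTable
    duncan: DuncanResult
    homoscedasticity: HomoscedasticityResult


def _subject_rng(master_seed: int, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(subject_id)]))


def _orders(config: RunConfig, rng: np.random.Generator, subject_index: int) -> list[str]:
    names = sorted(config.conditions)
    if config.order_mode == "latin":
        k = subject_index % len(names)
        return names[k:] + names[:k]  # cyclic Latin-square row
    return [names[i] for i in rng.permutation(len(names))]


def _simulate_subject(
    config: RunConfig, subject_id: int, subject_index: int
) -> list[dict]:
    rng = _subject_rng(config.seed, subject_id)
    profile = generate_subject_profile(subject_id, rng)
    if config.ideal_subjects:
        profile = replace(profile, response_delay_sd=0.0)

    params: CalibrationParams | None = None
    if config.mode == "raw":
        calib = generate_calibration_recording(
            profile,
            rng,
            interference_fraction=config.interference_fraction,
            drift_fraction=config.drift_fraction,
        )
        remg = rectify_rms(filter_raw(calib))
        params = calibrate(remg)
        if config.outdir is not None:
            eio.write_recording_csv(calib, config.outdir / f"subject{subject_id}_calibration.csv")
            params.to_json(config.outdir / f"subject{subject_id}_calibration.json")
        logger.info(
            "subject %d calibrated: MVC_ED=%.3f MVC_FDS=%.3f eps=%.3f mu=%.3f",
            subject_id, params.mvc_ed, params.mvc_fds, params.epsilon, params.mu,
        )

    rows = []
    # a fresh order permutation per subject (drawn from the subject's stream)
    order = _orders(config, rng, subject_index)
    for position, cond_name in enumerate(order, start=1):
        effect = config.conditions[cond_name]
        target = generate_target_sequence(
            rng, n_gestures=config.n_gestures, gesture_duration=config.gesture_duration
        )
        target_series = target.as_series()
        if config.mode == "raw":
            raw = generate_trial_recording(
                profile, target, effect, rng,
                interference_fraction=config.interference_fraction,
                drift_fraction=config.drift_fraction,
            )
            assert params is not None
            nemg = process_recording(raw, params)
            recognized = classify_series(nemg, params)
            if config.outdir is not None:
                eio.write_recording_csv(raw, config.outdir / f"subject{subject_id}_test{cond_name}.csv")
                eio.write_normalized_csv(nemg, config.outdir / f"subject{subject_id}_test{cond_name}_nemg.csv")
        else:
            recognized = simulate_recognized_series(profile, target, effect, rng)
        sync, score = score_trial(target_series, recognized)
        if config.outdir is not None:
            eio.write_gesture_csv(
                target_series,
                config.outdir / f"subject{subject_id}_test{cond_name}_order{position}_target.csv",
            )
            eio.write_gesture_csv(
                recognized,
                config.outdir / f"subject{subject_id}_test{cond_name}_order{position}_recognized.csv",
            )
            eio.write_trial_json(
                config.outdir / f"subject{subject_id}_test{cond_name}_result.json",
                subject_id, cond_name, position, sync.delay_seconds, score.d_l2,
            )
        logger.info(
            "subject %d test %s (order %d): T_d=%.2f s, d_L2=%.3f",
            subject_id, cond_name, position, sync.delay_seconds, score.d_l2,
        )
        rows.append(
            {
                "subject": subject_id,
                "test": cond_name,
                "order": position,
                "t_d_seconds": sync.delay_seconds,
                "d_l2": score.d_l2,
            }
        )
    return rows


def simulate_results_table(config: RunConfig) -> pd.DataFrame:
    """Cohort score table (subject, test, order, t_d_seconds, d_l2)."""
    rows: list[dict] = []
    for idx in range(config.n_subjects):
        subject_id = idx + 1
        try:
            rows.extend(_simulate_subject(config, subject_id, idx))
        except Exception as exc:  # noqa: BLE001 - re-tag with the failing unit
            raise RuntimeError(f"subject {subject_id} failed: {exc}") from exc
    return pd.DataFrame(rows)


def analyze_results(table: pd.DataFrame, alpha: float = 0.05) -> ExperimentResult:
    """Stats stage: ANOVA + Duncan + homoscedasticity on a score table."""
    validate_results_table(table)
    anova = fit_additive_anova(table)
    duncan = duncan_mrt(table, anova, alpha=alpha)
    homo = check_homoscedasticity(table, alpha=alpha)
    return ExperimentResult(table, anova, duncan, homo)


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Simulate the full cohort and run the statistics stage."""
    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
    table = simulate_results_table(config)
    result = analyze_results(table, alpha=config.alpha)
    if config.outdir is not None:
        eio.write_results_csv(table, config.outdir / "results.csv")
        result.anova.table.to_csv(config.outdir / "anova.csv")
        result.duncan.p_values.to_csv(config.outdir / "duncan.csv")
        summary = {
            "anova_p_test": result.anova.p_value("Test"),
            "anova_p_order": result.anova.p_value("Order"),
            "anova_p_individual": result.anova.p_value("Individual"),
            "residual_df": result.anova.residual_df,
            "levene_p": result.homoscedasticity.p_value,
            "mean_d_l2_by_test": result.duncan.group_means.to_dict(),
            "mean_t_d_seconds": float(table["t_d_seconds"].mean()),
        }
        (config.outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return result


def reanalyze(trials_dir: str | Path, alpha: float = 0.05) -> ExperimentResult:
    """Re-score and re-analyze archived gesture CSVs.

    Expects per-trial pairs named
    ``subject<id>_test<T>_order<k>_target.csv`` /
    ``..._recognized.csv`` (the layout ``run_experiment`` writes).
    Only the evaluation and statistics stages run; raw EMG is not needed.
    """
    trials_dir = Path(trials_dir)
    targets = sorted(trials_dir.glob("subject*_test*_order*_target.csv"))
    if not targets:
        raise ValueError(f"no '*_target.csv' trial files found in {trials_dir}")
    rows = []
    seen: set[tuple[int, str]] = set()
    for tpath in targets:
        stem = tpath.name[: -len("_target.csv")]
        rpath = trials_dir / f"{stem}_recognized.csv"
        if not rpath.exists():
            raise ValueError(f"missing recognized series for {tpath.name}")
        parts = stem.split("_")  # subject<i>, test<T>, order<k>
        subject = int(parts[0].removeprefix("subject"))
        test = parts[1].removeprefix("test")
        order = int(parts[2].removeprefix("order"))
        target = eio.read_gesture_csv(tpath, role="target")
        recognized = eio.read_gesture_csv(rpath, role="recognized")
        sync, score = score_trial(target, recognized)
        rows.append(
            {
                "subject": subject,
                "test": test,
                "order": order,
                "t_d_seconds": sync.delay_seconds,
                "d_l2": score.d_l2,
            }
        )
        seen.add((subject, test))
    table = pd.DataFrame(rows)
    subjects = sorted(table["subject"].unique())
    tests = sorted(table["test"].unique())
    for s in subjects:
        for t in tests:
            if (s, t) not in seen:
                raise ValueError(
                    f"unbalanced trial directory: missing subject {s}, test {t}"
                )
    return analyze_results(table, alpha=alpha)
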