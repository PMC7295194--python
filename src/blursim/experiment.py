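"""Simulated experiment runner.

One session runs a fresh 3-down-1-up staircase for each of the 16
conditions (4 retinal locations x clear/blurred x congruent/incongruent
cue), interleaved at random until every track terminates.  The cue's
congruency is a property of the staircase's condition: congruent and
incongruent tracks are interleaved in equal numbers, so the 50% cue
validity experienced by the simulated subject emerges from the design
itself.  Trial timing is virtual bookkeeping on a millisecond clock
(cue -> ISI -> target -> response); nothing is simulated in real time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .conditions import BLUR_LEVELS, CUE_LEVELS, Condition, LOCATIONS, OPPOSITE
from .observer import ObserverModel, simulate_response
from .staircase import (
    StaircaseConfig,
    ThresholdEstimate,
    estimate_threshold,
    interleave,
    new_staircase,
    update,
)

__all__ = [
    "ExperimentConfig",
    "TrialRecord",
    "Dataset",
    "build_conditions",
    "run_session",
    "run_experiment",
]


def _default_staircase() -> StaircaseConfig:
    # start four times above a nominal clear threshold of ~3 arcmin
    return StaircaseConfig(initial_level=12.0)


@dataclass(frozen=True)
class ExperimentConfig:
    locations: tuple[str, ...] = LOCATIONS
    sessions: int = 5
    cue_validity: float = 0.5
    cue_duration_ms: float = 50.0
    isi_ms: float = 66.0
    target_duration_ms: float = 33.0
    intertrial_ms: float = 500.0
    staircase: StaircaseConfig = field(default_factory=_default_staircase)
    n_subjects: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cue_validity < 1:
            raise ValueError("cue_validity must be in (0, 1)")
        if self.sessions < 1 or self.n_subjects < 1:
            raise ValueError("sessions and n_subjects must be >= 1")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["locations"] = list(self.locations)
        data["staircase"]["level_bounds"] = list(self.staircase.level_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "locations" in data:
            data["locations"] = tuple(data["locations"])
        if "staircase" in data:
            sc = dict(data["staircase"])
            if "level_bounds" in sc:
                sc["level_bounds"] = tuple(sc["level_bounds"])
            data["staircase"] = StaircaseConfig(**sc)
        return cls(**data)


class TrialRecord(NamedTuple):
    subject: str
    session: int
    trial: int
    location: str
    blur: str
    cue: str
    cue_location: str
    level_arcmin: float
    correct: bool
    rt_ms: float
    cue_onset_ms: float
    target_onset_ms: float
    target_offset_ms: float
    feedback: str


@dataclass
class Dataset:
    """Trial log plus per-staircase threshold estimates."""

    trials: pd.DataFrame
    estimates: pd.DataFrame
    config: ExperimentConfig

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.estimates.to_csv(out / "thresholds.csv", index=False)


def build_conditions(config: ExperimentConfig) -> list[Condition]:
    """Ordered cartesian product: locations x blur x cue."""
    return [
        Condition(loc, blur, cue)
        for loc in config.locations
        for blur in BLUR_LEVELS
        for cue in CUE_LEVELS
    ]


def run_session(
    config: ExperimentConfig,
    observer: ObserverModel,
    session: int,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], dict[Condition, ThresholdEstimate]]:
    """Run one session: fresh interleaved staircases, all to termination."""
    conditions = build_conditions(config)
    states = [new_staircase(config.staircase) for _ in conditions]
    records: list[TrialRecord] = []
    clock = 0.0
    trial = 0
    while any(not s.terminated for s in states):
        i = interleave(states, rng)
        cond = conditions[i]
        level = states[i].current_level
        correct, rt = simulate_response(observer, cond, level, rng)
        update(states[i], correct, config.staircase)
        cue_location = (
            cond.location if cond.cue == "congruent" else OPPOSITE[cond.location]
        )
        cue_onset = clock
        target_onset = cue_onset + config.cue_duration_ms + config.isi_ms
        target_offset = target_onset + config.target_duration_ms
        records.append(
            TrialRecord(
                subject=observer.subject_id,
                session=session,
                trial=trial,
                location=cond.location,
                blur=cond.blur,
                cue=cond.cue,
                cue_location=cue_location,
                level_arcmin=level,
                correct=correct,
                rt_ms=rt,
                cue_onset_ms=cue_onset,
                target_onset_ms=target_onset,
                target_offset_ms=target_offset,
                feedback="correct" if correct else "incorrect",
            )
        )
        clock = target_offset + rt + config.intertrial_ms
        trial += 1
    estimates = {
        cond: estimate_threshold(state, config.staircase)
        for cond, state in zip(conditions, states)
    }
    return records, estimates


def run_experiment(config: ExperimentConfig, cohort: list[ObserverModel]) -> Dataset:
    """Run all sessions for all subjects.

    Every (subject, session) pair gets an independent child stream
    spawned from ``config.seed``, so the full dataset is exactly
    reproducible from the config and cohort alone.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    children = np.random.SeedSequence(config.seed).spawn(len(cohort) * config.sessions)
    all_trials: list[TrialRecord] = []
    est_rows = []
    for si, observer in enumerate(cohort):
        for sess in range(config.sessions):
            rng = np.random.default_rng(children[si * config.sessions + sess])
            trials, estimates = run_session(config, observer, sess, rng)
            all_trials.extend(trials)
            for cond, est in estimates.items():
                est_rows.append(
                    (
                        observer.subject_id,
                        sess,
                        cond.location,
                        cond.blur,
                        cond.cue,
                        est.mad,
                        est.n_reversals_used,
                        est.n_trials,
                    )
                )
    trials_df = pd.DataFrame(all_trials, columns=TrialRecord._fields)
    estimates_df = pd.DataFrame(
        est_rows,
        columns=[
            "subject",
            "session",
            "location",
            "blur",
            "cue",
            "mad_arcmin",
            "n_reversals_used",
            "n_trials",
        ],
    )
    return Dataset(trials=trials_df, estimates=estimates_df, config=config)
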