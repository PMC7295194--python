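"""Transformed up-down adaptive procedure (three-down one-up).

A 3-down-1-up staircase lowers the stimulus level after three
consecutive correct responses and raises it after a single error, so it
converges at the level where the per-trial probability of a correct
response satisfies ``p**3 = 1/2``, i.e. p = (1/2)**(1/3) = 79.4%.

Steps are multiplicative (log units): a coarse factor while the track
descends toward threshold, shrinking to a fine factor (about 1 dB)
after a fixed number of reversals.  The per-track threshold is the
geometric mean of the last reversal levels -- the estimator that
matches multiplicative steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StaircaseError",
    "StaircaseConfig",
    "StaircaseState",
    "ThresholdEstimate",
    "new_staircase",
    "update",
    "estimate_threshold",
    "interleave",
    "run_staircase",
    "export_trace",
]


class StaircaseError(RuntimeError):
    """Staircase used outside its valid state."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Rule and stopping parameters of one adaptive track.

    Defaults give roughly 1-dB final steps, stop after 12 reversals and
    average the last 8 reversal levels.
    """

    initial_level: float
    down_count: int = 3
    up_count: int = 1
    initial_step: float = 1.5
    final_step: float = 1.122
    step_shrink_reversals: int = 2
    termination_reversals: int = 12
    reversals_averaged: int = 8
    level_bounds: tuple[float, float] = (0.25, 120.0)

    def __post_init__(self) -> None:
        if self.down_count < 1 or self.up_count < 1:
            raise ValueError("down_count and up_count must be >= 1")
        if self.initial_step <= 1 or self.final_step <= 1:
            raise ValueError("step factors must be > 1")
        if self.reversals_averaged > self.termination_reversals:
            raise ValueError("cannot average more reversals than are collected")
        lo, hi = self.level_bounds
        if not lo < hi:
            raise ValueError("level_bounds must be ordered")
        if not lo <= self.initial_level <= hi:
            raise ValueError("initial_level outside level_bounds")


@dataclass
class StaircaseState:
    """Mutable state of one track; history rows are
    ``(level, correct, reversal_flag, step_factor)``."""

    current_level: float
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    reversal_levels: list[float] = field(default_factory=list)
    trial_history: list[tuple[float, bool, bool, float]] = field(default_factory=list)
    direction: str | None = None
    terminated: bool = False


def new_staircase(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_level=config.initial_level)


def update(state: StaircaseState, correct: bool, config: StaircaseConfig) -> StaircaseState:
    """Advance the track by one response; mutates and returns ``state``.

    The level changes immediately on the ``down_count``-th consecutive
    correct response (or the ``up_count``-th consecutive error).  A
    direction change records the pre-change level as a reversal; the
    step factor shrinks once ``step_shrink_reversals`` reversals have
    occurred.  Levels clamp to the configured bounds, and clamping
    itself never counts as a reversal.
    """
    if state.terminated:
        raise StaircaseError("update() called on a terminated staircase")
    move = None
    if correct:
        state.consecutive_correct += 1
        state.consecutive_incorrect = 0
        if state.consecutive_correct >= config.down_count:
            move = "down"
            state.consecutive_correct = 0
    else:
        state.consecutive_incorrect += 1
        state.consecutive_correct = 0
        if state.consecutive_incorrect >= config.up_count:
            move = "up"
            state.consecutive_incorrect = 0
    step = (
        config.initial_step
        if len(state.reversal_levels) < config.step_shrink_reversals
        else config.final_step
    )
    is_reversal = False
    if move is not None:
        if state.direction is not None and move != state.direction:
            is_reversal = True
            state.reversal_levels.append(state.current_level)
            if len(state.reversal_levels) >= config.termination_reversals:
                state.terminated = True
        state.direction = move
    state.trial_history.append((state.current_level, bool(correct), is_reversal, step))
    if move is not None:
        lo, hi = config.level_bounds
        level = (
            state.current_level / step if move == "down" else state.current_level * step
        )
        state.current_level = min(max(level, lo), hi)
    return state


def estimate_threshold(state: StaircaseState, config: StaircaseConfig) -> "ThresholdEstimate":
    """Geometric mean of the last ``reversals_averaged`` reversal levels."""
    if not state.terminated:
        raise StaircaseError("estimate_threshold() requires a terminated staircase")
    tail = np.asarray(state.reversal_levels[-config.reversals_averaged :])
    mad = float(np.exp(np.mean(np.log(tail))))
    return ThresholdEstimate(
        mad=mad, n_reversals_used=len(tail), n_trials=len(state.trial_history)
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    mad: float
    n_reversals_used: int
    n_trials: int


def interleave(staircases: Sequence[StaircaseState], rng: np.random.Generator) -> int:
    """Uniformly random index among the non-terminated tracks."""
    active = [i for i, s in enumerate(staircases) if not s.terminated]
    if not active:
        raise StaircaseError("all staircases are terminated")
    return active[rng.integers(len(active))]


def run_staircase(
    config: StaircaseConfig,
    p_correct: Callable[[float], float],
    rng: np.random.Generator,
) -> StaircaseState:
    """Run one track to termination against a stochastic observer.

    ``p_correct(level)`` gives the probability of a correct response at
    a stimulus level; responses are drawn Bernoulli from it.
    """
    state = new_staircase(config)
    while not state.terminated:
        update(state, bool(rng.random() < p_correct(state.current_level)), config)
    return state


def export_trace(state: StaircaseState, path) -> None:
    """Write the trial-by-trial track history as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "level_arcmin", "correct", "reversal_flag", "step_factor"])
        for i, (level, correct, rev, step) in enumerate(state.trial_history):
            writer.writerow([i, repr(level), int(correct), int(rev), step])
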