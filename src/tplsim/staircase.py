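"""One-up-three-down adaptive staircase for 2IFC duration discrimination.

The comparison offset Δt starts at 20% of the standard interval T. Three
consecutive correct responses decrease Δt by the step in force; a single
error increases it. The step is 10% of T until the third reversal has been
recorded and 5% of T from the next Δt change onward. A transformed up/down
rule of this kind equilibrates where the probability of a 3-correct run
equals 1/2, i.e. at P(correct) = 0.5^(1/3) ≈ 0.794.

Reversal bookkeeping: a reversal is flagged on the trial whose Δt change
flips the realized movement direction (down→up or up→down). Trials with no
Δt change carry the last realized direction, and the first change only
establishes a direction. The reversal value recorded is the Δt presented on
the flagged trial, i.e. the local extremum of the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .observer import Condition, ObserverParams, respond_2ifc

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "init_staircase",
    "update_staircase",
    "step_in_force",
    "run_block",
    "recount_reversals",
    "convergence_probability",
]

_EPS = 1e-9


@dataclass(frozen=True)
class TimingMetadata:
    """Presentation timing of the task, carried for record-keeping only."""

    fixation_ms: float = 500.0
    isi_ms: float = 800.0
    feedback_ms: float = 1000.0


@dataclass(frozen=True)
class StaircaseConfig:
    standard_T: float
    initial_delta_fraction: float = 0.20
    coarse_step_fraction: float = 0.10
    fine_step_fraction: float = 0.05
    step_change_after_reversal: int = 3
    trials_per_block: int = 60
    down_rule: int = 3
    up_rule: int = 1
    #: Smallest presentable Δt; defaults to one fine step (never 0: a zero Δt
    #: would leave "correct" undefined).
    delta_floor: float | None = None
    #: Optional display-frame grid (e.g. 10 ms on a 100 Hz CRT); Δt is snapped
    #: to multiples of this after every change. Off by default.
    frame_grid_ms: float | None = None
    timing: TimingMetadata = field(default_factory=TimingMetadata)

    def __post_init__(self) -> None:
        if self.standard_T <= 0:
            raise ValueError("standard_T must be positive")
        for name in ("initial_delta_fraction", "coarse_step_fraction", "fine_step_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fine_step_fraction >= self.coarse_step_fraction:
            raise ValueError("fine step must be smaller than coarse step")
        if self.down_rule < 1 or self.up_rule != 1:
            raise ValueError("supported rules: down_rule >= 1, up_rule == 1")
        if self.trials_per_block < 1 or self.step_change_after_reversal < 0:
            raise ValueError("counts must be positive")
        floor = self.floor
        if not 0.0 < floor <= self.initial_delta_fraction * self.standard_T:
            raise ValueError("delta_floor must lie in (0, initial Δt]")

    @property
    def floor(self) -> float:
        if self.delta_floor is not None:
            return self.delta_floor
        return self.fine_step_fraction * self.standard_T

    @property
    def initial_delta(self) -> float:
        return self.initial_delta_fraction * self.standard_T


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of the staircase between trials."""

    delta: float
    consecutive_correct: int = 0
    direction: int = 0  # -1 moving down, +1 moving up, 0 no change yet
    reversal_values: tuple[float, ...] = ()
    trial_index: int = 0

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_values)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    delta: float  # Δt presented on this trial, ms
    order: str  # "standard_first" | "comparison_first"
    choice: str  # "first" | "second"
    correct: bool
    reversal: bool
    step_ms: float  # step size in force when this trial was scored


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Fresh state: Δt at 20% of T, counters zeroed, no direction yet."""
    return StaircaseState(delta=config.initial_delta)


def step_in_force(state: StaircaseState, config: StaircaseConfig) -> float:
    """Step size (ms) a Δt change at this point would use.

    Coarse until the configured reversal count has been recorded; the change
    that causes that reversal itself still uses the coarse step, and every
    later change uses the fine step.
    """
    if state.n_reversals < config.step_change_after_reversal:
        return config.coarse_step_fraction * config.standard_T
    return config.fine_step_fraction * config.standard_T


def update_staircase(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Score one response and return the next state.

    Three consecutive correct responses move Δt down one step (clamped at the
    floor) and reset the run counter; one error moves it up and resets the
    counter. A clamp that leaves Δt unchanged is not a realized movement and
    cannot produce a reversal.
    """
    step = step_in_force(state, config)
    cc = state.consecutive_correct
    change = 0.0
    if correct:
        cc += 1
        if cc >= config.down_rule:
            change = -step
            cc = 0
    else:
        change = +step
        cc = 0

    delta = state.delta
    direction = state.direction
    reversals = state.reversal_values
    if change != 0.0:
        new_delta = delta + change
        if config.frame_grid_ms:
            new_delta = round(new_delta / config.frame_grid_ms) * config.frame_grid_ms
        new_delta = max(new_delta, config.floor)
        if abs(new_delta - delta) > _EPS:
            move = 1 if new_delta > delta else -1
            if direction != 0 and move != direction:
                reversals = reversals + (delta,)
            direction = move
            delta = new_delta

    return StaircaseState(
        delta=delta,
        consecutive_correct=cc,
        direction=direction,
        reversal_values=reversals,
        trial_index=state.trial_index + 1,
    )


def run_block(
    config: StaircaseConfig,
    observer: ObserverParams,
    condition: Condition,
    session_index: int,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> tuple[list[TrialRecord], StaircaseState]:
    """Run one block: the observer responds trial-by-trial, the staircase adapts.

    Standard/comparison presentation order is randomized per trial with
    p = 0.5. Returns the per-trial log and the final state (whose ``delta``
    is the level the 61st trial would have been presented at).
    """
    if n_trials is None:
        n_trials = config.trials_per_block
    state = init_staircase(config)
    records: list[TrialRecord] = []
    T = config.standard_T
    for i in range(n_trials):
        delta = state.delta
        comparison_first = bool(rng.random() < 0.5)
        if comparison_first:
            t1, t2, order = T + delta, T, "comparison_first"
        else:
            t1, t2, order = T, T + delta, "standard_first"
        choice, correct = respond_2ifc(
            t1, t2, observer, condition, rng, session_index=session_index
        )
        step = step_in_force(state, config)
        nrev = state.n_reversals
        state = update_staircase(state, correct, config)
        records.append(
            TrialRecord(
                trial_index=i,
                delta=delta,
                order=order,
                choice=choice,
                correct=correct,
                reversal=state.n_reversals > nrev,
                step_ms=step,
            )
        )
    return records, state


def recount_reversals(
    presented_deltas: Sequence[float], final_delta: float
) -> list[bool]:
    """Recompute per-trial reversal flags from the Δt sequence alone.

    ``presented_deltas`` are the Δt values shown on trials 1..n and
    ``final_delta`` the post-block staircase level; the change scored on
    trial i is ``delta[i+1] - delta[i]``. A trial is flagged when the sign of
    its change differs from the last non-zero change before it.
    """
    seq = list(presented_deltas) + [final_delta]
    flags = [False] * len(presented_deltas)
    last = 0
    for i in range(len(presented_deltas)):
        diff = seq[i + 1] - seq[i]
        if abs(diff) > _EPS:
            d = 1 if diff > 0 else -1
            if last != 0 and d != last:
                flags[i] = True
            last = d
    return flags


def convergence_probability(down_rule: int) -> float:
    """Accuracy at which an n-down-1-up staircase equilibrates: 0.5^(1/n).

    At equilibrium the probabilities of a downward move (a run of ``n``
    consecutive correct responses) and an upward move are equal, so
    p^n = 1/2. For the 3-down rule this is ≈ 0.794, the classic "79%" point.
    """
    if down_rule < 1:
        raise ValueError("down_rule must be >= 1")
    return 0.5 ** (1.0 / down_rule)
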