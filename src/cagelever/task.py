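"""Trial classification and the adaptive hold-time scheduler.

The task has two stages. Stage 1 is habituation: any lever pull past the
3-degree registration threshold earns a water drop; a mouse advances to
stage 2 the day after it first performs at least 100 pulls in a day. In
stage 2 the lever must be held inside the 6-24 degree goal range for at
least the mouse's current *required hold time*, which starts at 0 s and is
re-benchmarked nightly at midnight: the candidate new requirement is the
75th percentile of that day's hold times (all trials, successes and
failures), adopted only if it exceeds the current value and the day had at
least 100 trials with a success rate of at least 30%. The requirement is
capped at 1 s. If the daily success rate falls below 10% for two
consecutive days, the requirement is reset to the last benchmark (the value
in force before the most recent upward update) to protect hydration and
motivation. Holds are truncated at 5 s, where lever resistance reverts to
the high-force state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import Trajectory

__all__ = [
    "LeverGeometry",
    "SchedulerState",
    "DaySummary",
    "CUE_START_HZ",
    "CUE_SUCCESS_HZ",
    "CUE_FAILURE_HZ",
    "MAX_HOLD_S",
    "compute_hold_time",
    "classify_trial",
    "advance_stage",
    "update_required_hold_time",
    "free_water_deficit",
]

CUE_START_HZ = 2500.0
CUE_SUCCESS_HZ = 5000.0
CUE_FAILURE_HZ = 1000.0

MAX_HOLD_S = 5.0  # lever resistance reverts to high force beyond this


@dataclass(frozen=True)
class LeverGeometry:
    """Angular layout of the lever: 0-30 degree travel, pull registration at
    3 degrees, goal range 6-24 degrees."""

    pull_threshold: float = 3.0
    goal_low: float = 6.0
    goal_high: float = 24.0
    range_max: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.pull_threshold < self.goal_low < self.goal_high <= self.range_max):
            raise ValueError("invalid lever geometry ordering")


@dataclass
class SchedulerState:
    """Per-mouse scheduler state carried across days."""

    mouse_id: str
    stage: int = 1
    required_hold_time: float = 0.0
    consecutive_low_days: int = 0
    last_benchmark: float = 0.0
    water_deficit_drops: int = 0


@dataclass
class DaySummary:
    """One completed day of one mouse's stage-2 trials."""

    mouse_id: str
    day_index: int
    hold_times: list[float] = field(default_factory=list)
    n_success: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.hold_times)

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_trials if self.n_trials else 0.0

    @property
    def p75_hold(self) -> float:
        if not self.hold_times:
            return 0.0
        # linear-interpolation (type-7) percentile
        return float(np.percentile(self.hold_times, 75))


def compute_hold_time(traj: Trajectory, geom: LeverGeometry = LeverGeometry()) -> float:
    """Hold duration (s) of the first maximal contiguous in-goal-range run.

    The run is searched from the first sample at or beyond the pull
    registration threshold; 0.0 if the lever never enters the goal range.
    Durations beyond 5 s are truncated at 5 s.
    """
    a = np.asarray(traj.angle, dtype=float)
    if a.size == 0:
        return 0.0
    reg = np.nonzero(a >= geom.pull_threshold)[0]
    if reg.size == 0:
        return 0.0
    a = a[reg[0]:]
    in_goal = (a >= geom.goal_low) & (a <= geom.goal_high)
    idx = np.nonzero(in_goal)[0]
    if idx.size == 0:
        return 0.0
    start = idx[0]
    off = np.nonzero(~in_goal[start:])[0]
    run = off[0] if off.size else in_goal.size - start
    return min(run / traj.fs, MAX_HOLD_S)


def classify_trial(hold_time: float, state: SchedulerState) -> tuple[bool, float]:
    """Outcome of one trial plus the buzzer cue frequency it triggers.

    Stage 1: any registered pull is a success. Stage 2: success iff the hold
    met the current requirement (ties count as success).
    """
    if state.stage == 1:
        success = True
    else:
        success = hold_time >= state.required_hold_time
    return success, CUE_SUCCESS_HZ if success else CUE_FAILURE_HZ


def advance_stage(day: DaySummary, state: SchedulerState, min_trials: int = 100) -> SchedulerState:
    """Stage-1 -> stage-2 promotion, effective the following day, on a day
    with at least ``min_trials`` pulls."""
    if state.stage != 1:
        return replace(state)
    if day.n_trials >= min_trials:
        return replace(state, stage=2, required_hold_time=0.0, last_benchmark=0.0)
    return replace(state)


def update_required_hold_time(
    day: DaySummary,
    state: SchedulerState,
    *,
    cap_s: float = 1.0,
    min_trials: int = 100,
    min_sr: float = 0.30,
    reset_sr: float = 0.10,
    reset_days: int = 2,
    percentile: float = 75.0,
) -> SchedulerState:
    """Nightly requirement update from one completed stage-2 day.

    The candidate is the 75th percentile of ALL of the day's hold times;
    it is adopted (capped at 1 s) only if it exceeds the current value, the
    day had >= 100 trials, and the success rate was >= 30%. Separately, a
    day below 10% success (a zero-trial day counts as one) increments the
    low-success counter; two consecutive low days reset the requirement to
    the last benchmark.
    """
    new = replace(state)
    if state.stage != 2:
        return new

    if day.n_trials > 0:
        candidate = float(np.percentile(day.hold_times, percentile))
        if (
            candidate > new.required_hold_time
            and day.success_rate >= min_sr
            and day.n_trials >= min_trials
        ):
            new.last_benchmark = new.required_hold_time
            new.required_hold_time = min(candidate, cap_s)

    low = day.n_trials == 0 or day.success_rate < reset_sr
    if low:
        new.consecutive_low_days += 1
        if new.consecutive_low_days >= reset_days:
            new.required_hold_time = new.last_benchmark
            new.consecutive_low_days = 0
    else:
        new.consecutive_low_days = 0
    return new


def free_water_deficit(
    rewards_earned_today: int, daily_water_ml: float = 1.0, drop_ul: float = 10.0
) -> int:
    """Compensatory drops owed for tomorrow to reach the ideal daily intake
    (1 mL at 10 uL per drop = 100 drops)."""
    target = int(round(daily_water_ml * 1000.0 / drop_ul))
    return max(0, target - rewards_earned_today)
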