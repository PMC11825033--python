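"""Closed-loop agent-based simulator of a multi-animal lever-task cage.

Each simulated mouse visits the chamber as a Poisson process, performs a
geometric-sized bout of trials per entry, and draws each trial's hold time
from the same two-process mixture the analysis suite fits: with
probability ``w(day)`` an exponential "untimed" pull (rate ``kappa(day)``),
otherwise a "timed" pull from a Gaussian centered just above the current
required hold time. The scheduler closes the loop nightly, so a regime in
which ``w`` declines (WT-like) ratchets the requirement toward the 1 s cap,
while a persistently untimed regime (HD-like) plateaus below it.

Trajectories are synthesized to reproduce exactly the sampled hold time
when scored by :func:`cagelever.task.compute_hold_time` (to within one
sample period), with band-limited >10 Hz noise of controllable standard
deviation so the jerkiness pipeline has a known ground truth.

An optional peer-influence coupling reduces an agent's ``w`` for one bout
whenever the preceding five minutes contain a >=10-trial bout by a
higher-success peer; the default gain is 0 (off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datamodel import DEFAULT_FS, EntryRecord, SessionLog, Trajectory, TrialRecord
from .kinematics import highpass_10hz
from .task import (
    DaySummary,
    LeverGeometry,
    MAX_HOLD_S,
    SchedulerState,
    advance_stage,
    classify_trial,
    compute_hold_time,
    free_water_deficit,
    update_required_hold_time,
)

__all__ = [
    "AgentParams",
    "SimConfig",
    "constant",
    "linear_schedule",
    "wt_like_agent",
    "hd_like_agent",
    "sample_hold_time",
    "synth_trajectory",
    "simulate_cage",
]

Schedule = Callable[[int], float]


def constant(v: float) -> Schedule:
    return lambda day: v


def linear_schedule(v0: float, v1: float, n_days: int) -> Schedule:
    """Linear ramp from v0 on day 0 to v1 on day n_days-1, clamped outside."""
    span = max(n_days - 1, 1)

    def f(day: int) -> float:
        frac = min(max(day / span, 0.0), 1.0)
        return v0 + (v1 - v0) * frac

    return f


@dataclass
class AgentParams:
    """Behavioral parameters of one simulated mouse.

    ``w_schedule``/``kappa_schedule`` map 0-based day in cage to the
    mixture weight and exponential rate; ``timed_margin`` is how far above
    the current requirement the timed component aims (s); ``jerk_sd`` the
    SD (degrees) of the >10 Hz trajectory noise; ``entry_rate`` chamber
    entries per hour; ``bout_geom_p`` the geometric parameter of trials per
    entry (mean 1/p); ``influence_gain`` the per-bout reduction of w after
    observing a better-performing peer (0 disables).
    """

    mouse_id: str
    genotype_label: str = "WT"
    w_schedule: Schedule = field(default_factory=lambda: constant(0.8))
    kappa_schedule: Schedule = field(default_factory=lambda: constant(4.0))
    timed_margin: float = 0.05
    sigma_t: float = 0.10
    jerk_sd: float = 0.077
    entry_rate: float = 1.5
    bout_geom_p: float = 0.25
    influence_gain: float = 0.0
    trial_gap_range: tuple[float, float] = (10.0, 60.0)

    def __post_init__(self) -> None:
        if not (0 < self.bout_geom_p <= 1):
            raise ValueError("bout_geom_p must be in (0, 1]")
        if self.sigma_t <= 0 or self.jerk_sd < 0 or self.entry_rate < 0:
            raise ValueError("invalid agent parameters")


@dataclass
class SimConfig:
    n_days: int
    agents: list[AgentParams]
    seed: int
    fs: float = DEFAULT_FS
    day0: str = "2024-01-01"
    cage_id: str = "sim-cage"
    geometry: LeverGeometry = field(default_factory=LeverGeometry)
    store_trajectories: bool = True
    # scheduler parameters (task defaults)
    min_trials: int = 100
    min_sr: float = 0.30


def wt_like_agent(mouse_id: str, n_days: int = 58, **overrides) -> AgentParams:
    """WT-like regime: the untimed weight declines 0.9 -> 0.4 over the run
    and the timed process tracks the requirement, so the scheduler ratchets
    the requirement toward the cap."""
    kw = dict(
        genotype_label="WT",
        w_schedule=linear_schedule(0.9, 0.4, n_days),
        kappa_schedule=constant(4.0),
        timed_margin=0.05,
        sigma_t=0.10,
        jerk_sd=0.077,
        entry_rate=1.5,
        bout_geom_p=0.25,
    )
    kw.update(overrides)
    return AgentParams(mouse_id, **kw)


def hd_like_agent(mouse_id: str, n_days: int = 58, **overrides) -> AgentParams:
    """HD-like regime: w stays high (0.85) and hold times lengthen only by
    a slowly decaying exponential rate, so the requirement plateaus well
    below the cap; trajectories are jerkier and bouts shorter."""
    kw = dict(
        genotype_label="HD",
        w_schedule=constant(0.85),
        kappa_schedule=linear_schedule(5.0, 4.0, n_days),
        timed_margin=0.05,
        sigma_t=0.12,
        jerk_sd=0.098,
        entry_rate=1.8,
        bout_geom_p=0.35,
    )
    kw.update(overrides)
    return AgentParams(mouse_id, **kw)


def sample_hold_time(
    params: AgentParams, day: int, required: float, rng: np.random.Generator
) -> float:
    """Draw one hold time from the agent's day-d mixture: exponential with
    probability w(day), else a Gaussian (truncated at 0) centered
    ``timed_margin`` above the requirement. Clipped at the 5 s ceiling."""
    w = float(np.clip(params.w_schedule(day), 0.0, 1.0))
    if rng.random() < w:
        x = rng.exponential(1.0 / params.kappa_schedule(day))
    else:
        x = rng.normal(required + params.timed_margin, params.sigma_t)
        while x < 0:
            x = rng.normal(required + params.timed_margin, params.sigma_t)
    return float(min(x, MAX_HOLD_S))


_RAMP_MAX = 176  # 0.44 s rise/fall cap at 400 Hz: <=0.005 deg filter leakage
_RAMP_MIN = 150  # narrowest plateau-profile ramp still meeting that bound
_BUMP_RAMP = 160  # rise/fall length of the peek-bump profile
_SUB_RAMP = 120  # rise/fall length of the sub-goal (zero-hold) bump
_LEAD_SAMPLES = 4


def _smoothstep7(x: np.ndarray) -> np.ndarray:
    """C3-continuous sigmoid on [0, 1]; its >10 Hz content at these ramp
    lengths is far below the raised cosine's."""
    return x**4 * (35 + x * (-84 + x * (70 - 20 * x)))


def synth_trajectory(
    hold_time: float,
    jerk_sd: float,
    geom: LeverGeometry = LeverGeometry(),
    fs: float = DEFAULT_FS,
    rng: np.random.Generator | None = None,
    trial_id: str = "synthetic",
) -> Trajectory:
    """Synthesize a lever trace whose scored hold equals ``hold_time`` to
    within one sample period.

    Long holds (>= roughly 0.45 s) use a plateau profile: a smooth sigmoid
    rise to a plateau (uniform 10-20 degrees), the plateau, and a mirrored
    return, with the plateau shortened by exactly the ramp samples inside
    the goal range (transit compensation). Shorter holds use a peek-bump
    profile: a smooth bump whose amplitude is solved so that exactly
    ``round(hold_time * fs)`` samples lie at or above the goal-range floor
    -- the way a brief real hold arises from a pull that barely crests the
    range rather than from an impossibly fast full transit. A zero hold is
    a bump peaking 1 degree below the range. All profiles are slow enough
    that the >10 Hz filter leakage stays near or below 0.005 degrees.

    Band-limited >10 Hz Gaussian noise with sample SD ``jerk_sd`` is added
    and the trace clipped to the lever range. The noise is suppressed where
    the noiseless trace lies within ``max(0.7, 6 * jerk_sd)`` degrees of
    the goal-range floor, so noise cannot split or extend the scored run;
    keep ``jerk_sd`` below about 0.3 degrees (margins shrink to <6 SD
    beyond).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not (0.0 <= hold_time <= MAX_HOLD_S):
        raise ValueError("hold_time must be within [0, 5] s")
    low = geom.goal_low
    n_hold = int(round(hold_time * fs))
    plateau = rng.uniform(10.0, 20.0)

    parts = None
    if n_hold == 0:
        sub_rise = (low - 1.0) * _smoothstep7(np.linspace(0.0, 1.0, _SUB_RAMP))
        parts = [np.zeros(_LEAD_SAMPLES), sub_rise, sub_rise[::-1], np.zeros(_LEAD_SAMPLES)]
    else:
        rise = plateau * _smoothstep7(np.linspace(0.0, 1.0, _RAMP_MAX))
        k = int(np.sum(rise >= low))
        if 2 * k > n_hold:
            R = _RAMP_MIN
            rise = plateau * _smoothstep7(np.linspace(0.0, 1.0, R))
            k = int(np.sum(rise >= low))
        if 2 * k <= n_hold:
            parts = [
                np.zeros(_LEAD_SAMPLES),
                rise,
                np.full(n_hold - 2 * k, plateau),
                rise[::-1],
                np.zeros(_LEAD_SAMPLES),
            ]
        else:
            parts = _peek_bump(n_hold, low, geom)
    angle = np.concatenate(parts)

    if jerk_sd > 0:
        white = rng.normal(0.0, 1.0, angle.size)
        shaped = highpass_10hz(Trajectory(trial_id, white, fs))
        sd = shaped.std(ddof=1)
        if sd > 0:
            margin = max(0.7, 6.0 * jerk_sd)
            envelope = (np.abs(angle - low) >= margin).astype(float)
            angle = angle + shaped * (jerk_sd / sd) * envelope
    angle = np.clip(angle, 0.0, geom.range_max)
    return Trajectory(trial_id, angle, fs)


def _peek_bump(n_hold: int, low: float, geom: LeverGeometry) -> list[np.ndarray]:
    """Smooth bump with exactly ``n_hold`` samples at or above ``low``.

    The rise/fall shape is fixed (sigmoid, endpoint excluded); the bump
    amplitude is placed between the order-statistic thresholds that bracket
    ``n_hold // 2`` in-range samples per side, with the parity absorbed by
    an optional single peak sample.
    """
    s = _smoothstep7(np.linspace(0.0, 1.0, _BUMP_RAMP, endpoint=False))
    k = n_hold // 2
    center = n_hold - 2 * k  # 0 or 1 peak samples
    if k == 0:
        # single-sample peek: only the center sample touches the floor
        amp = low
    else:
        lo_thr = low / s[_BUMP_RAMP - k]
        hi_thr = low / s[_BUMP_RAMP - k - 1] if k < _BUMP_RAMP else np.inf
        amp = min((lo_thr + hi_thr) / 2.0, lo_thr * 1.05)
    if amp > min(20.0, geom.goal_high - 2.0):
        raise ValueError("hold too long for the peek-bump profile")
    rise = amp * s
    return [
        np.zeros(_LEAD_SAMPLES),
        rise,
        np.full(center, amp),
        rise[::-1],
        np.zeros(_LEAD_SAMPLES),
    ]


@dataclass
class _Bout:
    """Completed bout bookkeeping for the peer-influence coupling."""

    mouse_id: str
    t_start: float
    t_end: float
    n_trials: int
    n_success: int

    @property
    def sr(self) -> float:
        return self.n_success / self.n_trials if self.n_trials else 0.0


def _day_schedule(agent: AgentParams, day: int, prev_exit: float, rng: np.random.Generator):
    """Entry windows and within-bout trial times for one agent-day.

    Returns (entries, prev_exit) where each entry is
    (t_enter, [trial times], t_exit). Arrivals are Poisson at
    ``entry_rate``/h; an arrival during an ongoing visit is deferred to
    just after it (count-preserving, so daily entry counts stay Poisson).
    """
    day_start = day * 86400.0
    n = rng.poisson(agent.entry_rate * 24.0)
    arrivals = np.sort(rng.uniform(day_start, day_start + 86400.0, n))
    lo, hi = agent.trial_gap_range
    out = []
    for a in arrivals:
        t_enter = max(float(a), prev_exit + 1.0)
        size = int(rng.geometric(agent.bout_geom_p))
        first = t_enter + rng.uniform(2.0, 10.0)
        gaps = rng.uniform(lo, hi, size - 1)
        times = first + np.concatenate([[0.0], np.cumsum(gaps)])
        t_exit = float(times[-1] + rng.uniform(5.0, 20.0))
        out.append((t_enter, list(map(float, times)), t_exit))
        prev_exit = t_exit
    return out, prev_exit


def simulate_cage(cfg: SimConfig) -> SessionLog:
    """Run the closed loop for ``cfg.n_days`` and return a validated
    SessionLog. Fully deterministic under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    agents = {a.mouse_id: a for a in cfg.agents}
    states = {a.mouse_id: SchedulerState(a.mouse_id) for a in cfg.agents}
    last_bout: dict[str, _Bout | None] = {a.mouse_id: None for a in cfg.agents}
    all_bouts: list[_Bout] = []

    trials: list[TrialRecord] = []
    entries: list[EntryRecord] = []
    trajectories: dict[str, Trajectory] = {}
    trial_no = {a.mouse_id: 0 for a in cfg.agents}
    entry_no = {a.mouse_id: 0 for a in cfg.agents}
    prev_exit = {a.mouse_id: -np.inf for a in cfg.agents}
    # day summaries keyed by (mouse, day of trial start) for the nightly update
    summaries: dict[tuple[str, int], DaySummary] = {}

    for day in range(cfg.n_days):
        # fixed agent order keeps the draw stream reproducible
        day_entries = []
        for a in cfg.agents:
            sched, prev_exit[a.mouse_id] = _day_schedule(a, day, prev_exit[a.mouse_id], rng)
            for t_enter, times, t_exit in sched:
                day_entries.append((t_enter, a.mouse_id, times, t_exit))
        day_entries.sort(key=lambda e: (e[0], e[1]))

        for t_enter, mid, times, t_exit in day_entries:
            agent = agents[mid]
            state = states[mid]
            eid = f"{mid}-e{entry_no[mid]:05d}"
            entry_no[mid] += 1
            entries.append(EntryRecord(eid, mid, t_enter, t_exit))

            w_shift = 0.0
            if agent.influence_gain > 0:
                mine = last_bout[mid]
                if mine is not None:
                    for b in reversed(all_bouts):
                        if b.t_end < t_enter - 300.0:
                            break
                        if (
                            b.mouse_id != mid
                            and b.n_trials >= 10
                            and b.t_end - b.t_start <= 300.0
                            and b.t_end <= t_enter
                            and b.sr > mine.sr
                        ):
                            w_shift = agent.influence_gain
                            break

            n_succ = 0
            for t in times:
                d_t = int(np.floor(t / 86400.0))
                w_day = float(np.clip(agent.w_schedule(d_t) - w_shift, 0.0, 1.0))
                if rng.random() < w_day:
                    hold = min(rng.exponential(1.0 / agent.kappa_schedule(d_t)), MAX_HOLD_S)
                else:
                    mu = state.required_hold_time + agent.timed_margin
                    hold = rng.normal(mu, agent.sigma_t)
                    while hold < 0:
                        hold = rng.normal(mu, agent.sigma_t)
                    hold = min(hold, MAX_HOLD_S)
                tid = f"{mid}-{trial_no[mid]:06d}"
                trial_no[mid] += 1
                if cfg.store_trajectories:
                    traj = synth_trajectory(
                        hold, agent.jerk_sd, cfg.geometry, cfg.fs, rng, trial_id=tid
                    )
                    measured = compute_hold_time(traj, cfg.geometry)
                    trajectories[tid] = traj
                    ref = tid
                else:
                    measured = round(hold * cfg.fs) / cfg.fs
                    ref = None
                success, _cue = classify_trial(measured, state)
                n_succ += int(success)
                trials.append(
                    TrialRecord(
                        trial_id=tid,
                        mouse_id=mid,
                        entry_id=eid,
                        t_start=float(t),
                        stage=state.stage,
                        required_hold_time=state.required_hold_time,
                        hold_time=measured,
                        success=success,
                        trajectory_ref=ref,
                    )
                )
                key = (mid, d_t)
                if key not in summaries:
                    summaries[key] = DaySummary(mid, d_t)
                if state.stage == 2:
                    summaries[key].hold_times.append(measured)
                    summaries[key].n_success += int(success)
                else:
                    # stage-1 pulls count toward promotion, not the update
                    summaries[key].hold_times.append(measured)
            b = _Bout(mid, times[0], times[-1], len(times), n_succ)
            all_bouts.append(b)
            last_bout[mid] = b

        # midnight: promote / re-benchmark each mouse on the completed day
        for a in cfg.agents:
            state = states[a.mouse_id]
            day_sum = summaries.get((a.mouse_id, day), DaySummary(a.mouse_id, day))
            if state.stage == 1:
                states[a.mouse_id] = advance_stage(day_sum, state, cfg.min_trials)
            else:
                states[a.mouse_id] = update_required_hold_time(
                    day_sum, state, min_trials=cfg.min_trials, min_sr=cfg.min_sr
                )
            rewards = day_sum.n_success if state.stage == 2 else day_sum.n_trials
            states[a.mouse_id].water_deficit_drops = free_water_deficit(rewards)

    log = SessionLog(
        trials=sorted(trials, key=lambda t: (t.t_start, t.trial_id)),
        entries=sorted(entries, key=lambda e: (e.t_enter, e.entry_id)),
        trajectories=trajectories,
        cage_id=cfg.cage_id,
        genotypes={a.mouse_id: a.genotype_label for a in cfg.agents},
        day0=cfg.day0,
    )
    log.validate()
    return log
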