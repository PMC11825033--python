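"""Event-log data model for the home-cage lever-hold task.

A cage session is recorded as three interlinked streams: per-trial records
(one lever-pull attempt each), chamber entry/exit records delimited by RFID
reads, and per-trial lever-angle trajectories sampled at a fixed 400 Hz.
All timestamps are seconds since a per-session epoch (``day0`` in the
session metadata); calendar days are derived as ``floor(t / 86400)``,
0-based internally and reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialRecord",
    "Trajectory",
    "EntryRecord",
    "SessionLog",
    "ValidationError",
    "SECONDS_PER_DAY",
    "DEFAULT_FS",
]

SECONDS_PER_DAY = 86400.0
DEFAULT_FS = 400.0


class ValidationError(ValueError):
    """A session log violates one of the data-model invariants.

    Carries the offending record ids in ``offenders``.
    """

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = list(offenders or [])


@dataclass
class TrialRecord:
    """One lever-pull attempt.

    ``hold_time`` is the achieved duration (s) the lever stayed within the
    goal range; ``required_hold_time`` is the scheduler requirement in force
    when the trial ran (0 to 1 s). In stage 1 any registered pull is
    rewarded, so ``success`` is True regardless of hold time; in stage 2
    ``success == (hold_time >= required_hold_time)``.
    """

    trial_id: str
    mouse_id: str
    entry_id: str
    t_start: float
    stage: int
    required_hold_time: float
    hold_time: float
    success: bool
    trajectory_ref: str | None = None


@dataclass
class Trajectory:
    """Lever-angle time series for one trial, degrees in [0, 30] at 400 Hz."""

    trial_id: str
    angle: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.trial_id == other.trial_id
            and self.fs == other.fs
            and self.angle.shape == other.angle.shape
            and bool(np.array_equal(self.angle, other.angle))
        )


@dataclass
class EntryRecord:
    """One chamber visit by one mouse, delimited by RFID detection."""

    entry_id: str
    mouse_id: str
    t_enter: float
    t_exit: float


@dataclass
class SessionLog:
    """A full multi-animal cage session.

    ``genotypes`` maps each mouse id to its group label (e.g. ``"WT"`` /
    ``"HD"``); ``day0`` is an ISO date string naming the session epoch.
    """

    trials: list[TrialRecord] = field(default_factory=list)
    entries: list[EntryRecord] = field(default_factory=list)
    trajectories: dict[str, Trajectory] = field(default_factory=dict)
    cage_id: str = "cage0"
    genotypes: dict[str, str] = field(default_factory=dict)
    day0: str = "1970-01-01"

    # -- derived views ---------------------------------------------------

    def mouse_ids(self) -> list[str]:
        return sorted(self.genotypes)

    def trials_for(self, mouse_id: str) -> list[TrialRecord]:
        """Time-ordered trials of one mouse."""
        out = [t for t in self.trials if t.mouse_id == mouse_id]
        out.sort(key=lambda t: t.t_start)
        return out

    def entries_for(self, mouse_id: str) -> list[EntryRecord]:
        out = [e for e in self.entries if e.mouse_id == mouse_id]
        out.sort(key=lambda e: e.t_enter)
        return out

    def day_of(self, t: float) -> int:
        """0-based calendar day in cage for a session timestamp."""
        return int(np.floor(t / SECONDS_PER_DAY))

    def n_days(self) -> int:
        if not self.trials and not self.entries:
            return 0
        last = 0.0
        if self.trials:
            last = max(last, max(t.t_start for t in self.trials))
        if self.entries:
            last = max(last, max(e.t_exit for e in self.entries))
        return self.day_of(last) + 1

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check every data-model invariant; raise ValidationError listing
        offending record ids."""
        bad: list[str] = []
        entry_ids = {e.entry_id for e in self.entries}
        for tr in self.trials:
            if tr.entry_id not in entry_ids:
                bad.append(tr.entry_id)
            if tr.hold_time < 0 or not (0.0 <= tr.required_hold_time <= 1.0):
                bad.append(tr.trial_id)
            if tr.stage not in (1, 2):
                bad.append(tr.trial_id)
            elif tr.stage == 2 and tr.success != (tr.hold_time >= tr.required_hold_time):
                bad.append(tr.trial_id)
            elif tr.stage == 1 and not tr.success:
                bad.append(tr.trial_id)
            if tr.mouse_id not in self.genotypes:
                bad.append(tr.trial_id)
            if tr.trajectory_ref is not None and tr.trajectory_ref not in self.trajectories:
                bad.append(tr.trial_id)
        for e in self.entries:
            if not (e.t_exit > e.t_enter):
                bad.append(e.entry_id)
            if e.mouse_id not in self.genotypes:
                bad.append(e.entry_id)
        # strictly increasing trial times and non-overlapping entries per mouse
        for m in {t.mouse_id for t in self.trials}:
            ts = [t for t in self.trials if t.mouse_id == m]
            ts.sort(key=lambda t: t.t_start)
            for a, b in zip(ts, ts[1:]):
                if not (b.t_start > a.t_start):
                    bad.append(b.trial_id)
        for m in {e.mouse_id for e in self.entries}:
            es = [e for e in self.entries if e.mouse_id == m]
            es.sort(key=lambda e: e.t_enter)
            for a, b in zip(es, es[1:]):
                if b.t_enter < a.t_exit:
                    bad.append(b.entry_id)
        for tj in self.trajectories.values():
            if tj.fs != DEFAULT_FS or len(tj.angle) < 1:
                bad.append(tj.trial_id)
            elif np.any(tj.angle < 0) or np.any(tj.angle > 30):
                bad.append(tj.trial_id)
        if bad:
            uniq = sorted(set(bad))
            raise ValidationError(
                f"session log violates invariants; offending records: {uniq}", uniq
            )
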