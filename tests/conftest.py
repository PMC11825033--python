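import numpy as np
import pytest

from cagelever.datamodel import EntryRecord, SessionLog, Trajectory, TrialRecord
from cagelever.simulate import SimConfig, hd_like_agent, simulate_cage, wt_like_agent


@pytest.fixture(scope="session")
def small_sim_log():
    """3-day WT-like + HD-like cage with trajectories (shared, read-only)."""
    cfg = SimConfig(
        n_days=3,
        agents=[wt_like_agent("wt1", 3), hd_like_agent("hd1", 3)],
        seed=1,
    )
    return simulate_cage(cfg)


@pytest.fixture(scope="session")
def week_sim_log():
    """7-day two-agent cage without trajectories (fast, shared)."""
    cfg = SimConfig(
        n_days=7,
        agents=[wt_like_agent("wt1", 7), hd_like_agent("hd1", 7)],
        seed=7,
        store_trajectories=False,
    )
    return simulate_cage(cfg)


def make_trial(
    trial_id,
    mouse_id,
    t_start,
    *,
    entry_id=None,
    stage=2,
    required=0.0,
    hold=None,
    success=True,
    trajectory_ref=None,
):
    """Hand-built consistent TrialRecord (hold chosen to match success)."""
    if hold is None:
        hold = required + 0.1 if success else max(required - 0.1, 0.0)
    if stage == 2:
        success = hold >= required
    else:
        success = True
    return TrialRecord(
        trial_id=trial_id,
        mouse_id=mouse_id,
        entry_id=entry_id or f"{mouse_id}-e0",
        t_start=float(t_start),
        stage=stage,
        required_hold_time=required,
        hold_time=hold,
        success=success,
        trajectory_ref=trajectory_ref,
    )


def make_log(trials, genotypes, entries=None, trajectories=None):
    """SessionLog with auto-generated covering entries if none given."""
    if entries is None:
        entries = []
        for m in genotypes:
            ts = [t.t_start for t in trials if t.mouse_id == m]
            lo = min(ts) - 1.0 if ts else 0.0
            hi = max(ts) + 1.0 if ts else 1.0
            entries.append(EntryRecord(f"{m}-e0", m, lo, hi))
        eids = {e.entry_id for e in entries}
        assert all(t.entry_id in eids for t in trials)
    log = SessionLog(
        trials=sorted(trials, key=lambda t: t.t_start),
        entries=entries,
        trajectories=trajectories or {},
        genotypes=dict(genotypes),
    )
    log.validate()
    return log


def flat_trajectory(trial_id, plateau=15.0, n_hold=120, rng=None, noise=0.0):
    """Minimal valid pull: rest, sub-goal rise, plateau, return."""
    rise = np.linspace(0, 5.0, 20)
    angle = np.concatenate([np.zeros(4), rise, np.full(n_hold, plateau), rise[::-1], np.zeros(4)])
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        angle = np.clip(angle + rng.normal(0, noise, angle.size), 0, 30)
    return Trajectory(trial_id, angle)
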