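"""DTW, moving SD, and the event-aligned variability analyses."""

import itertools

import numpy as np
import pytest

from cagelever.datamodel import SessionLog, Trajectory
from cagelever.variability import (
    align_to_holdtime_change,
    bout_variability,
    consecutive_dtw,
    dtw_distance,
    find_window_bouts,
    moving_std_holdtimes,
    outcome_run_variability,
)

from conftest import flat_trajectory, make_log, make_trial


def dtw_oracle(a, b):
    """Exhaustive enumeration of all monotone warping paths (tiny inputs)."""
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = cost
            return
        if i + 1 < len(a):
            walk(i + 1, j, cost)
        if j + 1 < len(b):
            walk(i, j + 1, cost)
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def test_textbook_example(self):
        assert dtw_distance([0, 1, 2], [0, 2]) == 1.0

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(1, 30))
            b = rng.normal(size=rng.integers(1, 30))
            assert dtw_distance(a, a) == 0.0
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_matches_enumeration_oracle_sample(self):
        # spot check; the full length<=4 enumeration runs in the acceptance suite
        seqs = [s for n in (1, 2, 3) for s in itertools.product((0, 1, 2), repeat=n)]
        rng = np.random.default_rng(1)
        for _ in range(150):
            a = seqs[rng.integers(len(seqs))]
            b = seqs[rng.integers(len(seqs))]
            assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b))


class TestMovingStd:
    def test_constant_series_is_zero(self):
        raw = moving_std_holdtimes([0.3] * 10, zscore=False)
        assert np.allclose(raw, 0.0)

    def test_full_window_value(self):
        raw = moving_std_holdtimes([0.1, 0.2, 0.3, 0.4, 0.5], zscore=False)
        assert raw[2] == pytest.approx(np.std([0.1, 0.2, 0.3, 0.4, 0.5], ddof=1))
        assert raw[2] == pytest.approx(0.158113883)

    def test_locality(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        y = x[:7] + [9.9, 0.1, 5.0]  # permute values far from the first window
        r1 = moving_std_holdtimes(x, zscore=False)
        r2 = moving_std_holdtimes(y, zscore=False)
        assert r1[2] == r2[2]

    def test_zscore_identity(self):
        z, degenerate = moving_std_holdtimes([0.1, 0.5, 0.2, 0.9, 0.3, 0.7, 0.4])
        assert not degenerate
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z, ddof=1) == pytest.approx(1.0, abs=1e-9)


def _traj_log(noises, mouse="m1", spacing=30.0, successes=None, t0=0.0):
    """Log with one trial per noise level, equally spaced in time."""
    rng = np.random.default_rng(42)
    trials, trajs = [], {}
    for i, nz in enumerate(noises):
        tid = f"{mouse}-{i:03d}"
        trajs[tid] = flat_trajectory(tid, noise=nz, rng=rng)
        ok = True if successes is None else successes[i]
        trials.append(
            make_trial(tid, mouse, t0 + i * spacing, required=0.2,
                       hold=0.3 if ok else 0.1, trajectory_ref=tid)
        )
    return make_log(trials, {mouse: "WT"}, trajectories=trajs)


class TestConsecutiveDTW:
    def test_zscore_identity(self):
        log = _traj_log([0.05, 0.1, 0.2, 0.05, 0.3, 0.15])
        z, degenerate = consecutive_dtw(log, "m1")
        assert not degenerate
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_single_trial_gives_empty(self):
        log = _traj_log([0.1])
        z, _ = consecutive_dtw(log, "m1")
        assert z.size == 0

    def test_identical_trajectories_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        trials, trajs = [], {}
        base = flat_trajectory("base")
        for i in range(5):
            tid = f"m1-{i:03d}"
            trajs[tid] = Trajectory(tid, base.angle.copy())
            trials.append(make_trial(tid, "m1", i * 30.0, trajectory_ref=tid))
        log = make_log(trials, {"m1": "WT"}, trajectories=trajs)
        z, degenerate = consecutive_dtw(log, "m1")
        assert degenerate and np.all(np.isnan(z))

    def test_variability_step_change_detected(self):
        log = _traj_log([0.03] * 12 + [0.3] * 12)
        z, _ = consecutive_dtw(log, "m1")
        assert np.nanmean(z[12:]) > np.nanmean(z[:11])


class TestAlignToHoldtimeChange:
    def _log_with_jump(self):
        """20 low-requirement trials, then a requirement jump with lagged
        adaptation: successes become rare right after the change."""
        rng = np.random.default_rng(3)
        trials, trajs = [], {}
        for i in range(40):
            tid = f"m1-{i:03d}"
            req = 0.2 if i < 20 else 0.5
            # before the jump the mouse clears 0.2 easily; after it mostly fails
            if i < 20:
                hold = 0.3
            elif i < 30:
                hold = 0.3 + 0.25 * (rng.random() < 0.2)
            else:
                hold = 0.55
            trajs[tid] = flat_trajectory(tid, noise=0.05 + 0.1 * (i >= 20 and i < 30), rng=rng)
            trials.append(make_trial(tid, "m1", i * 40.0, required=req, hold=hold, trajectory_ref=tid))
        return make_log(trials, {"m1": "WT"}, trajectories=trajs)

    def test_every_series_has_twenty_positions(self):
        out = align_to_holdtime_change(self._log_with_jump(), "m1")
        assert out
        for s in out:
            assert len(s.positions) == 20
            assert s.positions == list(range(-5, 0)) + list(range(1, 16))

    def test_success_drops_after_requirement_increase(self):
        out = align_to_holdtime_change(self._log_with_jump(), "m1")
        succ = next(s for s in out if s.statistic_name == "success")
        before = np.mean(succ.values[:5])
        after = np.mean(succ.values[5:10])
        assert after < before

    def test_no_events_gives_empty(self):
        log = _traj_log([0.1] * 8)
        assert align_to_holdtime_change(log, "m1") == []


class TestWindowBouts:
    def test_nine_trials_in_window_is_no_bout(self):
        trials = [make_trial(f"m1-{i:03d}", "m1", i * 30.0) for i in range(9)]
        assert find_window_bouts(trials) == []

    def test_ten_trials_within_five_minutes_is_a_bout(self):
        trials = [make_trial(f"m1-{i:03d}", "m1", i * 30.0) for i in range(10)]
        bouts = find_window_bouts(trials)
        assert len(bouts) == 1 and len(bouts[0]) == 10

    def test_span_boundary_at_300s(self):
        ok = [make_trial(f"a-{i}", "a", i * (300.0 / 9)) for i in range(10)]
        too_slow = [make_trial(f"b-{i}", "b", i * (301.0 / 9)) for i in range(10)]
        assert len(find_window_bouts(ok)) == 1
        assert find_window_bouts(too_slow) == []

    def test_identical_trials_in_bout_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        trials, trajs = [], {}
        base = flat_trajectory("base")
        for i in range(10):
            tid = f"m1-{i:03d}"
            trajs[tid] = Trajectory(tid, base.angle.copy())
            trials.append(make_trial(tid, "m1", i * 20.0, trajectory_ref=tid))
        log = make_log(trials, {"m1": "WT"}, trajectories=trajs)
        series = bout_variability(log, "m1")
        assert series.degenerate

    def test_settling_agent_shows_declining_variability(self):
        # three bouts whose within-bout noise decays trial by trial
        rng = np.random.default_rng(5)
        trials, trajs = [], {}
        t = 0.0
        idx = 0
        for _ in range(3):
            for j in range(10):
                tid = f"m1-{idx:03d}"
                trajs[tid] = flat_trajectory(tid, noise=0.3 * (0.7**j) + 0.02, rng=rng)
                trials.append(make_trial(tid, "m1", t, trajectory_ref=tid))
                t += 20.0
                idx += 1
            t += 1200.0
        log = make_log(trials, {"m1": "WT"}, trajectories=trajs)
        series = bout_variability(log, "m1")
        vals = np.asarray(series.values, dtype=float)
        assert np.nanmean(vals[1:4]) > np.nanmean(vals[-3:])


class TestOutcomeRuns:
    def _run_log(self, spacing, successes):
        return _traj_log([0.1] * len(successes), spacing=spacing, successes=successes)

    def test_run_spanning_151s_excluded(self):
        # 5 trials spanning 151 s -> excluded; 150 s -> included
        log = self._run_log(151.0 / 4, [True] * 5)
        assert np.all(np.isnan(outcome_run_variability(log, "m1", True).values))
        log = self._run_log(150.0 / 4, [True] * 5)
        assert not np.all(np.isnan(outcome_run_variability(log, "m1", True).values))

    def test_alternating_outcomes_give_no_runs(self):
        log = self._run_log(10.0, [True, False] * 5)
        assert np.all(np.isnan(outcome_run_variability(log, "m1", True).values))
        assert np.all(np.isnan(outcome_run_variability(log, "m1", False).values))

    def test_success_contingent_noise_reduction_detected(self):
        # success runs get quieter trial by trial; failure runs stay flat
        rng = np.random.default_rng(9)
        trials, trajs = [], {}
        t, idx = 0.0, 0
        for block in range(6):
            ok = block % 2 == 0
            for j in range(5):
                tid = f"m1-{idx:03d}"
                nz = (0.4 - 0.08 * j if ok else 0.25) + 0.01
                trajs[tid] = flat_trajectory(tid, noise=nz, rng=rng)
                trials.append(
                    make_trial(tid, "m1", t, required=0.2, hold=0.3 if ok else 0.1,
                               trajectory_ref=tid)
                )
                t += 20.0
                idx += 1
            t += 400.0
        log = make_log(trials, {"m1": "WT"}, trajectories=trajs)
        succ = np.asarray(outcome_run_variability(log, "m1", True).values, float)
        fail = np.asarray(outcome_run_variability(log, "m1", False).values, float)
        assert succ[0] > succ[-1]
        assert abs(fail[0] - fail[-1]) < abs(succ[0] - succ[-1])
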