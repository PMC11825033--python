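"""Closed-loop cage simulator: draw distributions, trajectory synthesis,
and whole-run behavior."""

import numpy as np
import pytest
from scipy import stats

from cagelever.datamodel import Trajectory
from cagelever.io import save_session
from cagelever.kinematics import trial_jerkiness
from cagelever.simulate import (
    AgentParams,
    SimConfig,
    constant,
    hd_like_agent,
    linear_schedule,
    sample_hold_time,
    simulate_cage,
    synth_trajectory,
    wt_like_agent,
)
from cagelever.task import LeverGeometry, compute_hold_time


class TestSampleHoldTime:
    def test_pure_exponential_mean(self):
        p = AgentParams("m", w_schedule=constant(1.0), kappa_schedule=constant(4.0))
        rng = np.random.default_rng(0)
        x = np.array([sample_hold_time(p, 0, 0.0, rng) for _ in range(100_000)])
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 0.25) < 3 * se

    def test_pure_timed_mean(self):
        p = AgentParams("m", w_schedule=constant(0.0), timed_margin=0.05, sigma_t=0.1)
        rng = np.random.default_rng(0)
        x = np.array([sample_hold_time(p, 0, 0.5, rng) for _ in range(100_000)])
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 0.55) < 3 * se

    def test_draw_stream_reproducible(self):
        p = AgentParams("m", w_schedule=constant(0.5))
        a = [sample_hold_time(p, 0, 0.3, np.random.default_rng(9)) for _ in range(1)]
        xs = [
            [sample_hold_time(p, 0, 0.3, rng) for _ in range(100)]
            for rng in (np.random.default_rng(9), np.random.default_rng(9))
        ]
        assert xs[0] == xs[1]
        assert xs[0][0] == a[0]

    def test_clipped_at_five_seconds(self):
        p = AgentParams("m", w_schedule=constant(1.0), kappa_schedule=constant(0.2))
        rng = np.random.default_rng(3)
        x = [sample_hold_time(p, 0, 0.0, rng) for _ in range(2000)]
        assert max(x) <= 5.0


class TestSynthTrajectory:
    def test_noiseless_trajectory_has_negligible_jerkiness(self):
        t = synth_trajectory(0.5, 0.0, rng=np.random.default_rng(0))
        r = trial_jerkiness(t)
        assert not r.excluded and r.jerkiness <= 0.005

    def test_jerk_sd_is_recovered_by_the_pipeline(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            t = synth_trajectory(0.5, 0.1, rng=rng)
            vals.append(trial_jerkiness(t).jerkiness)
        assert abs(np.mean(vals) - 0.1) / 0.1 < 0.20

    def test_zero_hold_never_enters_goal_range(self):
        geom = LeverGeometry()
        t = synth_trajectory(0.0, 0.0, geom, rng=np.random.default_rng(2))
        assert not np.any((t.angle >= geom.goal_low) & (t.angle <= geom.goal_high))
        assert compute_hold_time(t, geom) == 0.0

    @pytest.mark.parametrize("hold", [0.0, 0.0025, 0.1, 0.517, 1.0, 4.99])
    def test_scored_hold_matches_requested(self, hold):
        rng = np.random.default_rng(5)
        t = synth_trajectory(hold, 0.08, rng=rng)
        assert abs(compute_hold_time(t) - hold) <= 1 / 400.0 + 1e-12


class TestSimulateCage:
    def test_wt_like_learning_raises_hold_times(self, monkeypatch):
        cfg = SimConfig(
            n_days=58,
            agents=[wt_like_agent("wt1")],
            seed=2,
            store_trajectories=False,
        )
        log = simulate_cage(cfg)
        per_day = {}
        for t in log.trials_for("wt1"):
            per_day.setdefault(log.day_of(t.t_start), []).append(t.hold_time)
        early = np.mean([h for d in range(8) for h in per_day.get(d, [])])
        late = np.mean([h for d in range(49, 58) for h in per_day.get(d, [])])
        assert late > early

    def test_hd_like_requirement_plateaus_below_cap(self):
        cfg = SimConfig(
            n_days=58, agents=[hd_like_agent("hd1")], seed=2, store_trajectories=False
        )
        log = simulate_cage(cfg)
        final_req = max(
            t.required_hold_time
            for t in log.trials_for("hd1")
            if log.day_of(t.t_start) >= 50
        )
        assert final_req < 1.0

    def test_zero_entry_agent_stays_stage_one(self):
        quiet = AgentParams("m0", entry_rate=0.0)
        cfg = SimConfig(n_days=3, agents=[quiet], seed=4, store_trajectories=False)
        log = simulate_cage(cfg)
        assert log.trials == []
        assert log.entries == []

    def test_determinism_identical_bytes(self, tmp_path):
        cfg = lambda: SimConfig(  # noqa: E731
            n_days=2,
            agents=[wt_like_agent("wt1", 2), hd_like_agent("hd1", 2)],
            seed=13,
        )
        a, b = tmp_path / "a", tmp_path / "b"
        save_session(simulate_cage(cfg()), str(a), trajectory_format="hdf5")
        save_session(simulate_cage(cfg()), str(b), trajectory_format="hdf5")
        for name in ("trials.csv", "entries.csv", "metadata.yaml"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_scheduler_trace_respects_cap_and_monotonicity(self, week_sim_log):
        log = week_sim_log
        for m in log.mouse_ids():
            reqs = {}
            for t in log.trials_for(m):
                reqs.setdefault(log.day_of(t.t_start), set()).add(t.required_hold_time)
            # requirement is constant within a day and capped
            assert all(len(v) == 1 for v in reqs.values())
            daily = [v.pop() for _, v in sorted(reqs.items())]
            assert all(0.0 <= r <= 1.0 for r in daily)
            # non-decreasing except at (rare) reset events back to a benchmark
            drops = [i for i in range(1, len(daily)) if daily[i] < daily[i - 1]]
            for i in drops:
                assert daily[i] in daily[: i - 1] + [0.0]

    def test_daily_holds_match_generating_mixture(self):
        # KS check of one stage-2 day against the generating mixture
        ag = AgentParams(
            "m1",
            w_schedule=constant(0.7),
            kappa_schedule=constant(4.0),
            timed_margin=0.05,
            sigma_t=0.1,
            entry_rate=4.0,
            bout_geom_p=0.15,
        )
        cfg = SimConfig(n_days=3, agents=[ag], seed=8, store_trajectories=False)
        log = simulate_cage(cfg)
        trials = [t for t in log.trials_for("m1") if t.stage == 2 and log.day_of(t.t_start) == 2]
        assert len(trials) >= 500
        req = trials[0].required_hold_time
        x = np.array([t.hold_time for t in trials])

        def cdf(v):
            v = np.asarray(v)
            expo = 1 - np.exp(-4.0 * np.clip(v, 0, None))
            mu, sd = req + 0.05, 0.1
            z0 = stats.norm.cdf(0, mu, sd)
            gauss = (stats.norm.cdf(v, mu, sd) - z0) / (1 - z0)
            return 0.7 * expo + 0.3 * np.clip(gauss, 0, 1)

        d = stats.kstest(x, cdf).statistic
        # sample-grid quantization (1/400 s) adds at most ~kappa/(2*400) to D
        assert d < 1.63 / np.sqrt(len(x)) + 0.01

    def test_influence_gain_shifts_w_downward(self):
        # with a high-success peer present, a positive influence gain makes
        # the follower's untimed weight (hence short-pull fraction) drop
        def cage(gain, seed):
            follower = AgentParams(
                "f1",
                w_schedule=constant(0.8),
                entry_rate=4.0,
                bout_geom_p=0.1,
                influence_gain=gain,
                trial_gap_range=(10.0, 25.0),
            )
            peer = AgentParams(
                "p1",
                w_schedule=constant(0.05),
                entry_rate=4.0,
                bout_geom_p=0.1,
                trial_gap_range=(10.0, 25.0),
            )
            cfg = SimConfig(n_days=6, agents=[follower, peer], seed=seed,
                            store_trajectories=False)
            log = simulate_cage(cfg)
            holds = [t.hold_time for t in log.trials_for("f1") if t.stage == 2]
            return np.mean([h < 0.15 for h in holds])  # short-pull fraction

        frac_null = np.mean([cage(0.0, s) for s in range(3)])
        frac_gain = np.mean([cage(0.5, s) for s in range(3)])
        assert frac_gain < frac_null
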