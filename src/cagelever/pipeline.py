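"""One-call orchestration of the full analysis battery on a session log.

``run_pipeline`` executes engagement, mixture fits, jerkiness, the three
variability analyses and the social-motif detection on a SessionLog (or a
session directory) and writes one CSV per analysis plus a JSON manifest
(config, seed, input fingerprint) so that re-runs on the same inputs are
byte-identical. ``demo`` simulates a WT-like / HD-like pair for 58 days
and analyzes it end to end.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .datamodel import SessionLog
from .engagement import daily_engagement, entry_bout_sizes
from .io import load_session
from .kinematics import daily_jerkiness
from .mixture import MIN_FIT_TRIALS, daily_fits
from .simulate import SimConfig, hd_like_agent, simulate_cage, wt_like_agent
from .social import find_controls, find_motifs, influence_summary
from .variability import (
    REPLICATION_DAYS,
    align_to_holdtime_change,
    bout_variability,
    outcome_run_variability,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo"]

_FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    """Analysis battery configuration; defaults are the task's stated
    parameters (58-day standardization, 10-trial/5-minute bouts, 5-trial
    windows, 75th-percentile scheduler)."""

    replication_mode: bool = True
    n_days: int = REPLICATION_DAYS
    min_fit_trials: int = MIN_FIT_TRIALS
    bout_min_trials: int = 10
    bout_window_s: float = 300.0
    motif_max_gap_s: float = 300.0
    control_gap_s: tuple[float, float] = (300.0, 900.0)
    run_engagement: bool = True
    run_mixture: bool = True
    run_jerkiness: bool = True
    run_variability: bool = True
    run_motifs: bool = True
    seed: int = 0
    out_dir: str = "pipeline_out"


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig, log: SessionLog | str) -> dict[str, str]:
    """Run the enabled analyses; returns {analysis: csv path}.

    ``log`` is a SessionLog or a session directory. Outputs are written
    under ``cfg.out_dir``; identical inputs and config reproduce identical
    bytes.
    """
    if isinstance(log, str):
        log = load_session(log)
    os.makedirs(cfg.out_dir, exist_ok=True)
    mice = log.mouse_ids()
    n_days = cfg.n_days if cfg.replication_mode else log.n_days()
    outputs: dict[str, str] = {}

    if cfg.run_engagement:
        rows = []
        for m in mice:
            for rec in daily_engagement(log, m, n_days=n_days):
                rows.append(vars(rec))
        hist_rows = []
        for m in mice:
            hist, sr = entry_bout_sizes(log, m, replication=cfg.replication_mode)
            for size, count in hist.items():
                hist_rows.append(
                    {"mouse_id": m, "bout_size": size, "count": count,
                     "success_rate": sr[size]}
                )
        path = os.path.join(cfg.out_dir, "engagement.csv")
        _write_csv(pd.DataFrame(rows), path)
        bpath = os.path.join(cfg.out_dir, "entry_bouts.csv")
        _write_csv(pd.DataFrame(hist_rows, columns=["mouse_id", "bout_size", "count", "success_rate"]), bpath)
        outputs["engagement"] = path
        outputs["entry_bouts"] = bpath

    if cfg.run_mixture:
        rows = []
        for m in mice:
            fits = daily_fits(log, m, days=range(n_days), min_fit_trials=cfg.min_fit_trials)
            for day, f in enumerate(fits):
                if f is None:
                    rows.append({"mouse_id": m, "day": day + 1, "w": float("nan"),
                                 "kappa": float("nan"), "mu": float("nan"),
                                 "sigma": float("nan"), "n": 0, "nll": float("nan"),
                                 "converged": 0})
                else:
                    rows.append({"mouse_id": m, "day": day + 1, "w": f.params.w,
                                 "kappa": f.params.kappa, "mu": f.params.mu,
                                 "sigma": f.params.sigma, "n": f.n_trials,
                                 "nll": f.nll, "converged": int(f.converged)})
        path = os.path.join(cfg.out_dir, "mixture_w.csv")
        cols = ["mouse_id", "day", "w", "kappa", "mu", "sigma", "n", "nll", "converged"]
        _write_csv(pd.DataFrame(rows, columns=cols), path)
        outputs["mixture"] = path

    if cfg.run_jerkiness and log.trajectories:
        rows = []
        for m in mice:
            series = daily_jerkiness(log, m, n_days=n_days)
            rows += [{"mouse_id": m, "day": d + 1, "mean_jerkiness": v} for d, v in enumerate(series)]
        path = os.path.join(cfg.out_dir, "jerkiness.csv")
        _write_csv(pd.DataFrame(rows, columns=["mouse_id", "day", "mean_jerkiness"]), path)
        outputs["jerkiness"] = path

    if cfg.run_variability and log.trajectories:
        rows = []
        for m in mice:
            for s in align_to_holdtime_change(log, m, replication=cfg.replication_mode):
                for p, v in zip(s.positions, s.values):
                    rows.append({"mouse_id": m, "analysis": "holdtime_change",
                                 "event_id": s.event_id, "statistic": s.statistic_name,
                                 "position": p, "value": v})
            s = bout_variability(log, m, cfg.bout_min_trials, cfg.bout_window_s,
                                 replication=cfg.replication_mode)
            for p, v in zip(s.positions, s.values):
                rows.append({"mouse_id": m, "analysis": "window_bout", "event_id": s.event_id,
                             "statistic": s.statistic_name, "position": p, "value": v})
            for outcome, name in ((True, "success_runs"), (False, "failure_runs")):
                s = outcome_run_variability(log, m, outcome, replication=cfg.replication_mode)
                for p, v in zip(s.positions, s.values):
                    rows.append({"mouse_id": m, "analysis": name, "event_id": s.event_id,
                                 "statistic": s.statistic_name, "position": p, "value": v})
        path = os.path.join(cfg.out_dir, "variability.csv")
        _write_csv(pd.DataFrame(rows, columns=["mouse_id", "analysis", "event_id", "statistic", "position", "value"]), path)
        outputs["variability"] = path

    if cfg.run_motifs:
        motifs = find_motifs(log, cfg.bout_min_trials, cfg.bout_window_s, cfg.motif_max_gap_s)
        controls = find_controls(log, cfg.bout_min_trials, *cfg.control_gap_s)
        rows = [
            {
                "follower_id": m.follower_id,
                "influencer_id": m.influencer_id,
                "t_start": m.bout1[0].t_start,
                "sr_baseline": m.sr_baseline,
                "sr_influencer": m.sr_influencer,
                "sr_after": m.sr_after,
                "influencer_class": m.influencer_class,
                "delta_success": m.delta_success,
            }
            for m in motifs
        ]
        path = os.path.join(cfg.out_dir, "motifs.csv")
        _write_csv(pd.DataFrame(rows, columns=["follower_id", "influencer_id", "t_start",
                                               "sr_baseline", "sr_influencer", "sr_after",
                                               "influencer_class", "delta_success"]), path)
        outputs["motifs"] = path
        crows = [
            {"mouse_id": c.mouse_id, "t_start": c.bout1[0].t_start,
             "sr_baseline": c.sr_baseline, "sr_after": c.sr_after,
             "delta_success": c.delta_success}
            for c in controls
        ]
        cpath = os.path.join(cfg.out_dir, "controls.csv")
        _write_csv(pd.DataFrame(crows, columns=["mouse_id", "t_start", "sr_baseline",
                                                "sr_after", "delta_success"]), cpath)
        outputs["controls"] = cpath
        spath = os.path.join(cfg.out_dir, "influence_summary.csv")
        _write_csv(influence_summary(motifs, controls, log.genotypes), spath)
        outputs["influence_summary"] = spath

    fingerprint = hashlib.sha256()
    for t in log.trials:
        fingerprint.update(f"{t.trial_id},{t.t_start},{t.hold_time},{t.success}".encode())
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "input_sha256": fingerprint.hexdigest(),
        "n_trials": len(log.trials),
        "n_mice": len(mice),
        "outputs": sorted(os.path.basename(p) for p in outputs.values()),
    }
    mpath = os.path.join(cfg.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = mpath
    return outputs


def demo(seed: int = 11, out_dir: str = "demo_out", n_days: int = REPLICATION_DAYS,
         store_trajectories: bool = True) -> tuple[SessionLog, dict[str, str]]:
    """Simulate a WT-like + HD-like pair for ``n_days`` and run the full
    battery on the result. Returns the log and the output paths."""
    sim = SimConfig(
        n_days=n_days,
        agents=[wt_like_agent("wt1", n_days), hd_like_agent("hd1", n_days)],
        seed=seed,
        store_trajectories=store_trajectories,
    )
    log = simulate_cage(sim)
    cfg = PipelineConfig(seed=seed, out_dir=out_dir, n_days=n_days)
    outputs = run_pipeline(cfg, log)
    return log, outputs
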