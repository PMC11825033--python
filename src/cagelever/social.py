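"""Follower-influencer motifs and matched solitary controls.

A motif is a three-bout sequence on the cage's merged, time-sorted trial
stream: the *follower* performs a bout of at least 10 trials within a
5-minute window (baseline), the *influencer* -- a different mouse --
performs a comparable bout starting within 5 minutes of the baseline's
end, and the follower returns for a third bout within 5 minutes of the
influencer's. The influencer is classed *good* if its bout's success rate
exceeds the follower's baseline, else *bad*. The effect statistic is the
relative change in the follower's success rate,

    delta = (SR_after - SR_baseline) / SR_baseline.

Controls are two qualifying bouts by the same mouse separated by a 5-15
minute gap with no intervening >=10-trial bout by any other mouse,
capturing intrinsic bout-to-bout fluctuation without a peer.

Events with a zero baseline success rate are excluded from mean deltas
(the relative change is undefined) and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import SessionLog, TrialRecord
from .variability import find_window_bouts

__all__ = ["MotifEvent", "ControlEvent", "find_motifs", "find_controls", "influence_summary"]


@dataclass
class MotifEvent:
    follower_id: str
    influencer_id: str
    bout1: list[TrialRecord]
    bout2: list[TrialRecord]
    bout3: list[TrialRecord]
    sr_baseline: float
    sr_influencer: float
    sr_after: float
    influencer_class: str  # "good" | "bad"

    @property
    def delta_success(self) -> float:
        if self.sr_baseline == 0:
            return float("nan")
        return (self.sr_after - self.sr_baseline) / self.sr_baseline


@dataclass
class ControlEvent:
    mouse_id: str
    bout1: list[TrialRecord]
    bout2: list[TrialRecord]
    sr_baseline: float
    sr_after: float

    @property
    def delta_success(self) -> float:
        if self.sr_baseline == 0:
            return float("nan")
        return (self.sr_after - self.sr_baseline) / self.sr_baseline


def _bout_sr(bout: list[TrialRecord], first_n: int | None) -> float:
    ts = bout[:first_n] if first_n else bout
    return sum(t.success for t in ts) / len(ts)


def _mouse_bouts(log: SessionLog, min_trials: int, window_s: float):
    return {
        m: find_window_bouts(log.trials_for(m), min_trials, window_s)
        for m in log.mouse_ids()
    }


def find_motifs(
    log: SessionLog,
    min_trials: int = 10,
    bout_window_s: float = 300.0,
    max_gap_s: float = 300.0,
    sr_first_n: int | None = 10,
) -> list[MotifEvent]:
    """Detect follower-influencer motifs for every ordered mouse pair.

    Bouts are window bouts (>= ``min_trials`` within ``bout_window_s``);
    consecutive bouts must satisfy gap (next start - previous end)
    <= ``max_gap_s``. Candidates are consumed greedily in time order
    without reusing a bout across motifs of the same ordered pair. Bout
    success rates use the first ``sr_first_n`` trials (None = full run).
    """
    bouts = _mouse_bouts(log, min_trials, bout_window_s)
    motifs: list[MotifEvent] = []
    for follower in log.mouse_ids():
        for influencer in log.mouse_ids():
            if influencer == follower:
                continue
            fb = bouts[follower]
            ib = bouts[influencer]
            used_f: set[int] = set()
            used_i: set[int] = set()
            for i1, b1 in enumerate(fb):
                if i1 in used_f:
                    continue
                end1 = b1[-1].t_start
                j = next(
                    (
                        k
                        for k, b2 in enumerate(ib)
                        if k not in used_i
                        and b2[0].t_start >= end1
                        and b2[0].t_start - end1 <= max_gap_s
                    ),
                    None,
                )
                if j is None:
                    continue
                b2 = ib[j]
                end2 = b2[-1].t_start
                k = next(
                    (
                        kk
                        for kk, b3 in enumerate(fb)
                        if kk > i1
                        and kk not in used_f
                        and b3[0].t_start >= end2
                        and b3[0].t_start - end2 <= max_gap_s
                    ),
                    None,
                )
                if k is None:
                    continue
                b3 = fb[k]
                sr1 = _bout_sr(b1, sr_first_n)
                sr2 = _bout_sr(b2, sr_first_n)
                sr3 = _bout_sr(b3, sr_first_n)
                motifs.append(
                    MotifEvent(
                        follower_id=follower,
                        influencer_id=influencer,
                        bout1=b1,
                        bout2=b2,
                        bout3=b3,
                        sr_baseline=sr1,
                        sr_influencer=sr2,
                        sr_after=sr3,
                        influencer_class="good" if sr2 > sr1 else "bad",
                    )
                )
                used_f.update((i1, k))
                used_i.add(j)
    motifs.sort(key=lambda m: (m.bout1[0].t_start, m.follower_id, m.influencer_id))
    return motifs


def find_controls(
    log: SessionLog,
    min_trials: int = 10,
    gap_min_s: float = 300.0,
    gap_max_s: float = 900.0,
    sr_first_n: int | None = 10,
) -> list[ControlEvent]:
    """Solitary two-bout controls: per mouse, pairs of consecutive window
    bouts whose gap lies in [gap_min_s, gap_max_s] with no other mouse
    starting a qualifying bout inside the gap."""
    bouts = _mouse_bouts(log, min_trials, 300.0)
    controls: list[ControlEvent] = []
    for m in log.mouse_ids():
        mb = bouts[m]
        others = [b for om, obs in bouts.items() if om != m for b in obs]
        for b1, b2 in zip(mb, mb[1:]):
            gap_lo = b1[-1].t_start
            gap = b2[0].t_start - gap_lo
            if not (gap_min_s <= gap <= gap_max_s):
                continue
            if any(gap_lo <= ob[0].t_start <= b2[0].t_start for ob in others):
                continue
            controls.append(
                ControlEvent(
                    mouse_id=m,
                    bout1=b1,
                    bout2=b2,
                    sr_baseline=_bout_sr(b1, sr_first_n),
                    sr_after=_bout_sr(b2, sr_first_n),
                )
            )
    controls.sort(key=lambda c: (c.bout1[0].t_start, c.mouse_id))
    return controls


def influence_summary(
    motifs: list[MotifEvent],
    controls: list[ControlEvent],
    genotypes: dict[str, str],
) -> pd.DataFrame:
    """Mean/SEM of delta_success by follower genotype x influencer class,
    plus the control condition per genotype.

    Zero-baseline events (undefined relative change) are excluded from the
    means and counted in ``n_zero_baseline``.
    """
    rows = []
    groups: dict[tuple[str, str], list[float]] = {}
    zeros: dict[tuple[str, str], int] = {}
    for mt in motifs:
        key = (genotypes.get(mt.follower_id, "?"), mt.influencer_class)
        if mt.sr_baseline == 0:
            zeros[key] = zeros.get(key, 0) + 1
        else:
            groups.setdefault(key, []).append(mt.delta_success)
    for c in controls:
        key = (genotypes.get(c.mouse_id, "?"), "control")
        if c.sr_baseline == 0:
            zeros[key] = zeros.get(key, 0) + 1
        else:
            groups.setdefault(key, []).append(c.delta_success)
    for key in sorted(set(groups) | set(zeros)):
        vals = np.asarray(groups.get(key, []), dtype=float)
        rows.append(
            {
                "genotype": key[0],
                "condition": key[1],
                "n": vals.size,
                "mean_delta": float(vals.mean()) if vals.size else float("nan"),
                "sem_delta": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else float("nan"),
                "n_zero_baseline": zeros.get(key, 0),
            }
        )
    return pd.DataFrame(rows, columns=["genotype", "condition", "n", "mean_delta", "sem_delta", "n_zero_baseline"])
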