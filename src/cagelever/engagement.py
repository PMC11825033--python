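"""Daily engagement metrics and entry-bout-size analyses.

Engagement is summarized per calendar day in cage: trial and entry counts,
mean time in chamber per entrance, trials per entry and daily success
rate. An *entry bout* is the sequence of consecutive trials initiated
within one chamber entry (distinct from the 10-trials-in-5-minutes
*window bout* used by the variability analyses); bout sizes follow an
approximately exponential distribution, with success rate rising with
bout size. In replication mode daily metrics are standardized to the
first 58 days in cage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import SessionLog
from .variability import REPLICATION_DAYS

__all__ = ["EngagementDay", "daily_engagement", "entry_bout_sizes"]


@dataclass
class EngagementDay:
    mouse_id: str
    day: int  # 1-based reporting convention
    n_trials: int
    n_entries: int
    mean_time_in_chamber_s: float  # NaN on days without entries
    trials_per_entry: float  # NaN on days without entries
    success_rate: float  # NaN on days without trials


def daily_engagement(
    log: SessionLog, mouse_id: str, n_days: int | None = None, replication: bool = True
) -> list[EngagementDay]:
    """One engagement record per day (1-based days 1..58 in replication
    mode, else the log's span)."""
    if n_days is None:
        n_days = REPLICATION_DAYS if replication else log.n_days()
    trials = log.trials_for(mouse_id)
    entries = log.entries_for(mouse_id)

    out = []
    for d in range(n_days):
        dt = [t for t in trials if log.day_of(t.t_start) == d]
        de = [e for e in entries if log.day_of(e.t_enter) == d]
        n_entries = len(de)
        durations = [e.t_exit - e.t_enter for e in de]
        out.append(
            EngagementDay(
                mouse_id=mouse_id,
                day=d + 1,
                n_trials=len(dt),
                n_entries=n_entries,
                mean_time_in_chamber_s=float(np.mean(durations)) if de else float("nan"),
                trials_per_entry=len(dt) / n_entries if n_entries else float("nan"),
                success_rate=(sum(t.success for t in dt) / len(dt)) if dt else float("nan"),
            )
        )
    return out


def entry_bout_sizes(
    log: SessionLog, mouse_id: str, size_cap: int = 14, replication: bool = False
) -> tuple[dict[int, int], dict[int, float]]:
    """Histogram of entry-bout sizes and per-size mean success rate.

    A bout is the trials of one chamber entry (entries with no trials are
    not bouts). Sizes above ``size_cap`` are binned at ``size_cap``.
    Returns ``(histogram, success_by_size)`` keyed by (possibly capped)
    bout size.
    """
    trials = log.trials_for(mouse_id)
    if replication:
        trials = [t for t in trials if log.day_of(t.t_start) < REPLICATION_DAYS]
    by_entry: dict[str, list] = {}
    for t in trials:
        by_entry.setdefault(t.entry_id, []).append(t)

    hist: dict[int, int] = {}
    succ: dict[int, list[float]] = {}
    for ts in by_entry.values():
        size = min(len(ts), size_cap)
        hist[size] = hist.get(size, 0) + 1
        succ.setdefault(size, []).extend(float(t.success) for t in ts)
    success_by_size = {k: float(np.mean(v)) for k, v in sorted(succ.items())}
    return dict(sorted(hist.items())), success_by_size
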