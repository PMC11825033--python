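"""Trial-to-trial variability measures and event-aligned analyses.

Two complementary variability measures are used. Dynamic time warping
(DTW) between the lever trajectories of temporally adjacent trials
quantifies how dissimilar successive movements are, tolerating differences
in trial length; the moving standard deviation of hold times (window of 5
trials) quantifies timing variability. Both are z-scored per mouse over
the trials entering a given analysis, since raw values scale with trial
duration.

Three event-aligned analyses are built on these measures:

* requirement changes — the 5 trials before and 15 after each upward
  change in required hold time (success, DTW z, moving-SD z per offset);
* window bouts — the first 10 trials of bouts of >=10 trials within a
  5-minute window (DTW z per within-bout position);
* outcome runs — runs of 5 consecutive all-success or all-failure trials
  spanning <=150 s (DTW z for the 4 consecutive pairs).

DTW here is the classic unconstrained dynamic program with unit steps
(match / insert / delete) and absolute difference as the local cost. Note
DTW is not a metric (it violates the triangle inequality), so only
symmetry and identity are relied on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import SessionLog, TrialRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "AlignedSeries",
    "dtw_distance",
    "consecutive_dtw",
    "moving_std_holdtimes",
    "align_to_holdtime_change",
    "bout_variability",
    "outcome_run_variability",
    "find_window_bouts",
    "REPLICATION_DAYS",
]

REPLICATION_DAYS = 58


@dataclass
class AlignedSeries:
    """A per-offset statistic aligned to one event (or averaged over
    events): ``positions[i]`` is the trial offset and ``values[i]`` the
    statistic there (NaN where undefined)."""

    event_id: str
    mouse_id: str
    statistic_name: str
    positions: list[int]
    values: list[float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")


def _dtw_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.size, b.size
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            cur[j] = c + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return float(prev[m])


if _HAVE_NUMBA:

    @njit(cache=False)
    def _dtw_nb(a, b):  # pragma: no cover - numba-compiled
        n = a.size
        m = b.size
        prev = np.full(m + 1, np.inf)
        prev[0] = 0.0
        cur = np.empty(m + 1)
        for i in range(1, n + 1):
            cur[0] = np.inf
            for j in range(1, m + 1):
                c = abs(a[i - 1] - b[j - 1])
                best = prev[j]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                cur[j] = c + best
            prev, cur = cur, prev
        return prev[m]


def dtw_distance(a, b) -> float:
    """Minimal cumulative |a_i - b_j| over all monotone warping paths
    (unit match/insert/delete steps, no window constraint)."""
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    if _HAVE_NUMBA:
        return float(_dtw_nb(a, b))
    return _dtw_py(a, b)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """z-score ignoring NaN; flags the degenerate zero-spread case."""
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        return np.full_like(x, np.nan), True
    sd = finite.std(ddof=1)
    if sd == 0:
        return np.full_like(x, np.nan), True
    return (x - finite.mean()) / sd, False


def consecutive_dtw(
    log: SessionLog, mouse_id: str, trial_set: list[TrialRecord] | None = None
) -> tuple[np.ndarray, bool]:
    """DTW distances between each pair of consecutive trajectories of a
    mouse, z-scored over the analyzed set.

    Returns ``(z, degenerate)`` with ``z[i]`` the z-scored distance for the
    pair ``(i, i+1)``; pairs missing a trajectory are NaN. Fewer than two
    trials give an empty series.
    """
    if trial_set is None:
        trial_set = log.trials_for(mouse_id)
    if len(trial_set) < 2:
        return np.array([]), False
    raw = np.full(len(trial_set) - 1, np.nan)
    for i, (a, b) in enumerate(zip(trial_set, trial_set[1:])):
        if a.trajectory_ref is None or b.trajectory_ref is None:
            continue
        raw[i] = dtw_distance(
            log.trajectories[a.trajectory_ref].angle, log.trajectories[b.trajectory_ref].angle
        )
    return _zscore(raw)


def moving_std_holdtimes(hold_times, window: int = 5, zscore: bool = True):
    """Centered moving SD (n-1) of an ordered hold-time list; edge windows
    are truncated. z-scored over the series unless ``zscore=False``."""
    x = np.asarray(hold_times, dtype=float)
    if x.size == 0:
        return (np.array([]), False) if zscore else np.array([])
    half = window // 2
    raw = np.empty(x.size)
    for i in range(x.size):
        seg = x[max(0, i - half): i + half + 1]
        raw[i] = seg.std(ddof=1) if seg.size > 1 else 0.0
    if not zscore:
        return raw
    return _zscore(raw)


# ---------------------------------------------------------------------------
# event-aligned analyses


def _restrict_days(trials: list[TrialRecord], log: SessionLog, replication: bool):
    if not replication:
        return trials
    return [t for t in trials if log.day_of(t.t_start) < REPLICATION_DAYS]


def align_to_holdtime_change(
    log: SessionLog,
    mouse_id: str,
    n_before: int = 5,
    n_after: int = 15,
    replication: bool = True,
) -> list[AlignedSeries]:
    """Per-event aligned series around each upward change in the required
    hold time.

    For every increase, the ``n_before`` trials preceding and ``n_after``
    following the change (by trial index, crossing chamber entries) yield
    three series per event: success (0/1), consecutive-DTW z and
    moving-SD-of-hold-times z at offsets -5..-1, 1..15. DTW and moving-SD
    values are z-scored per mouse across all of that mouse's event windows.
    Mice that never left their initial requirement yield an empty list.
    """
    trials = _restrict_days(log.trials_for(mouse_id), log, replication)
    stage2 = [t for t in trials if t.stage == 2]
    events = [
        i
        for i in range(1, len(stage2))
        if stage2[i].required_hold_time > stage2[i - 1].required_hold_time
    ]
    positions = list(range(-n_before, 0)) + list(range(1, n_after + 1))
    out: list[AlignedSeries] = []

    windows = []
    for k, i in enumerate(events):
        if i < n_before or i + n_after > len(stage2):
            continue
        windows.append((k, stage2[i - n_before: i + n_after]))
    if not windows:
        return out

    # raw measures per window, then z-scores pooled across windows per mouse
    dtw_raw, mov_raw = [], []
    for _, wtr in windows:
        raw = np.full(len(wtr) - 1, np.nan)
        for i, (a, b) in enumerate(zip(wtr, wtr[1:])):
            if a.trajectory_ref is not None and b.trajectory_ref is not None:
                raw[i] = dtw_distance(
                    log.trajectories[a.trajectory_ref].angle,
                    log.trajectories[b.trajectory_ref].angle,
                )
        dtw_raw.append(raw)
        mov_raw.append(moving_std_holdtimes([t.hold_time for t in wtr], zscore=False))
    dtw_z, dtw_deg = _zscore(np.concatenate(dtw_raw))
    mov_z, mov_deg = _zscore(np.concatenate(mov_raw))
    dtw_z = dtw_z.reshape(len(windows), -1)
    mov_z = mov_z.reshape(len(windows), -1)

    for row, (k, wtr) in enumerate(windows):
        ev = f"{mouse_id}-change{k:03d}"
        succ = [float(t.success) for t in wtr]
        out.append(AlignedSeries(ev, mouse_id, "success", positions, succ))
        # pair (i-1, i) is assigned to the later trial's offset
        dvals = [np.nan] + list(dtw_z[row])
        out.append(AlignedSeries(ev, mouse_id, "dtw_z", positions, dvals, dtw_deg))
        out.append(AlignedSeries(ev, mouse_id, "movstd_z", positions, list(mov_z[row]), mov_deg))
    return out


def find_window_bouts(
    trials: list[TrialRecord], min_trials: int = 10, window_s: float = 300.0
) -> list[list[TrialRecord]]:
    """Greedy left-to-right detection of 'window bouts': maximal runs in
    which every trailing ``min_trials`` trials span <= ``window_s``.

    A bout starts at the first trial t such that trials t..t+min_trials-1
    span the window; it extends while each added trial keeps the trailing
    ``min_trials``-trial span within the window; candidates are consumed
    greedily without overlap.
    """
    bouts: list[list[TrialRecord]] = []
    i = 0
    n = len(trials)
    while i + min_trials <= n:
        if trials[i + min_trials - 1].t_start - trials[i].t_start <= window_s:
            j = i + min_trials
            while (
                j < n
                and trials[j].t_start - trials[j - min_trials + 1].t_start <= window_s
            ):
                j += 1
            bouts.append(trials[i:j])
            i = j
        else:
            i += 1
    return bouts


def bout_variability(
    log: SessionLog,
    mouse_id: str,
    min_trials: int = 10,
    window_s: float = 300.0,
    replication: bool = True,
) -> AlignedSeries:
    """Mean consecutive-DTW z over the first 10 trials of each window bout.

    Positions are within-bout trial indices 1..10; the pair (i-1, i) is
    assigned to position i, so position 1 is NaN. z-scoring pools all
    analyzed pairs of the mouse.
    """
    trials = _restrict_days(log.trials_for(mouse_id), log, replication)
    bouts = [b[:min_trials] for b in find_window_bouts(trials, min_trials, window_s)]
    positions = list(range(1, min_trials + 1))
    if not bouts:
        return AlignedSeries("window-bouts", mouse_id, "dtw_z", positions,
                             [np.nan] * min_trials)
    raw = np.full((len(bouts), min_trials - 1), np.nan)
    for r, b in enumerate(bouts):
        for i, (x, y) in enumerate(zip(b, b[1:])):
            if x.trajectory_ref is not None and y.trajectory_ref is not None:
                raw[r, i] = dtw_distance(
                    log.trajectories[x.trajectory_ref].angle,
                    log.trajectories[y.trajectory_ref].angle,
                )
    z, degenerate = _zscore(raw.ravel())
    z = z.reshape(raw.shape)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(z, axis=0)
    return AlignedSeries(
        "window-bouts", mouse_id, "dtw_z", positions, [np.nan] + list(means), degenerate
    )


def outcome_run_variability(
    log: SessionLog,
    mouse_id: str,
    outcome: bool,
    run_length: int = 5,
    span_s: float = 150.0,
    replication: bool = True,
) -> AlignedSeries:
    """Mean consecutive-DTW z across runs of ``run_length`` same-outcome
    trials whose first-to-last span is <= ``span_s``.

    Runs longer than ``run_length`` contribute only their first
    ``run_length``-trial window (non-overlapping). Positions 1..4 index the
    consecutive pairs of the run.
    """
    trials = _restrict_days(log.trials_for(mouse_id), log, replication)
    runs: list[list[TrialRecord]] = []
    i = 0
    n = len(trials)
    while i < n:
        if trials[i].success != outcome:
            i += 1
            continue
        j = i
        while j < n and trials[j].success == outcome:
            j += 1
        # maximal same-outcome run trials[i:j]; take leading window only
        if j - i >= run_length:
            cand = trials[i: i + run_length]
            if cand[-1].t_start - cand[0].t_start <= span_s:
                runs.append(cand)
        i = j
    positions = list(range(1, run_length))
    if not runs:
        return AlignedSeries("outcome-runs", mouse_id, "dtw_z", positions,
                             [np.nan] * (run_length - 1))
    raw = np.full((len(runs), run_length - 1), np.nan)
    for r, b in enumerate(runs):
        for i, (x, y) in enumerate(zip(b, b[1:])):
            if x.trajectory_ref is not None and y.trajectory_ref is not None:
                raw[r, i] = dtw_distance(
                    log.trajectories[x.trajectory_ref].angle,
                    log.trajectories[y.trajectory_ref].angle,
                )
    z, degenerate = _zscore(raw.ravel())
    z = z.reshape(raw.shape)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(z, axis=0)
    return AlignedSeries("outcome-runs", mouse_id, "dtw_z", positions, list(means), degenerate)
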