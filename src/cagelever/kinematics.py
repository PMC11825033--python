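"""Movement jerkiness from high-pass-filtered lever trajectories.

Jerkiness of a trial is the standard deviation of the >10 Hz component of
its lever-angle trace: a high-pass filter isolates rapid fluctuations (the
classic tremor-quantification approach), and their SD measures how rough
the pull was. Trials shorter than 20 samples (0.05 s at 400 Hz) are
excluded as non-representative.

The filter is a minimum-order elliptic high-pass (10 Hz cutoff, >=60 dB
stopband attenuation at and below 5 Hz, 0.1 dB passband ripple) applied
zero-phase. The default applies it forward-backward (``scipy.signal.filtfilt``),
which cancels phase exactly; a single forward pass of a linear-phase FIR
with its group delay removed is available as ``mode="fir"``. Jerkiness is
an SD, which is phase-insensitive, so the two modes agree to within the
attenuation bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .datamodel import SessionLog, Trajectory

__all__ = [
    "JerkinessResult",
    "highpass_10hz",
    "trial_jerkiness",
    "daily_jerkiness",
    "MIN_SAMPLES",
]

MIN_SAMPLES = 20

CUTOFF_HZ = 10.0
STOP_HZ = 5.0
STOP_DB = 60.0
PASS_DB = 0.1


@dataclass
class JerkinessResult:
    trial_id: str
    jerkiness: float | None
    excluded: bool = False
    reason: str | None = None


@lru_cache(maxsize=8)
def _iir(fs: float):
    order, wn = signal.ellipord(CUTOFF_HZ, STOP_HZ, PASS_DB, STOP_DB, fs=fs)
    return signal.ellip(order, PASS_DB, STOP_DB, wn, btype="highpass", output="sos", fs=fs)


@lru_cache(maxsize=8)
def _fir(fs: float):
    # Kaiser design: stopband edge 5 Hz, passband edge 15 Hz, 60 dB
    width = 2 * (CUTOFF_HZ - STOP_HZ)
    ntaps, beta = signal.kaiserord(STOP_DB, width / (fs / 2))
    ntaps |= 1  # odd length -> integer group delay, exact linear phase
    return signal.firwin(ntaps, CUTOFF_HZ, window=("kaiser", beta), pass_zero=False, fs=fs)


def highpass_10hz(traj: Trajectory, mode: str = "filtfilt") -> np.ndarray:
    """Zero-phase >10 Hz component of a trajectory; output length = input
    length. Raises ValueError below 2 samples (callers treat short trials
    via :func:`trial_jerkiness` exclusion instead)."""
    x = np.asarray(traj.angle, dtype=float)
    if x.size < 2:
        raise ValueError("trajectory too short to filter")
    x = x - x.mean()  # exact DC rejection; the filter stopband handles the rest
    if mode == "filtfilt":
        sos = _iir(traj.fs)
        padlen = min(x.size - 1, 200)
        return signal.sosfiltfilt(sos, x, padlen=padlen)
    if mode == "fir":
        taps = _fir(traj.fs)
        half = len(taps) // 2
        # odd reflection keeps the extension slope-continuous at the edges
        left = 2 * x[0] - x[min(half, x.size - 1):0:-1]
        right = 2 * x[-1] - x[-2:-2 - min(half, x.size - 1):-1]
        xp = np.concatenate([np.full(half - left.size, x[0]), left, x, right,
                             np.full(half - right.size, x[-1])])
        return np.convolve(xp, taps, mode="valid")
    raise ValueError(f"unknown filter mode: {mode!r}")


def trial_jerkiness(traj: Trajectory, mode: str = "filtfilt") -> JerkinessResult:
    """SD (n-1 denominator) of the high-pass-filtered trace, or an
    exclusion for trials under 20 samples."""
    n = len(traj.angle)
    if n < MIN_SAMPLES:
        return JerkinessResult(traj.trial_id, None, excluded=True, reason=f"{n} samples < {MIN_SAMPLES}")
    y = highpass_10hz(traj, mode=mode)
    return JerkinessResult(traj.trial_id, float(np.std(y, ddof=1)))


def daily_jerkiness(
    log: SessionLog, mouse_id: str, n_days: int | None = None, mode: str = "filtfilt"
) -> "np.ndarray":
    """Per-day mean jerkiness over non-excluded trials of one mouse.

    Returns an array of length ``n_days`` (defaults to the log's span)
    indexed by 0-based day; days with no scorable trials are NaN.
    """
    if n_days is None:
        n_days = log.n_days()
    sums = np.zeros(n_days)
    counts = np.zeros(n_days, dtype=int)
    for t in log.trials_for(mouse_id):
        if t.trajectory_ref is None:
            continue
        day = log.day_of(t.t_start)
        if day >= n_days:
            continue
        res = trial_jerkiness(log.trajectories[t.trajectory_ref], mode=mode)
        if not res.excluded:
            sums[day] += res.jerkiness
            counts[day] += 1
    out = np.full(n_days, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out
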