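"""Two-process generative model of hold-time distributions.

Daily hold-time distributions in this task are bimodal: a mass of brief,
seemingly impulsive pulls near zero, and (in animals that learn the timing
requirement) a second mode near the required duration. The model treats
each hold time as drawn from a mixture of two behavioral processes:

    p(x) = w * Exponential(x; kappa) + (1 - w) * Normal(x; mu, sigma^2)

where ``w`` is the weight of the exponential ("untimed") component,
``kappa`` its rate (1/s), and ``mu``/``sigma^2`` the mean and variance of
the Gaussian ("timed") component. The daily trajectory of the fitted ``w``
indexes the shift from exploratory to deliberate responding: it declines
with learning and stays high when timing control fails to develop.

Fitting is maximum likelihood by derivative-free simplex (Nelder-Mead)
search over transformed parameters (logit w, log kappa, mu, log sigma),
multi-started from a small grid of initializations. The Gaussian component
is left untruncated, as in the model definition; for fitted regimes
(mu >= 3 sigma) its mass below zero is negligible and is reported as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .datamodel import SessionLog
from .task import MAX_HOLD_S

__all__ = ["MixtureParams", "DailyFit", "mixture_pdf", "mixture_nll", "fit_day", "w_trajectory"]

MIN_FIT_TRIALS = 30
_DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class MixtureParams:
    """Parameters (w, kappa, mu, sigma2) of the two-process model."""

    w: float
    kappa: float
    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0 and self.kappa > 0 and self.sigma2 > 0):
            raise ValueError("mixture parameters out of range")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def gaussian_mass_below_zero(self) -> float:
        """Diagnostic: probability mass of the (untruncated) timed component
        below 0 s."""
        return float(stats.norm.cdf(0.0, self.mu, self.sigma))


@dataclass
class DailyFit:
    mouse_id: str
    day_index: int
    params: MixtureParams
    n_trials: int
    nll: float
    converged: bool
    n_censored: int = 0  # trials at the 5 s truncation ceiling, excluded


def mixture_pdf(params: MixtureParams, x: np.ndarray) -> np.ndarray:
    """Mixture density w*Exp(kappa) + (1-w)*N(mu, sigma2); the exponential
    component has support x >= 0."""
    x = np.asarray(x, dtype=float)
    expo = np.where(x >= 0, params.kappa * np.exp(-params.kappa * np.clip(x, 0, None)), 0.0)
    sigma = params.sigma
    z = (x - params.mu) / sigma
    gauss = np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))
    return params.w * expo + (1.0 - params.w) * gauss


def mixture_nll(params: MixtureParams, x) -> float:
    """Negative log-likelihood of hold times under the mixture; densities
    are floored at a tiny positive constant against underflow. Empty data
    gives 0."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    dens = np.maximum(mixture_pdf(params, x), _DENSITY_FLOOR)
    return float(-np.sum(np.log(dens)))


def _unpack(theta: np.ndarray) -> MixtureParams:
    w = float(np.clip(expit(theta[0]), 1e-9, 1 - 1e-9))
    kappa = float(np.exp(np.clip(theta[1], -20, 20)))
    mu = float(theta[2])
    sigma = float(np.exp(np.clip(theta[3], -20, 20)))
    return MixtureParams(w, kappa, mu, sigma * sigma)


def _pack(p: MixtureParams) -> np.ndarray:
    return np.array([logit(np.clip(p.w, 1e-6, 1 - 1e-6)), np.log(p.kappa), p.mu, np.log(p.sigma)])


def _default_starts(x: np.ndarray) -> list[MixtureParams]:
    mean = float(np.mean(x)) or 0.1
    kappa0 = 1.0 / max(mean, 1e-3)
    slow = x[x > 0.2]
    mu0 = float(np.median(slow)) if slow.size else max(mean, 0.3)
    sigma0 = max(float(np.std(slow)) if slow.size > 5 else 0.1, 0.02)
    starts = [MixtureParams(w, kappa0, mu0, sigma0**2) for w in (0.2, 0.5, 0.8)]
    starts.append(MixtureParams(0.5, 2.0 * kappa0, mu0, sigma0**2))
    starts.append(MixtureParams(0.9, kappa0, max(mean, 0.3), 0.01))
    return starts


def fit_day(
    x,
    init: MixtureParams | None = None,
    min_fit_trials: int = MIN_FIT_TRIALS,
    mouse_id: str = "",
    day_index: int = 0,
) -> DailyFit:
    """Maximum-likelihood fit of the two-process model to one day's hold
    times.

    Runs Nelder-Mead from five initializations (or the provided ``init``
    plus the defaults) and keeps the best; refuses days with fewer than
    ``min_fit_trials`` usable trials. Trials at the 5 s hold ceiling are
    censored out and counted in the diagnostics.
    """
    x = np.asarray(x, dtype=float)
    n_censored = int(np.sum(x >= MAX_HOLD_S))
    x = x[x < MAX_HOLD_S]
    if x.size < min_fit_trials:
        raise ValueError(
            f"need at least {min_fit_trials} trials to fit the mixture, got {x.size}"
        )

    starts = _default_starts(x)
    if init is not None:
        starts.insert(0, init)

    best: optimize.OptimizeResult | None = None
    converged = False
    for s in starts:
        res = optimize.minimize(
            lambda th: mixture_nll(_unpack(th), x),
            _pack(s),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    params = _unpack(best.x)
    return DailyFit(
        mouse_id=mouse_id,
        day_index=day_index,
        params=params,
        n_trials=int(x.size),
        nll=float(best.fun),
        converged=converged,
        n_censored=n_censored,
    )


def daily_fits(
    log: SessionLog,
    mouse_id: str,
    days: range | None = None,
    min_fit_trials: int = MIN_FIT_TRIALS,
    pool_days: int = 1,
) -> list[DailyFit | None]:
    """Per-day mixture fits of one mouse's stage-2 hold times.

    Returns one entry per day of the requested 0-based range (the log's
    span by default); days below the minimum trial count yield None.
    ``pool_days > 1`` fits a trailing window of that many days (e.g. 3 to
    pool days 1-3 the way example fits are sometimes shown).
    """
    if mouse_id not in log.genotypes:
        raise KeyError(f"unknown mouse: {mouse_id!r}")
    if days is None:
        days = range(log.n_days())
    per_day: dict[int, list[float]] = {}
    for t in log.trials_for(mouse_id):
        if t.stage == 2:
            per_day.setdefault(log.day_of(t.t_start), []).append(t.hold_time)

    out: list[DailyFit | None] = []
    for d in days:
        xs: list[float] = []
        for dd in range(d - pool_days + 1, d + 1):
            xs.extend(per_day.get(dd, []))
        if len(xs) < min_fit_trials:
            out.append(None)
            continue
        out.append(fit_day(xs, min_fit_trials=min_fit_trials, mouse_id=mouse_id, day_index=d))
    return out


def w_trajectory(
    log: SessionLog,
    mouse_id: str,
    days: range | None = None,
    min_fit_trials: int = MIN_FIT_TRIALS,
    pool_days: int = 1,
) -> list[tuple[int, float]]:
    """Per-day fitted exponential weight (NaN where no fit); the w column
    of :func:`daily_fits`."""
    if days is None:
        days = range(log.n_days())
    fits = daily_fits(log, mouse_id, days, min_fit_trials, pool_days)
    return [
        (d, f.params.w if f is not None else float("nan"))
        for d, f in zip(days, fits)
    ]
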