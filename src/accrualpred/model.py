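"""Bayesian constant-accrual model: conjugate posterior and closed-form predictives.

The model treats the waiting times between successive enrollments as i.i.d.
exponential with mean ``theta`` (time units per subject).  The prior on
``theta`` is inverse gamma, ``IG(n*P, T*P)``, where ``(n, T)`` is the study
design (target sample size, planned accrual duration) and ``P`` in (0, 1] is
the investigator's confidence that the plan is achievable: the prior carries
the information of ``n*P`` pseudo-subjects enrolled over ``T*P`` pseudo-time.

Two posterior predictive distributions are available in closed form:

* the number of additional subjects recruitable in the remaining window is
  negative binomial ``NB(r, p)`` with ``r = n*P + m`` and
  ``p = (T*P + Tm)/(T*P + T)``;
* the remaining time to recruit ``k`` more subjects is a scaled beta prime
  ("inverse beta"): ``T_rem / (T_rem + s) ~ Beta(k, r)`` with
  ``s = T*P + Tm``.

Each predictive has an exact path, a moment-matched normal approximation,
and a two-stage Monte-Carlo path (draw ``theta`` from the posterior, then
the Poisson count or gamma time given ``theta``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudyDesign",
    "AccrualObservation",
    "PosteriorState",
    "CountPrediction",
    "TimePrediction",
    "ApproximationValidityWarning",
    "WindowExceededError",
    "update_posterior",
    "predictive_count_params",
    "count_interval_exact",
    "count_interval_normal",
    "time_prediction",
    "time_interval_exact",
    "time_interval_normal",
    "completion_probability",
    "on_time_probability",
    "sample_predictive",
]


class ApproximationValidityWarning(UserWarning):
    """Normal approximation used outside its recommended validity region."""


class WindowExceededError(ValueError):
    """Elapsed time Tm exceeds the planning window T.

    The fixed-window count predictive is undefined once the window is
    exhausted; extend T or switch to the time-to-target predictive.
    """


@dataclass(frozen=True)
class StudyDesign:
    """The planning triple (n, T, P).

    Parameters
    ----------
    n : int
        Target sample size, ``n >= 1``.
    T : float
        Planned accrual duration, in caller-chosen time units (``T > 0``).
        The unit must be used consistently for every quantity in an analysis.
    P : float
        Prior confidence on a 0-1 scale, ``0 < P <= 1``.  ``P = 0`` is
        rejected: it would make the prior improper and degenerate every
        downstream closed form.  ``P = 0.1`` is a reasonable starting value
        when no better judgement is available; ``P = 0.5`` encodes strong
        confidence in the plan.
    """

    n: int
    T: float
    P: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"target sample size n must be an integer >= 1, got {self.n!r}")
        if not self.T > 0:
            raise ValueError(f"planned duration T must be > 0, got {self.T!r}")
        if not 0 < self.P <= 1:
            raise ValueError(f"prior confidence P must be in (0, 1], got {self.P!r}")

    @property
    def prior(self) -> "PosteriorState":
        """Prior state IG(nP, TP)."""
        return PosteriorState(r=self.n * self.P, s=self.T * self.P)

    @property
    def planned_rate(self) -> float:
        """Planned enrollment rate n/T (subjects per time unit)."""
        return self.n / self.T


@dataclass(frozen=True)
class AccrualObservation:
    """Observed enrollment record.

    Parameters
    ----------
    enrollment_times : tuple of float
        Ordered offsets ``t_1 <= ... <= t_m`` from trial start.  Ties
        (same-day enrollments) are permitted.
    Tm : float
        Elapsed observation time, ``Tm >= t_m``.  By default this is the
        review time, which may exceed the last enrollment time (the censored
        gap since the last enrollment still carries likelihood information
        under the Poisson-process model).  Use :meth:`at_last_enrollment`
        for the strict convention ``Tm = sum(w_i)``.
    """

    enrollment_times: tuple[float, ...]
    Tm: float

    def __init__(self, enrollment_times: Sequence[float] = (), Tm: float | None = None):
        times = tuple(float(t) for t in enrollment_times)
        if any(t < 0 for t in times):
            raise ValueError("enrollment times must be non-negative")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("enrollment times must be sorted non-decreasingly")
        last = times[-1] if times else 0.0
        if Tm is None:
            Tm = last
        Tm = float(Tm)
        if Tm < last:
            raise ValueError(f"Tm={Tm} precedes the last enrollment at t={last}")
        if Tm < 0:
            raise ValueError("Tm must be non-negative")
        object.__setattr__(self, "enrollment_times", times)
        object.__setattr__(self, "Tm", Tm)

    @classmethod
    def at_last_enrollment(cls, enrollment_times: Sequence[float]) -> "AccrualObservation":
        """Observation clocked at the m-th enrollment, so ``Tm = sum(w_i)``."""
        return cls(enrollment_times)

    @classmethod
    def empty(cls, Tm: float = 0.0) -> "AccrualObservation":
        return cls((), Tm)

    @property
    def m(self) -> int:
        """Number of subjects enrolled so far."""
        return len(self.enrollment_times)

    @property
    def waiting_times(self) -> np.ndarray:
        """Gaps ``w_i = t_i - t_{i-1}`` with ``t_0 = 0``."""
        return np.diff(np.concatenate(([0.0], self.enrollment_times)))


@dataclass(frozen=True)
class PosteriorState:
    """Inverse-gamma parameters (shape ``r``, scale ``s``) for theta."""

    r: float
    s: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"inverse-gamma shape r must be > 0, got {self.r}")
        if not self.s > 0:
            raise ValueError(f"inverse-gamma scale s must be > 0, got {self.s}")

    @property
    def distribution(self) -> stats.distributions.rv_frozen:
        """The IG(r, s) distribution of the mean waiting time theta."""
        return stats.invgamma(self.r, scale=self.s)

    @property
    def theta_mean(self) -> float:
        """Posterior mean of theta, s/(r-1); requires r > 1."""
        if self.r <= 1:
            raise ValueError("posterior mean of theta requires shape r > 1")
        return self.s / (self.r - 1)

    def theta_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval for theta."""
        a = (1.0 - level) / 2.0
        d = self.distribution
        return float(d.ppf(a)), float(d.ppf(1.0 - a))


@dataclass(frozen=True)
class CountPrediction:
    """Negative-binomial predictive NB(r, p) for the remaining count.

    ``eta``, the number of additional subjects recruitable in the remaining
    window ``horizon_T - Tm``, is NB(r, p) with
    ``p = (T*P + Tm)/(T*P + horizon_T)``.  ``p = 1`` iff the window is
    exhausted.  The predictive mean of ``eta`` is ``r(1-p)/p``.
    """

    r: float
    p: float
    horizon_T: float
    m: int = 0
    Tm: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("NB size r must be > 0")
        if not 0 < self.p <= 1:
            raise ValueError(f"NB probability p must be in (0, 1], got {self.p}")

    @property
    def mean_remaining(self) -> float:
        return self.r * (1.0 - self.p) / self.p

    @property
    def var_remaining(self) -> float:
        return self.r * (1.0 - self.p) / self.p**2

    @property
    def mean_total(self) -> float:
        return self.m + self.mean_remaining

    def prob_at_least(self, k: int) -> float:
        """P(eta >= k): probability of recruiting at least k more in the window."""
        if k <= 0:
            return 1.0
        if self.p == 1.0:
            return 0.0
        return float(stats.nbinom.sf(k - 1, self.r, self.p))


@dataclass(frozen=True)
class TimePrediction:
    """Scaled beta-prime predictive for the time to recruit ``k`` more subjects.

    The remaining time satisfies ``T_rem/(T_rem + s) ~ Beta(k, r)``;
    equivalently ``T_rem = s * X`` with ``X ~ BetaPrime(k, r)``.  The total
    accrual time is ``Tm + T_rem``; ``k = 0`` makes it ``Tm`` with certainty.
    """

    k: int
    r: float
    s: float
    Tm: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("remaining count k must be >= 0")
        if not (self.r > 0 and self.s > 0):
            raise ValueError("posterior parameters r, s must be > 0")

    @property
    def mean_total(self) -> float:
        """Mean total time Tm + s*k/(r-1); requires r > 1 (or k = 0)."""
        if self.k == 0:
            return self.Tm
        if self.r <= 1:
            return math.inf
        return self.Tm + self.s * self.k / (self.r - 1)

    @property
    def var_remaining(self) -> float:
        """Variance of the remaining time; finite only for r > 2."""
        if self.k == 0:
            return 0.0
        if self.r <= 2:
            return math.inf
        return self.s**2 * self.k * (self.k + self.r - 1) / ((self.r - 1) ** 2 * (self.r - 2))

    def cdf_total(self, t: float) -> float:
        """P(total accrual time <= t)."""
        if self.k == 0:
            return 1.0 if t >= self.Tm else 0.0
        rem = t - self.Tm
        if rem <= 0:
            return 0.0
        x = rem / (rem + self.s)
        return float(stats.beta.cdf(x, self.k, self.r))

    def ppf_total(self, q: float) -> float:
        """Quantile of the total accrual time."""
        if self.k == 0:
            return self.Tm
        x = float(stats.beta.ppf(q, self.k, self.r))
        if x >= 1.0:
            return math.inf
        return self.Tm + self.s * x / (1.0 - x)


def update_posterior(design: StudyDesign, obs: AccrualObservation) -> PosteriorState:
    """Conjugate update: IG(nP, TP) prior + (m, Tm) data -> IG(nP+m, TP+Tm).

    With no data (m = 0, Tm = 0) the prior is returned unchanged.  The update
    depends on the data only through the sufficient statistic (m, Tm), so it
    is additive: two incremental updates equal one pooled update.
    """
    r = design.n * design.P + obs.m
    s = design.T * design.P + obs.Tm
    assert r > 0 and s > 0, "posterior parameters must be positive"
    return PosteriorState(r=r, s=s)


def predictive_count_params(design: StudyDesign, obs: AccrualObservation) -> CountPrediction:
    """NB(r, p) parameters for the count recruitable by the planned horizon T.

    Raises
    ------
    WindowExceededError
        If ``Tm > T``: the planning window is already exhausted, so the
        fixed-window count question is vacuous — extend T or ask the
        time-to-target question instead.
    """
    if obs.Tm > design.T:
        raise WindowExceededError(
            f"elapsed time Tm={obs.Tm} exceeds the planning window T={design.T}; "
            "extend T or use the time-to-target prediction"
        )
    state = update_posterior(design, obs)
    p = (design.T * design.P + obs.Tm) / (design.T * design.P + design.T)
    return CountPrediction(r=state.r, p=p, horizon_T=design.T, m=obs.m, Tm=obs.Tm)


def _check_level(level: float) -> tuple[float, float]:
    if not 0 < level < 1:
        raise ValueError(f"coverage level must be in (0, 1), got {level}")
    a = (1.0 - level) / 2.0
    return a, 1.0 - a


def count_interval_exact(cp: CountPrediction, level: float = 0.95) -> tuple[int, int]:
    """Equal-tailed credible interval for the TOTAL count recruited by T.

    Endpoints are ``m`` plus the discrete NB quantiles (smallest integer
    whose CDF reaches the tail mass).  With ``p = 1`` the window is
    exhausted and the interval collapses to ``(m, m)``.
    """
    lo_q, hi_q = _check_level(level)
    if cp.p >= 1.0:
        return cp.m, cp.m
    lo = int(stats.nbinom.ppf(lo_q, cp.r, cp.p))
    hi = int(stats.nbinom.ppf(hi_q, cp.r, cp.p))
    return cp.m + lo, cp.m + hi


def count_interval_normal(
    cp: CountPrediction,
    level: float = 0.95,
    *,
    r_min: float = 30.0,
    p_range: tuple[float, float] = (0.1, 0.9),
) -> tuple[int, int]:
    """Moment-matched normal approximation to :func:`count_interval_exact`.

    Uses a normal with the NB mean ``m + r(1-p)/p`` and variance
    ``r(1-p)/p**2``, rounded outward to integers and truncated below at
    ``m``.  The approximation is reliable when ``r`` is large and ``p`` is
    neither too small nor too large; outside ``r >= r_min`` and
    ``p_range`` an :class:`ApproximationValidityWarning` is emitted.
    """
    lo_q, hi_q = _check_level(level)
    if cp.p >= 1.0:
        return cp.m, cp.m
    if cp.r < r_min or not (p_range[0] <= cp.p <= p_range[1]):
        warnings.warn(
            f"normal approximation may be inaccurate: r={cp.r:.3g}, p={cp.p:.3g} "
            f"outside the recommended region r >= {r_min}, p in {p_range}",
            ApproximationValidityWarning,
            stacklevel=2,
        )
    mean = cp.mean_total
    sd = math.sqrt(cp.var_remaining)
    lo = max(cp.m, math.floor(mean + stats.norm.ppf(lo_q) * sd))
    hi = math.ceil(mean + stats.norm.ppf(hi_q) * sd)
    return int(lo), int(max(lo, hi))


def time_prediction(design: StudyDesign, obs: AccrualObservation) -> TimePrediction:
    """Predictive for the total time to reach the target sample size n."""
    state = update_posterior(design, obs)
    k = max(design.n - obs.m, 0)
    return TimePrediction(k=k, r=state.r, s=state.s, Tm=obs.Tm)


def time_interval_exact(tp: TimePrediction, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval for the total accrual time.

    The Beta(k, r) quantile ``x`` maps to the total time
    ``Tm + s*x/(1 - x)``.  ``k = 0`` returns ``(Tm, Tm)``.
    """
    lo_q, hi_q = _check_level(level)
    if tp.k == 0:
        return tp.Tm, tp.Tm
    return tp.ppf_total(lo_q), tp.ppf_total(hi_q)


def time_interval_normal(tp: TimePrediction, level: float = 0.95) -> tuple[float, float]:
    """Moment-matched normal approximation to :func:`time_interval_exact`.

    Normal with mean ``Tm + s*k/(r-1)`` and the scaled beta-prime variance
    ``s**2 * k(k+r-1) / ((r-1)**2 (r-2))``, truncated below at ``Tm``.

    Raises
    ------
    ValueError
        If ``r <= 2`` (the beta-prime variance is undefined); use the exact
        or Monte-Carlo path instead.
    """
    lo_q, hi_q = _check_level(level)
    if tp.k == 0:
        return tp.Tm, tp.Tm
    if tp.r <= 2:
        raise ValueError(
            f"normal approximation requires shape r > 2 (got r={tp.r}); "
            "the predictive variance is infinite — use the exact or MC path"
        )
    mean = tp.mean_total
    sd = math.sqrt(tp.var_remaining)
    lo = max(tp.Tm, mean + stats.norm.ppf(lo_q) * sd)
    hi = max(lo, mean + stats.norm.ppf(hi_q) * sd)
    return float(lo), float(hi)


def completion_probability(design: StudyDesign, obs: AccrualObservation) -> float:
    """P(at least n - m further subjects are recruited by the horizon T)."""
    cp = predictive_count_params(design, obs)
    return cp.prob_at_least(design.n - obs.m)


def on_time_probability(design: StudyDesign, obs: AccrualObservation) -> float:
    """P(total time to reach n is at most T), via the inverse-beta predictive.

    Identical to :func:`completion_probability` — 'recruit the remaining
    k = n - m subjects within the window' and 'total accrual time <= T'
    describe the same event; both reduce to the regularized incomplete beta
    function ``I_{1-p}(k, r)``.
    """
    tp = time_prediction(design, obs)
    return tp.cdf_total(design.T)


def sample_predictive(
    state: PosteriorState,
    mode: Literal["count", "time"],
    *,
    window: float | None = None,
    k: int | None = None,
    n_draws: int = 200_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Two-stage Monte-Carlo draws from either posterior predictive.

    Stage one draws ``theta`` from the inverse-gamma posterior; stage two
    draws, per ``theta``, either the Poisson count of arrivals in ``window``
    time units (``mode='count'``) or the gamma-distributed remaining time to
    ``k`` further arrivals (``mode='time'``).

    Parameters
    ----------
    state : PosteriorState
    mode : {'count', 'time'}
    window : float, required in count mode
        Remaining window length (time units).
    k : int, required in time mode
        Remaining subjects to recruit; ``k = 0`` yields all-zero draws.
    n_draws : int
    seed : int, Generator or None
        Passing the same integer seed reproduces the draws bit-for-bit.

    Returns
    -------
    numpy.ndarray
        ``n_draws`` i.i.d. draws of the remaining count (integers) or the
        remaining time (floats).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "count":
        if window is None:
            raise ValueError("count mode requires window=")
        if window < 0:
            raise ValueError("window must be >= 0")
        theta = stats.invgamma.rvs(state.r, scale=state.s, size=n_draws, random_state=rng)
        return rng.poisson(window / theta)
    if mode == "time":
        if k is None:
            raise ValueError("time mode requires k=")
        if k == 0:
            return np.zeros(n_draws)
        theta = stats.invgamma.rvs(state.r, scale=state.s, size=n_draws, random_state=rng)
        return rng.gamma(shape=k, scale=theta)
    raise ValueError(f"unknown mode {mode!r}; expected 'count' or 'time'")
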