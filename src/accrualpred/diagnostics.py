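"""Accrual diagnostics: projection bands and waiting-time distribution checks.

All functions here return plain numeric series; rendering is a thin optional
layer (:func:`plot_projection`, :func:`plot_diagnostics`) so that tests and
downstream code work with numbers, not images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    AccrualObservation,
    CountPrediction,
    PosteriorState,
    StudyDesign,
    count_interval_exact,
    update_posterior,
)

__all__ = [
    "ProjectionBand",
    "WaitingTimeDiagnostics",
    "projection_band",
    "retrospective_band",
    "expected_line",
    "waiting_time_diagnostics",
    "plot_projection",
    "plot_diagnostics",
]


@dataclass(frozen=True)
class ProjectionBand:
    """Credible tunnel for cumulative accrual across a grid of future times.

    ``lower <= median <= upper`` elementwise; every series is non-decreasing
    in time, and at ``t = Tm`` the band collapses to the observed count m.
    """

    eval_times: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        for name in ("eval_times", "lower", "median", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.eval_times) == len(self.lower) == len(self.median) == len(self.upper)):
            raise ValueError("band series must have equal length")

    def at(self, t: float) -> tuple[float, float, float]:
        """(lower, median, upper) at grid time t (must be a grid point)."""
        idx = np.flatnonzero(np.isclose(self.eval_times, t))
        if idx.size == 0:
            raise ValueError(f"t={t} is not on the evaluation grid")
        i = int(idx[0])
        return float(self.lower[i]), float(self.median[i]), float(self.upper[i])

    def scaled(self, factor: float) -> "ProjectionBand":
        """Band multiplied by a positive factor (e.g. 1/J for per-site shares)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ProjectionBand(
            self.eval_times, self.lower * factor, self.median * factor,
            self.upper * factor, self.level,
        )


@dataclass(frozen=True)
class WaitingTimeDiagnostics:
    """Series behind the diagnostic panel: ECDF vs fitted exponential CDF.

    ``fitted_rate`` is 1 over the posterior mean of theta (``s/(r-1)``);
    ``ecdf_points``/``fitted_cdf_points`` are evaluated at the sorted
    waiting times; ``cumulative_trajectory`` is the (t_i, i) step series.
    """

    waiting_times: np.ndarray
    fitted_rate: float
    ecdf_points: np.ndarray       # (sorted w, ECDF at w)
    fitted_cdf_points: np.ndarray  # (sorted w, exponential CDF at w)
    cumulative_trajectory: np.ndarray  # (t_i, i)

    @property
    def ks_distance(self) -> float:
        """sup |ECDF - fitted exponential CDF| over the observed support."""
        w = self.ecdf_points[:, 0]
        ecdf_hi = self.ecdf_points[:, 1]
        ecdf_lo = ecdf_hi - 1.0 / len(w)
        fit = self.fitted_cdf_points[:, 1]
        return float(np.max(np.maximum(np.abs(ecdf_hi - fit), np.abs(ecdf_lo - fit))))


def projection_band(
    design: StudyDesign,
    obs: AccrualObservation,
    eval_times: np.ndarray,
    level: float = 0.95,
) -> ProjectionBand:
    """Project cumulative accrual forward from the current state.

    At each grid time ``t >= Tm`` the remaining count over the window
    ``(Tm, t]`` is NB(r, p_t) with ``p_t = (T*P + Tm)/(T*P + t)``; the band
    holds the equal-tailed interval and median of ``m`` plus that count.
    At ``t = Tm`` the band is exactly ``(m, m, m)``.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if eval_times.size == 0:
        raise ValueError("evaluation grid must be non-empty")
    if np.any(eval_times < obs.Tm):
        raise ValueError("evaluation times must be at or after the elapsed time Tm")
    state = update_posterior(design, obs)
    TP = design.T * design.P
    lower, median, upper = [], [], []
    for t in eval_times:
        p_t = (TP + obs.Tm) / (TP + t)
        cp = CountPrediction(r=state.r, p=min(p_t, 1.0), horizon_T=t, m=obs.m, Tm=obs.Tm)
        lo, hi = count_interval_exact(cp, level)
        med = obs.m + (0 if cp.p >= 1.0 else int(stats.nbinom.ppf(0.5, cp.r, cp.p)))
        lower.append(lo)
        median.append(med)
        upper.append(hi)
    return ProjectionBand(eval_times, np.array(lower), np.array(median), np.array(upper), level)


def retrospective_band(
    state: PosteriorState,
    eval_times: np.ndarray,
    level: float = 0.95,
) -> ProjectionBand:
    """Cumulative accrual re-projected from trial start under a fitted posterior.

    For each grid time ``t > 0`` the count of arrivals in a fresh window of
    length ``t`` is NB(r, s/(s+t)) under the posterior IG(r, s) for theta.
    Unlike :func:`projection_band` the observed count is not conditioned on,
    so the band is non-degenerate at the review time itself — this is the
    tunnel a multi-site review compares each site's trajectory against.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if eval_times.size == 0:
        raise ValueError("evaluation grid must be non-empty")
    if np.any(eval_times < 0):
        raise ValueError("evaluation times must be non-negative")
    a = (1.0 - level) / 2.0
    lower, median, upper = [], [], []
    for t in eval_times:
        if t == 0:
            lower.append(0.0)
            median.append(0.0)
            upper.append(0.0)
            continue
        p_t = state.s / (state.s + t)
        lower.append(stats.nbinom.ppf(a, state.r, p_t))
        median.append(stats.nbinom.ppf(0.5, state.r, p_t))
        upper.append(stats.nbinom.ppf(1.0 - a, state.r, p_t))
    return ProjectionBand(eval_times, np.array(lower), np.array(median), np.array(upper), level)


def expected_line(design: StudyDesign, times: np.ndarray) -> np.ndarray:
    """The planned constant-rate reference: the line from (0, 0) to (T, n)."""
    times = np.asarray(times, dtype=float)
    return design.planned_rate * times


def waiting_time_diagnostics(
    obs: AccrualObservation, state: PosteriorState
) -> WaitingTimeDiagnostics:
    """Compare the observed waiting-time distribution with the fitted model.

    Raises
    ------
    ValueError
        If ``m = 0`` — no enrollments to diagnose.
    """
    if obs.m == 0:
        raise ValueError("no enrollments to diagnose (m = 0)")
    theta_hat = state.theta_mean
    w = obs.waiting_times
    w_sorted = np.sort(w)
    ecdf = np.arange(1, len(w) + 1) / len(w)
    fitted = stats.expon.cdf(w_sorted, scale=theta_hat)
    trajectory = np.column_stack(
        (np.asarray(obs.enrollment_times), np.arange(1, obs.m + 1))
    )
    return WaitingTimeDiagnostics(
        waiting_times=w,
        fitted_rate=1.0 / theta_hat,
        ecdf_points=np.column_stack((w_sorted, ecdf)),
        fitted_cdf_points=np.column_stack((w_sorted, fitted)),
        cumulative_trajectory=trajectory,
    )


def plot_projection(
    band: ProjectionBand,
    design: StudyDesign,
    obs: AccrualObservation | None = None,
    ax=None,
):
    """Render the projection tunnel with the planned-rate reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(band.eval_times, band.lower, band.upper,
                    color="0.8", label=f"{band.level:.0%} credible band")
    ax.plot(band.eval_times, band.median, color="white", lw=2, label="projected median")
    ref_t = np.linspace(0, design.T, 50)
    ax.plot(ref_t, expected_line(design, ref_t), color="red", label="planned accrual")
    if obs is not None and obs.m > 0:
        t = np.asarray(obs.enrollment_times)
        ax.step(np.concatenate(([0.0], t)), np.arange(obs.m + 1),
                where="post", color="black", label="observed")
    ax.set_xlabel("time")
    ax.set_ylabel("cumulative subjects")
    ax.legend(loc="upper left", fontsize="small")
    return ax


def plot_diagnostics(diag: WaitingTimeDiagnostics, axes=None):
    """Three-panel layout: cumulative trajectory, waiting-time histogram, ECDF."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    traj = diag.cumulative_trajectory
    axes[0].step(traj[:, 0], traj[:, 1], where="post", color="black")
    axes[0].set_xlabel("time")
    axes[0].set_ylabel("cumulative subjects")

    w = diag.waiting_times
    axes[1].hist(w, bins="auto", density=True, color="0.7", edgecolor="white")
    grid = np.linspace(0, max(w.max(), 1e-9), 100)
    axes[1].plot(grid, diag.fitted_rate * np.exp(-diag.fitted_rate * grid), color="red")
    axes[1].set_xlabel("waiting time")
    axes[1].set_ylabel("density")

    axes[2].step(diag.ecdf_points[:, 0], diag.ecdf_points[:, 1],
                 where="post", color="black", label="ECDF")
    axes[2].plot(diag.fitted_cdf_points[:, 0], diag.fitted_cdf_points[:, 1],
                 color="red", label="fitted exponential")
    axes[2].set_xlabel("waiting time")
    axes[2].set_ylabel("CDF")
    axes[2].legend(fontsize="small")
    return axes
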