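"""Multi-site recruitment review.

The accrual model is a single-stream model; a multicenter review pools all
sites' enrollments, fits one posterior, and compares each center's cumulative
trajectory against its share of the pooled credible tunnel.  Sites whose
counts fall below the per-site lower band at the review snapshot are flagged
as under-performing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import ProjectionBand, retrospective_band
from .model import AccrualObservation, StudyDesign, update_posterior

__all__ = ["SiteAccrual", "SiteEvaluation", "evaluate_sites", "site_summary_table", "pool_sites"]


@dataclass(frozen=True)
class SiteAccrual:
    """One center's enrollment stream: a label and sorted non-negative offsets."""

    site_id: str
    enrollment_times: tuple[float, ...]

    def __init__(self, site_id: str, enrollment_times: Sequence[float] = ()):
        times = tuple(float(t) for t in enrollment_times)
        if any(t < 0 for t in times):
            raise ValueError(f"site {site_id}: enrollment times must be non-negative")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"site {site_id}: enrollment times must be sorted")
        object.__setattr__(self, "site_id", str(site_id))
        object.__setattr__(self, "enrollment_times", times)

    @property
    def m(self) -> int:
        return len(self.enrollment_times)

    def count_at(self, t: float) -> int:
        return int(np.searchsorted(self.enrollment_times, t, side="right"))


@dataclass(frozen=True)
class SiteEvaluation:
    """A site's trajectory versus its share of the pooled projection."""

    site_id: str
    trajectory: np.ndarray          # (time, cumulative count) step series
    band: ProjectionBand            # pooled band divided by the site weight
    expected_line: np.ndarray       # per-site linear target at the band grid
    flag: str                       # 'within-band' | 'below-band' | 'above-band'
    count_at_review: int
    review_time: float


def pool_sites(site_data: Sequence[SiteAccrual], Tm: float) -> AccrualObservation:
    """Concatenate all sites' enrollments into one time-sorted observation."""
    merged = sorted(t for site in site_data for t in site.enrollment_times)
    return AccrualObservation(merged, Tm=Tm)


def evaluate_sites(
    design: StudyDesign,
    site_data: Sequence[SiteAccrual],
    review_time: float,
    level: float = 0.95,
    *,
    eval_times: np.ndarray | None = None,
    weights: Sequence[float] | None = None,
) -> list[SiteEvaluation]:
    """Flag each center against its share of the pooled credible tunnel.

    All sites' enrollments up to ``review_time`` are pooled into a single
    stream, the posterior for the mean waiting time is fitted to the pool,
    and cumulative accrual is re-projected from trial start under that
    posterior (NB(r, s/(s+t)) across the grid).  The tunnel and the linear
    planned-rate reference are divided equally among the J sites (or by the
    supplied weights) and each site's count at the review snapshot is
    compared with its band: below the lower limit -> ``below-band``, above
    the upper limit -> ``above-band``, otherwise ``within-band``.

    Band endpoints after division are kept as reals: they bound a per-site
    average, not a count.
    """
    if len(site_data) < 2:
        raise ValueError("site evaluation requires at least 2 sites")
    if review_time > design.T:
        raise ValueError(f"review_time={review_time} exceeds the planned duration T={design.T}")
    for site in site_data:
        if site.m and site.enrollment_times[-1] > review_time:
            raise ValueError(
                f"site {site.site_id} has enrollments after review_time={review_time}"
            )
    J = len(site_data)
    if weights is None:
        weights = np.full(J, 1.0 / J)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (J,) or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per site")
        weights = weights / weights.sum()

    pooled = pool_sites(site_data, Tm=review_time)
    state = update_posterior(design, pooled)
    if eval_times is None:
        eval_times = np.linspace(0.0, design.T, 49)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if not np.any(np.isclose(eval_times, review_time)):
        eval_times = np.sort(np.append(eval_times, review_time))
    pooled_band = retrospective_band(state, eval_times, level)

    evaluations = []
    for site, w in zip(site_data, weights):
        band = pooled_band.scaled(w)
        lo, _, hi = band.at(review_time)
        count = site.count_at(review_time)
        if count < lo:
            flag = "below-band"
        elif count > hi:
            flag = "above-band"
        else:
            flag = "within-band"
        times = np.asarray(site.enrollment_times)
        trajectory = np.column_stack((times, np.arange(1, site.m + 1)))
        evaluations.append(
            SiteEvaluation(
                site_id=site.site_id,
                trajectory=trajectory,
                band=band,
                expected_line=design.planned_rate * eval_times * w,
                flag=flag,
                count_at_review=count,
                review_time=review_time,
            )
        )
    return evaluations


def site_summary_table(evaluations: Sequence[SiteEvaluation]) -> pd.DataFrame:
    """One row per site: count at review, share of the pooled total, flag."""
    if not evaluations:
        raise ValueError("no site evaluations to summarize")
    counts = np.array([e.count_at_review for e in evaluations], dtype=float)
    total = counts.sum()
    shares = counts / total if total > 0 else np.zeros_like(counts)
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in evaluations],
            "count": counts.astype(int),
            "share": shares,
            "flag": [e.flag for e in evaluations],
        }
    )
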