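"""Enrollment-log reading and writing.

The log format is a delimited text file with a header and one row per
enrolled subject.  Either a ``date`` column (ISO-8601 calendar dates) or an
``offset`` column (numeric day/month offsets from trial start) identifies
the enrollment time; an optional ``site`` column splits the log into
per-site streams.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AccrualObservation
from .sites import SiteAccrual

__all__ = ["read_enrollment_log", "write_enrollment_log", "DAYS_PER_MONTH"]

# mean Gregorian month length, used for day<->month conversion
DAYS_PER_MONTH = 30.4375

_UNITS = ("days", "months")


def _to_unit(days: np.ndarray, unit: str) -> np.ndarray:
    if unit == "days":
        return days
    if unit == "months":
        return days / DAYS_PER_MONTH
    raise ValueError(f"unknown unit {unit!r}; expected one of {_UNITS}")


def read_enrollment_log(
    path: str | Path,
    trial_start: str | None = None,
    unit: str = "days",
    Tm: float | None = None,
) -> AccrualObservation | list[SiteAccrual]:
    """Parse a delimited enrollment log into observation objects.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.  Must contain either ``date`` (ISO
        dates) or ``offset`` (non-negative numbers in ``unit``); an optional
        ``site`` column yields one stream per site.
    trial_start : str, optional
        ISO date of trial start; required when the log carries a ``date``
        column.  Offsets are computed as (date - trial_start) in ``unit``.
    unit : {'days', 'months'}
    Tm : float, optional
        Elapsed review time; defaults to the last enrollment offset.
        Ignored for per-site output (sites carry raw streams).

    Returns
    -------
    AccrualObservation or list of SiteAccrual
        Per-site streams when a ``site`` column is present, a single pooled
        observation otherwise.  Rows are sorted on load.
    """
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {_UNITS}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "offset" in df.columns:
        offsets = df["offset"].astype(float).to_numpy()
    elif "date" in df.columns:
        if trial_start is None:
            raise ValueError("a 'date' column requires trial_start")
        dates = pd.to_datetime(df["date"], format="ISO8601")
        start = pd.Timestamp(trial_start)
        offsets = _to_unit((dates - start).dt.days.to_numpy(dtype=float), unit)
    else:
        raise ValueError("enrollment log needs a 'date' or 'offset' column")
    if np.any(offsets < 0):
        raise ValueError("negative offset: enrollment before trial start")

    if "site" in df.columns:
        out = []
        for site_id, grp in df.assign(_offset=offsets).groupby("site", sort=True):
            out.append(SiteAccrual(str(site_id), np.sort(grp["_offset"].to_numpy())))
        return out
    return AccrualObservation(np.sort(offsets), Tm=Tm)


def write_enrollment_log(
    path: str | Path,
    data: AccrualObservation | Sequence[SiteAccrual],
) -> None:
    """Write observations back to the CSV format :func:`read_enrollment_log` reads."""
    if isinstance(data, AccrualObservation):
        df = pd.DataFrame({"offset": list(data.enrollment_times)})
    else:
        rows = [
            {"offset": t, "site": site.site_id}
            for site in data
            for t in site.enrollment_times
        ]
        df = pd.DataFrame(rows, columns=["offset", "site"])
    df.to_csv(path, index=False)
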