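"""Time-stratified case-crossover strata and design matrices.

Each retained death defines one stratum: the case day plus every other
day in the same calendar month and year that shares the case day's day
of week (3 or 4 referent days, by the calendar).  Matching on
weekday-within-month-within-year controls day-of-week effects,
seasonality and long-term trends by design; matching on "location" is
automatic because a death's referent days use the same locality's
exposure series.

Every row of a stratum carries a 7-day exposure history (lags 0..6) of
assigned PM2.5 and temperature.  A stratum is dropped whenever any lag
value on any of its rows is missing or incomplete (the complete-history
rule).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import LocalitySeries

__all__ = [
    "referent_days",
    "build_stratum",
    "build_strata_table",
    "build_design_matrix",
    "CaseCrossoverStratum",
    "StackedDesign",
]

N_LAGS = 7  # lags 0..6

DROP_NO_GEOGRAPHY = "no-exposure-geography"
DROP_INCOMPLETE = "incomplete-lag-history"


def referent_days(case_date) -> list[dt.date]:
    """All same-weekday days in the case day's month/year, case excluded.

    Always returns 3 or 4 dates, sorted ascending: a 28-day month holds
    each weekday exactly 4 times, a 29-31-day month holds it 4 or 5.
    """
    d = pd.Timestamp(case_date).date()
    n_days = calendar.monthrange(d.year, d.month)[1]
    first_same = (d.day - 1) % 7 + 1  # earliest day-of-month sharing d's weekday
    return [
        dt.date(d.year, d.month, day)
        for day in range(first_same, n_days + 1, 7)
        if day != d.day
    ]


@dataclass
class CaseCrossoverStratum:
    """One case day plus its 3-4 referent days with full lag histories."""

    stratum_id: int
    locality_id: str
    dates: list[dt.date]  # case first, then referents ascending
    is_case: np.ndarray  # (n_rows,) 1/0
    pm25_lags: np.ndarray  # (n_rows, 7)
    temp_lags: np.ndarray  # (n_rows, 7)


@dataclass
class StackedDesign:
    """Stacked covariate rows grouped by stratum, ready for the
    conditional-logistic likelihood.

    Rows are sorted so each stratum is contiguous; ``starts`` gives the
    first row of each stratum.
    """

    X: np.ndarray
    is_case: np.ndarray
    starts: np.ndarray
    colnames: list[str]

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    @property
    def counts(self) -> np.ndarray:
        return np.diff(np.append(self.starts, len(self.is_case)))


def _lag_history(series: LocalitySeries, col: int, day_idx: int):
    """(pm_lags, temp_lags, ok) for one locality-day; lag l = day_idx - l."""
    if day_idx - (N_LAGS - 1) < 0 or day_idx >= len(series.dates):
        return None, None, False
    sl = slice(day_idx - N_LAGS + 1, day_idx + 1)
    pm = series.pm[sl, col][::-1]
    temp = series.temp[sl, col][::-1]
    ok = bool(series.complete[sl, col].all())
    return pm, temp, ok


def build_stratum(record, series: LocalitySeries, stratum_id: int = 0):
    """Build one stratum from a mortality record, or a drop reason.

    ``record`` needs ``death_date`` and ``locality_id`` attributes or
    keys.  Returns ``(stratum, None)`` on success or ``(None, reason)``
    when the locality is unknown or any of the 7 lag days on any row is
    missing/incomplete.
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    lid = str(get("locality_id"))
    try:
        col = series.column(lid)
    except KeyError:
        return None, DROP_NO_GEOGRAPHY
    case_date = pd.Timestamp(get("death_date"))
    try:
        t0 = series.dates.get_loc(case_date)
    except KeyError:
        return None, DROP_INCOMPLETE
    dates = [case_date.date()] + referent_days(case_date)
    rows_pm, rows_temp = [], []
    for d in dates:
        idx = t0 + (pd.Timestamp(d) - case_date).days
        pm, temp, ok = _lag_history(series, col, idx)
        if not ok or np.isnan(pm).any() or np.isnan(temp).any():
            return None, DROP_INCOMPLETE
        rows_pm.append(pm)
        rows_temp.append(temp)
    is_case = np.zeros(len(dates), dtype=int)
    is_case[0] = 1
    return (
        CaseCrossoverStratum(
            stratum_id=stratum_id,
            locality_id=lid,
            dates=dates,
            is_case=is_case,
            pm25_lags=np.array(rows_pm),
            temp_lags=np.array(rows_temp),
        ),
        None,
    )


def build_strata_table(
    records: pd.DataFrame, series: LocalitySeries
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised stratum construction for a whole record table.

    Returns ``(rows, drops)``.  ``rows`` has one row per stratum row
    with columns ``stratum_id, is_case, locality_id, date,
    pm25_lag0..6, temp_lag0..6``; ``drops`` logs one row per dropped
    record with its reason.
    """
    n = len(records)
    lids = records["locality_id"].astype(str).to_numpy()
    col_of = {lid: j for j, lid in enumerate(series.locality_ids)}
    loc_col = np.array([col_of.get(l, -1) for l in lids])

    case_dates = pd.to_datetime(records["death_date"])
    origin = series.dates[0]
    day_idx = (case_dates - origin).dt.days.to_numpy()

    # enumerate all rows (case + referents) per record
    rec_ids, row_dates = [], []
    for i, d in enumerate(case_dates):
        rds = referent_days(d)
        rec_ids.extend([i] * (1 + len(rds)))
        row_dates.append(d)
        row_dates.extend(pd.Timestamp(x) for x in rds)
    rec_ids = np.array(rec_ids)
    row_dates = pd.DatetimeIndex(row_dates)
    row_day = (row_dates - origin).days.to_numpy()
    is_case = np.zeros(len(rec_ids), dtype=int)
    is_case[np.flatnonzero(np.diff(np.append(-1, rec_ids)))] = 1

    ok_geo = loc_col >= 0
    in_range = (row_day >= N_LAGS - 1) & (row_day < len(series.dates))
    row_loc = loc_col[rec_ids]

    pm_l = np.full((len(rec_ids), N_LAGS), np.nan)
    temp_l = np.full_like(pm_l, np.nan)
    comp = np.zeros((len(rec_ids), N_LAGS), dtype=bool)
    valid = in_range & (row_loc >= 0)
    for lag in range(N_LAGS):
        t = row_day[valid] - lag
        c = row_loc[valid]
        pm_l[valid, lag] = series.pm[t, c]
        temp_l[valid, lag] = series.temp[t, c]
        comp[valid, lag] = series.complete[t, c]

    row_ok = valid & comp.all(axis=1) & ~np.isnan(pm_l).any(axis=1) & ~np.isnan(
        temp_l
    ).any(axis=1)
    rec_ok = np.ones(n, dtype=bool)
    np.logical_and.at(rec_ok, rec_ids, row_ok)
    rec_ok &= ok_geo

    reasons = np.where(~ok_geo, DROP_NO_GEOGRAPHY, DROP_INCOMPLETE)
    drops = pd.DataFrame(
        {"record_index": records.index[~rec_ok], "reason": reasons[~rec_ok]}
    )

    keep = rec_ok[rec_ids]
    rows = pd.DataFrame(
        {
            "stratum_id": rec_ids[keep],
            "is_case": is_case[keep],
            "locality_id": lids[rec_ids[keep]],
            "date": row_dates[keep],
        }
    )
    for lag in range(N_LAGS):
        rows[f"pm25_lag{lag}"] = pm_l[keep, lag]
    for lag in range(N_LAGS):
        rows[f"temp_lag{lag}"] = temp_l[keep, lag]
    return rows, drops


def build_design_matrix(rows: pd.DataFrame, model_spec=None) -> StackedDesign:
    """Covariate matrix from stacked stratum rows.

    Column order: the 7 PM2.5 lag terms (or their per-lag spline
    expansions, or a single cumulative column), then the temperature-
    adjustment basis columns.  Strata absorb intercepts, so spline bases
    enter with one column dropped (the stratum-constant direction).
    """
    from .inference import ModelSpec, spline_columns  # deferred: avoids cycle

    if model_spec is None:
        model_spec = ModelSpec()
    if len(rows) == 0:
        raise ValueError("empty strata set: no design to build")
    rows = rows.sort_values(["stratum_id"], kind="stable").reset_index(drop=True)
    sid = rows["stratum_id"].to_numpy()
    starts = np.flatnonzero(np.diff(np.append(-1, sid)))

    cols, names = [], []
    pm = rows[[f"pm25_lag{l}" for l in model_spec.pm_lags]].to_numpy()
    if model_spec.pm_constraint == "cumulative":
        cols.append(pm.sum(axis=1, keepdims=True))
        names.append("pm25_cumulative")
    elif model_spec.pm_spline_df:
        for j, l in enumerate(model_spec.pm_lags):
            B, nm = spline_columns(
                pm[:, j], df=model_spec.pm_spline_df, degree=2, prefix=f"pm25_lag{l}"
            )
            cols.append(B)
            names.extend(nm)
    else:
        cols.append(pm)
        names.extend(f"pm25_lag{l}" for l in model_spec.pm_lags)

    if model_spec.temp_structure == "mean":
        tmean = rows[[f"temp_lag{l}" for l in range(N_LAGS)]].to_numpy().mean(axis=1)
        B, nm = spline_columns(
            tmean, df=model_spec.temp_df, degree=model_spec.temp_degree, prefix="temp_mean06"
        )
        cols.append(B)
        names.extend(nm)
    elif model_spec.temp_structure == "per-lag":
        for l in range(N_LAGS):
            B, nm = spline_columns(
                rows[f"temp_lag{l}"].to_numpy(),
                df=model_spec.temp_df,
                degree=model_spec.temp_degree,
                prefix=f"temp_lag{l}",
            )
            cols.append(B)
            names.extend(nm)
    elif model_spec.temp_structure is not None:
        raise ValueError(f"unknown temp_structure {model_spec.temp_structure!r}")

    X = np.hstack([np.atleast_2d(c) if c.ndim == 2 else c[:, None] for c in cols])
    return StackedDesign(
        X=X,
        is_case=rows["is_case"].to_numpy().astype(int),
        starts=starts,
        colnames=names,
    )
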