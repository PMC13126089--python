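"""Annual climate variables from daily surface weather.

Five site-level annual variables drive the synchrony analysis: mean July
temperature, total June precipitation, mean January temperature, total
January precipitation (all of the focal year), and the July-temperature
differential ``delta_t = JulyTemp(t-2) - JulyTemp(t-3)``.  The differential
is a surrogate for mast seeding: seed crops in year ``t-1`` respond to the
difference of the two preceding July temperatures, and seed-eating small
mammals respond to the crop one year later, in year ``t``.

Daily mean temperature is approximated as ``(tmax + tmin) / 2`` (the
standard proxy when only daily extremes are recorded).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

#: Annual variable names, in reporting order.
CLIMATE_VARIABLES = (
    "july_temp",
    "june_precip",
    "january_temp",
    "january_precip",
    "delta_t",
)

#: Display names used in result tables.
CLIMATE_LABELS = {
    "july_temp": "JulyTemp_t",
    "june_precip": "JunePrecip_t",
    "january_temp": "JanuaryTemp_t",
    "january_precip": "JanuaryPrecip_t",
    "delta_t": "DeltaT_2-3",
    "proximity": "Proximity",
}

_DAYS_IN_MONTH = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30,
                  7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31}


class MonthlyValue(NamedTuple):
    mean_temp: float
    total_precip: float
    completeness: float


def monthly_aggregate(daily: pd.DataFrame, site: str, year: int,
                      month: int) -> MonthlyValue | None:
    """Mean daily temperature and total precipitation for one site-month.

    Returns ``None`` when the month has no daily rows (missing, not zero).
    ``completeness`` is the fraction of calendar days present.
    """
    d = daily[daily["site"].astype(str) == site]
    dt = pd.to_datetime(d["date"])
    d = d[(dt.dt.year == year) & (dt.dt.month == month)]
    if d.empty:
        return None
    mean_temp = float(((d["tmax"] + d["tmin"]) / 2.0).mean())
    total_precip = float(d["prcp"].sum())
    return MonthlyValue(mean_temp, total_precip,
                        len(d) / _DAYS_IN_MONTH[month])


def monthly_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a daily table to (site, year, month) means and totals."""
    if daily.empty:
        return pd.DataFrame(
            columns=["site", "year", "month", "mean_temp", "total_precip",
                     "completeness"]
        )
    d = daily.copy()
    dt = pd.to_datetime(d["date"])
    d["year"] = dt.dt.year
    d["month"] = dt.dt.month
    d["mean_temp"] = (d["tmax"] + d["tmin"]) / 2.0
    g = d.groupby(["site", "year", "month"], observed=True)
    out = g.agg(
        mean_temp=("mean_temp", "mean"),
        total_precip=("prcp", "sum"),
        n_days=("prcp", "size"),
    ).reset_index()
    out["completeness"] = out["n_days"] / out["month"].map(_DAYS_IN_MONTH)
    return out.drop(columns="n_days")


def derive_annual(monthly: pd.DataFrame,
                  analysis_years: Iterable[int]) -> pd.DataFrame:
    """Annual climate table: one row per (site, analysis year).

    Rows missing an antecedent July mean (needed for the temperature
    differential) or any focal-month value are flagged ``complete=False``
    with the affected variables left missing.
    """
    analysis_years = sorted(int(y) for y in analysis_years)
    sites = sorted(monthly["site"].astype(str).unique())

    def pick(site, year, month, col):
        m = monthly[(monthly["site"].astype(str) == site)
                    & (monthly["year"] == year)
                    & (monthly["month"] == month)]
        if m.empty:
            return np.nan
        return float(m.iloc[0][col])

    rows = []
    for site in sites:
        sub = monthly[monthly["site"].astype(str) == site]
        july = sub[sub["month"] == 7].set_index("year")["mean_temp"]
        for year in analysis_years:
            july_t = july.get(year, np.nan)
            j2 = july.get(year - 2, np.nan)
            j3 = july.get(year - 3, np.nan)
            delta = j2 - j3 if np.isfinite(j2) and np.isfinite(j3) else np.nan
            row = {
                "site": site,
                "year": year,
                "july_temp": july_t,
                "june_precip": pick(site, year, 6, "total_precip"),
                "january_temp": pick(site, year, 1, "mean_temp"),
                "january_precip": pick(site, year, 1, "total_precip"),
                "delta_t": delta,
            }
            row["complete"] = bool(
                np.all(np.isfinite([row[v] for v in CLIMATE_VARIABLES]))
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    bad = (out[["june_precip", "january_precip"]] < 0).any(axis=None)
    if bad:
        raise ValueError("negative precipitation in monthly input")
    return out


def annual_climate(daily: pd.DataFrame,
                   analysis_years: Iterable[int]) -> pd.DataFrame:
    """Daily weather straight to the annual climate table."""
    monthly = monthly_table(daily)
    low = monthly[monthly["completeness"] < 0.9]
    if not low.empty:
        import logging
        logging.getLogger(__name__).warning(
            "%d site-months have under 90%% of days present", len(low)
        )
    return derive_annual(monthly, analysis_years)


def climate_series(annual: pd.DataFrame, variable: str) -> dict[str, pd.Series]:
    """Per-site annual series for one climate variable (missing dropped)."""
    if variable not in CLIMATE_VARIABLES:
        raise KeyError(f"unknown climate variable {variable!r}")
    out = {}
    for site, grp in annual.groupby("site", observed=True):
        s = grp.set_index("year")[variable].dropna().sort_index()
        if not s.empty:
            out[str(site)] = s
    return out
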