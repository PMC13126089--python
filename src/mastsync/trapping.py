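"""Effort-corrected annual abundance indices from box-trapping records.

The abundance index for one (site, species, year) is the number of unique
tagged individuals captured divided by the trap-night effort (traps set and
functional, summed over grids and nights).  Series are then screened with
the study's inclusion rules: a year qualifies when at least four distinct
calendar months were trapped, a series is kept when it has at least four
consecutive qualifying years (and is truncated to that run), and series
whose raw annual captures never exceed one individual are dropped as
too sparse to carry a signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FUNCTIONAL_STATUSES

logger = logging.getLogger(__name__)


@dataclass
class PopulationSeries:
    """Annual effort-corrected index for one (site, species).

    ``data`` is indexed by year with columns ``count`` (unique individuals),
    ``trap_nights`` (site-level effort), ``index`` (count / trap_nights) and
    ``n_months`` (distinct calendar months trapped at the site that year).
    """

    site: str
    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if (d["trap_nights"] <= 0).any():
            raise ValueError(
                f"{self.label}: every retained year needs positive effort"
            )
        if not np.allclose(d["index"] * d["trap_nights"], d["count"]):
            raise ValueError(f"{self.label}: index * effort != count")

    @property
    def label(self) -> str:
        return f"{self.site}:{self.species}"

    @property
    def index(self) -> pd.Series:
        """Captures per trap night by year."""
        return self.data["index"]

    @property
    def counts(self) -> pd.Series:
        return self.data["count"]

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def truncated(self, years: list) -> "PopulationSeries":
        return PopulationSeries(self.site, self.species,
                                self.data.loc[list(years)])


def _capture_rows(records: pd.DataFrame) -> pd.DataFrame:
    """Capture rows identified to species (nonempty tag and species code)."""
    tag = records["tagID"].fillna("")
    taxon = records["taxonID"]
    if isinstance(taxon.dtype, pd.CategoricalDtype):
        taxon = taxon.cat.add_categories(
            [""] if "" not in taxon.cat.categories else []
        ).fillna("")
    else:
        taxon = taxon.fillna("")
    return records[(tag != "").to_numpy() & (taxon != "").to_numpy()]


def resolve_tag_conflicts(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve tags recorded under two species codes within one site-year.

    Majority vote over the tag's capture rows; ties exclude the tag.  Both
    outcomes are logged.  Returns capture rows with consistent species codes.
    """
    caps = _capture_rows(records).copy()
    if caps.empty:
        return caps
    year = pd.to_datetime(caps["collectDate"]).dt.year
    caps = caps.assign(_year=year.to_numpy())
    key = ["siteID", "_year", "tagID"]
    nuniq = caps.groupby(key, observed=True)["taxonID"].transform("nunique")
    clean = caps[nuniq == 1]
    dirty = caps[nuniq > 1]
    if dirty.empty:
        return clean
    keep = []
    for (site, yr, tag), grp in dirty.groupby(key, observed=True):
        counts = grp["taxonID"].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            logger.warning(
                "tag %s at %s in %d has tied species codes %s; excluded",
                tag, site, yr, list(counts.index[:2]),
            )
            continue
        winner = counts.index[0]
        logger.warning(
            "tag %s at %s in %d has conflicting species codes; resolved to "
            "%s by majority", tag, site, yr, winner,
        )
        g = grp.copy()
        g["taxonID"] = winner
        keep.append(g)
    if keep:
        return pd.concat([clean] + keep)
    return clean


def count_unique_individuals(records: pd.DataFrame, site: str, species: str,
                             year: int) -> int:
    """Distinct tagged individuals of one species at one site in one year."""
    caps = resolve_tag_conflicts(records)
    if caps.empty:
        return 0
    yr = pd.to_datetime(caps["collectDate"]).dt.year
    sel = caps[(caps["siteID"].astype(str) == site)
               & (caps["taxonID"].astype(str) == species)
               & (yr.to_numpy() == year)]
    return int(sel["tagID"].nunique())


def compute_effort(records: pd.DataFrame, site: str, year: int,
                   functional_statuses: frozenset = FUNCTIONAL_STATUSES) -> int:
    """Trap nights at a site in a year: rows with a functional-trap status.

    Raises ``ValueError`` when the site-year has no records at all or no
    functional trap nights (such a year is unsampled, not zero-abundance).
    """
    yr = pd.to_datetime(records["collectDate"]).dt.year
    sel = records[(records["siteID"].astype(str) == site)
                  & (yr.to_numpy() == year)]
    if sel.empty:
        raise ValueError(f"no trapping records for {site} in {year}")
    effort = int(sel["trapStatus"].astype(str).isin(functional_statuses).sum())
    if effort == 0:
        raise ValueError(
            f"{site} in {year} has records but zero functional trap nights"
        )
    return effort


def build_index(counts: pd.Series, effort: pd.Series) -> pd.Series:
    """Per-year captures per trap night (count / effort), full precision."""
    counts, effort = counts.align(effort, join="inner")
    if ((effort <= 0) & (counts > 0)).any():
        raise ValueError("positive count with zero effort")
    if (effort <= 0).any():
        raise ValueError("effort must be positive for retained years")
    return counts / effort


def build_population_series(
    records: pd.DataFrame,
    analysis_years: range | list | None = None,
    functional_statuses: frozenset = FUNCTIONAL_STATUSES,
) -> list[PopulationSeries]:
    """All (site, species) annual series derivable from a record table.

    A site-year enters a series when it has positive functional effort; a
    species observed anywhere at the site gets an explicit zero count in
    sampled years without captures.  ``analysis_years`` restricts the window.
    """
    records = records.copy()
    records["_year"] = pd.to_datetime(records["collectDate"]).dt.year
    records["_month"] = pd.to_datetime(records["collectDate"]).dt.month
    if analysis_years is not None:
        years = set(int(y) for y in analysis_years)
        records = records[records["_year"].isin(years)]
    if records.empty:
        return []

    functional = records[records["trapStatus"].isin(functional_statuses)]
    effort = functional.groupby(
        ["siteID", "_year"], observed=True
    ).size().rename("trap_nights")
    months = records.groupby(["siteID", "_year"], observed=True)[
        "_month"
    ].nunique().rename("n_months")

    caps = resolve_tag_conflicts(records)
    out: list[PopulationSeries] = []
    if caps.empty:
        return out
    counts = caps.groupby(
        ["siteID", "taxonID", "_year"], observed=True
    )["tagID"].nunique().rename("count")

    site_year = effort.reset_index()
    for (site, species), grp in counts.reset_index().groupby(
        ["siteID", "taxonID"], observed=True
    ):
        site = str(site)
        species = str(species)
        sy = site_year[site_year["siteID"].astype(str) == site]
        if sy.empty:
            continue
        frame = sy.set_index("_year")[["trap_nights"]].sort_index()
        c = grp.set_index("_year")["count"]
        frame["count"] = c.reindex(frame.index).fillna(0).astype(int)
        frame["index"] = frame["count"] / frame["trap_nights"]
        frame["n_months"] = months.loc[site].reindex(frame.index).to_numpy()
        frame.index.name = "year"
        out.append(
            PopulationSeries(site, species,
                             frame[["count", "trap_nights", "index",
                                    "n_months"]])
        )
    return out


def _longest_qualifying_run(years: np.ndarray, qualifies: np.ndarray) -> list:
    """Longest run of consecutive qualifying years; ties -> most recent run."""
    best: list = []
    current: list = []
    prev_year = None
    for y, ok in zip(years, qualifies):
        if ok and (prev_year is not None and y == prev_year + 1 and current):
            current.append(int(y))
        elif ok:
            current = [int(y)]
        else:
            current = []
        if len(current) >= len(best):
            best = list(current)
        prev_year = int(y)
    return best


def filter_series(
    series: list[PopulationSeries],
    min_consecutive_years: int = 4,
    min_months_per_year: int = 4,
) -> tuple[list[PopulationSeries], pd.DataFrame]:
    """Apply the data-quantity inclusion rules.

    A year qualifies when at least ``min_months_per_year`` distinct calendar
    months were trapped; a series is retained when its longest run of
    consecutive qualifying years reaches ``min_consecutive_years``, and is
    truncated to that run (ties between equal runs break toward the most
    recent).  Returns the retained series and an exclusion report with one
    row per input series.
    """
    retained = []
    report_rows = []
    for s in series:
        ok = (s.data["n_months"] >= min_months_per_year).to_numpy()
        run = _longest_qualifying_run(s.years, ok)
        if len(run) >= min_consecutive_years:
            retained.append(s.truncated(run))
            report_rows.append(
                {"site": s.site, "species": s.species, "retained": True,
                 "rule": "", "years_kept": len(run)}
            )
        else:
            rule = (
                "fewer than "
                f"{min_consecutive_years} consecutive qualifying years "
                f"(longest run {len(run)})"
            )
            report_rows.append(
                {"site": s.site, "species": s.species, "retained": False,
                 "rule": rule, "years_kept": 0}
            )
            logger.info("excluded %s: %s", s.label, rule)
    return retained, pd.DataFrame(
        report_rows, columns=["site", "species", "retained", "rule",
                              "years_kept"]
    )


def low_capture_filter(
    series: list[PopulationSeries],
    max_count: int = 1,
) -> tuple[list[PopulationSeries], pd.DataFrame]:
    """Drop series whose raw annual captures never exceed ``max_count``.

    Applies only to series with at least two years of data; single-year
    series are left to the consecutive-years rule.
    """
    retained = []
    report_rows = []
    for s in series:
        counts = s.counts.to_numpy()
        drop = len(counts) >= 2 and counts.max() <= max_count
        if drop:
            rule = (
                "low captures (never more than "
                f"{max_count} individual{'s' if max_count != 1 else ''} "
                "per year)"
            )
            logger.info("excluded %s: %s", s.label, rule)
        else:
            retained.append(s)
            rule = ""
        report_rows.append(
            {"site": s.site, "species": s.species, "retained": not drop,
             "rule": rule}
        )
    return retained, pd.DataFrame(
        report_rows, columns=["site", "species", "retained", "rule"]
    )


def aggregate_site_series(series: list[PopulationSeries],
                          site: str) -> pd.Series:
    """Species-summed annual index for one site.

    Because all species at a site share the same trap-night denominator,
    summing per-trap-night indices equals summing counts and dividing once.
    """
    own = [s for s in series if s.site == site]
    if not own:
        raise ValueError(f"no retained series at site {site}")
    summed = None
    for s in own:
        summed = s.index if summed is None else summed.add(s.index,
                                                           fill_value=0.0)
    return summed.sort_index()


def standardize_0_100(series: pd.Series) -> pd.Series:
    """Min-max rescale to [0, 100] across years; order-preserving."""
    lo, hi = float(series.min()), float(series.max())
    if hi == lo:
        raise ValueError("cannot standardize a constant series")
    return 100.0 * (series - lo) / (hi - lo)


def series_table(series: list[PopulationSeries]) -> pd.DataFrame:
    """Tidy long table (site, species, year, count, trap_nights, index)."""
    rows = []
    for s in series:
        d = s.data.reset_index()
        d.insert(0, "species", s.species)
        d.insert(0, "site", s.site)
        rows.append(d)
    if not rows:
        return pd.DataFrame(
            columns=["site", "species", "year", "count", "trap_nights",
                     "index", "n_months"]
        )
    return pd.concat(rows, ignore_index=True)
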