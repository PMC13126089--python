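"""Synthetic continental trapping worlds with a controllable climate dipole.

This module generates NEON-like small-mammal box-trapping records and
Daymet-like daily surface weather for a configurable set of sites spanning
continental distances, with a known causal chain built in:

    July-temperature dipole  ->  masting pulse (lagged 1 yr via the
    July-temperature differential)  ->  rodent abundance (lagged 1 more yr)

The sign-flipping (dipole) mode of July temperature has loading
``E(s) = cos(pi * x_s)`` where ``x_s`` is the site's longitude rescaled to
[0, 1]: sites at the west pole carry loading +1, sites at the east pole -1,
so a common annual mode ``Z_y`` pushes July anomalies in opposite directions
at the two ends of the continent.  Residual climate variation is spatially
correlated with an exponential correlogram ``exp(-d / noise_range_km)``.

The masting index for mast year ``y`` responds to the July-temperature
differential of the two preceding summers (DeltaT = July(y-1) - July(y-2)),
and consumer abundance in year ``t`` responds to the mast crop of year
``t-1``; abundance therefore carries the dipole at a two/three-summer lag,
exactly the signal the downstream correlogram and matrix-regression stages
are designed to recover.

Every generated table is a deterministic function of the configuration
(including its seed).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: The nine mast-eating focal taxa (NEON-style 4-letter codes).
SPECIES_POOL = (
    "MYGA",  # Myodes gapperi
    "NEFL",  # Neotoma floridana
    "OCNU",  # Ochrotomys nuttalli
    "PEBO",  # Peromyscus boylii
    "PEKE",  # Peromyscus keeni
    "PELE",  # Peromyscus leucopus
    "PEMA",  # Peromyscus maniculatus
    "PETR",  # Peromyscus truei
    "POFL",  # Podomys floridanus
)

# Trap-status vocabulary (NEON-flavoured). Statuses 4-6 mean the trap was set
# and functional for the night; 1-3 do not contribute trapping effort.
STATUS_NOT_SET = "1 - trap not set"
STATUS_DISTURBED = "2 - trap disturbed"
STATUS_SPRUNG_EMPTY = "3 - trap sprung, no capture"
STATUS_MULTI_CAPTURE = "4 - more than 1 capture in one trap"
STATUS_CAPTURE = "5 - capture"
STATUS_SET_EMPTY = "6 - trap set and empty"

#: Statuses that count toward trap-night effort (trap set and operable).
FUNCTIONAL_STATUSES = frozenset(
    {STATUS_MULTI_CAPTURE, STATUS_CAPTURE, STATUS_SET_EMPTY}
)

# Months in which trapping bouts may be scheduled (peak greenness).
_BOUT_MONTHS = (4, 5, 6, 7, 8, 9)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    Geometry and sampling structure mirror the NEON small-mammal protocol:
    100-trap grids, 3-8 grids per site, bouts of three consecutive nights,
    about four bouts per year, 2013-2022 analysis years with daily weather
    from 2009 so that the two/three-summer temperature differential is
    defined for the first analysis year.
    """

    n_sites: int = 23
    extent_km: float = 4000.0
    first_year: int = 2009
    last_year: int = 2022
    analysis_start: int = 2013

    # Climate field
    dipole_strength: float = 1.5   # degC amplitude of the July dipole mode
    noise_range_km: float = 1500.0  # e-folding range of residual correlation
    climate_noise_sd: float = 0.6   # degC sd of monthly residual anomalies
    daily_temp_sd: float = 2.5      # degC day-to-day noise around monthly mean

    # Masting / abundance chain
    beta_mast: float = 1.0    # masting sensitivity to the July differential
    alpha_mast: float = 0.5   # log-abundance response to prior-year mast
    alpha_july: float = 0.15  # log-abundance response to current July anomaly
    alpha0: float = -5.0      # baseline log captures per trap night
    species_sd: float = 0.2   # per-(site, species) lognormal abundance sd
    overdispersion: float = 0.0  # 0 => Poisson counts; >0 => neg. binomial

    # Trapping structure
    species_min: int = 1
    species_max: int = 3
    bouts_min: int = 4
    bouts_max: int = 6
    traps_per_grid: int = 100
    grids_min: int = 3
    grids_max: int = 8
    recapture_rate: float = 0.3   # P(an individual is recaptured >= once)
    nonfunctional_rate: float = 0.03  # P(trap disturbed / sprung / not set)
    missing_year_sites: tuple[tuple[str, int], ...] = (
        ("S04", 2020),
        ("S11", 2020),
        ("S17", 2020),
    )

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 0 < self.extent_km <= math.pi * EARTH_RADIUS_KM:
            raise ValueError(
                "extent_km must be positive and no more than half the Earth "
                f"circumference ({math.pi * EARTH_RADIUS_KM:.0f} km)"
            )
        if self.bouts_min < 1:
            raise ValueError("bouts_per_year must be >= 1")
        if self.bouts_max > len(_BOUT_MONTHS):
            raise ValueError(
                f"bouts_max cannot exceed {len(_BOUT_MONTHS)} (one bout per "
                "calendar month within the trapping season)"
            )
        if not 1 <= self.species_min <= self.species_max <= len(SPECIES_POOL):
            raise ValueError("species range must satisfy 1 <= min <= max <= 9")
        if not 1 <= self.grids_min <= self.grids_max:
            raise ValueError("grid range must satisfy 1 <= min <= max")
        for name in ("dipole_strength", "climate_noise_sd", "beta_mast",
                     "alpha_mast", "alpha_july", "alpha0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.analysis_start - self.first_year < 3:
            raise ValueError(
                "year range too short: the July-temperature differential for "
                f"analysis year {self.analysis_start} needs July means back to "
                f"{self.analysis_start - 3}, but the series starts in "
                f"{self.first_year}"
            )
        if self.last_year < self.analysis_start:
            raise ValueError("last_year must be >= analysis_start")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    @property
    def analysis_years(self) -> range:
        return range(self.analysis_start, self.last_year + 1)

    def replace(self, **kwargs) -> "WorldConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Latent state of a synthetic world, for recovery tests.

    Attributes
    ----------
    site_ids : list of str
    years : ndarray of int
        All simulated years (climate support years included).
    dipole_loading : ndarray, shape (n_sites,)
        E(s) in [-1, 1]; opposite signs at the two poles.
    common_mode : ndarray, shape (n_years,)
        Z_y, the annual amplitude of the dipole mode.
    july_anomaly : ndarray, shape (n_sites, n_years)
        Simulated July monthly-mean temperature anomaly (degC).
    mast_index : ndarray, shape (n_sites, n_years)
        M_{s,y} >= 0, softplus of beta_mast times the July differential
        July(y-1) - July(y-2); NaN where the differential is undefined.
    expected_rate : ndarray, shape (n_sites, n_years)
        lambda_{s,t} (captures per trap night) for analysis years, NaN
        elsewhere.
    species : dict site -> tuple of species codes
    species_factor : dict (site, species) -> multiplicative abundance factor
    config : WorldConfig
    """

    site_ids: list
    years: np.ndarray
    dipole_loading: np.ndarray
    common_mode: np.ndarray
    july_anomaly: np.ndarray
    mast_index: np.ndarray
    expected_rate: np.ndarray
    species: dict
    species_factor: dict
    config: WorldConfig

    def rate_series(self, site: str, species: str) -> pd.Series:
        """Expected captures-per-trap-night series for one (site, species)."""
        i = self.site_ids.index(site)
        f = self.species_factor[(site, species)]
        vals = self.expected_rate[i] * f
        s = pd.Series(vals, index=self.years)
        return s.dropna()


@dataclass
class World:
    """A fully generated synthetic world."""

    config: WorldConfig
    sites: pd.DataFrame
    daily_climate: pd.DataFrame
    trapping: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# RNG plumbing: each stage derives its own independent child stream from the
# config seed, so stages can be regenerated standalone and stay deterministic.
# ---------------------------------------------------------------------------

_STAGE_KEYS = {"sites": 0, "climate": 1, "trapping": 2}


def _stage_rng(config: WorldConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STAGE_KEYS))
    return np.random.default_rng(children[_STAGE_KEYS[stage]])


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def generate_sites(config: WorldConfig) -> pd.DataFrame:
    """Generate site coordinates spanning roughly ``extent_km``.

    Two anchor sites are pinned at the same latitude with their longitudes
    solved so the great-circle distance between them equals ``extent_km``
    (the continental axis).  When there are at least three sites, the third
    is placed ~30 km from the western anchor so the shortest distance class
    of the correlogram is populated.  Remaining sites scatter uniformly over
    the longitude span within an 8-degree latitude band.

    Returns a DataFrame with columns ``siteID, lat, lon``.
    """
    rng = _stage_rng(config, "sites")
    n = config.n_sites
    base_lat = 40.0
    lon_w = -120.0

    # Solve the anchor longitude offset from the haversine formula at equal
    # latitudes: d = 2R asin(cos(lat) sin(dlon/2)).
    s = math.sin(config.extent_km / (2.0 * EARTH_RADIUS_KM))
    ratio = s / math.cos(math.radians(base_lat))
    if ratio > 1.0:
        raise ValueError(
            f"extent_km={config.extent_km} km is not reachable along the "
            f"{base_lat} degree parallel"
        )
    dlon = math.degrees(2.0 * math.asin(ratio))

    lats = np.empty(n)
    lons = np.empty(n)
    lats[0], lons[0] = base_lat, lon_w
    lats[1], lons[1] = base_lat, lon_w + dlon
    if n >= 3:
        # ~30 km east of the western anchor
        lats[2] = base_lat
        lons[2] = lon_w + 30.0 / (
            111.19492664455873 * math.cos(math.radians(base_lat))
        )
    if n > 3:
        lats[3:] = rng.uniform(base_lat - 4.0, base_lat + 4.0, n - 3)
        lons[3:] = rng.uniform(lon_w + 0.02 * dlon, lon_w + 0.98 * dlon, n - 3)
    return pd.DataFrame(
        {
            "siteID": [f"S{i:02d}" for i in range(n)],
            "lat": np.round(lats, 6),
            "lon": np.round(lons, 6),
        }
    )


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def _pairwise_distance_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    la = np.radians(lats)[:, None]
    lb = np.radians(lats)[None, :]
    dla = lb - la
    dlo = np.radians(lons)[None, :] - np.radians(lons)[:, None]
    a = np.sin(dla / 2) ** 2 + np.cos(la) * np.cos(lb) * np.sin(dlo / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def dipole_loading(lons: np.ndarray) -> np.ndarray:
    """Sign-flipping loading over the site cloud's long (longitude) axis."""
    lons = np.asarray(lons, dtype=float)
    span = lons.max() - lons.min()
    if span == 0:
        return np.ones_like(lons)
    x = (lons - lons.min()) / span
    return np.cos(np.pi * x)


def _spatial_factor(dist: np.ndarray, noise_range_km: float) -> np.ndarray:
    """Matrix L with L @ L.T = exp(-d / range) (eigen square root)."""
    n = dist.shape[0]
    if noise_range_km <= 0:
        return np.eye(n)
    if math.isinf(noise_range_km):
        corr = np.ones((n, n))
    else:
        corr = np.exp(-dist / noise_range_km)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)[None, :]


def _monthly_fields(sites: pd.DataFrame, config: WorldConfig,
                    rng: np.random.Generator):
    """Latent monthly anomaly fields shared by climate and trapping stages.

    Returns (temp_anom[n_sites, n_years, 12], prcp_factor[...], Z[n_years],
    E[n_sites]); month axis is 0-based (index 6 = July).
    """
    lats = sites["lat"].to_numpy()
    lons = sites["lon"].to_numpy()
    n_sites = len(sites)
    years = np.array(config.years)
    n_years = len(years)

    E = dipole_loading(lons)
    Z = rng.standard_normal(n_years)
    L = _spatial_factor(_pairwise_distance_km(lats, lons),
                        config.noise_range_km)

    temp_anom = np.empty((n_sites, n_years, 12))
    prcp_factor = np.empty((n_sites, n_years, 12))
    for iy in range(n_years):
        for im in range(12):
            temp_anom[:, iy, im] = config.climate_noise_sd * (
                L @ rng.standard_normal(n_sites)
            )
            prcp_factor[:, iy, im] = np.exp(
                0.4 * (L @ rng.standard_normal(n_sites))
            )
        temp_anom[:, iy, 6] += config.dipole_strength * E * Z[iy]
    return temp_anom, prcp_factor, Z, E


def _baseline_monthly_temp(lat: float, month: int) -> float:
    """Smooth latitude/season climatology (degC); July is the warmest month."""
    return (
        25.0
        - 0.6 * (lat - 30.0)
        + 12.0 * math.cos(2.0 * math.pi * (month - 7) / 12.0)
    )


def generate_daily_climate(sites: pd.DataFrame, config: WorldConfig) -> pd.DataFrame:
    """Daymet-like daily weather for every site and day of the year range.

    Columns: ``site, date, tmax, tmin, prcp`` with tmax >= tmin and prcp >= 0.
    Daily means are the monthly climatology plus the latent monthly anomaly
    plus independent day-to-day noise; the diurnal range is drawn uniform in
    [6, 14] degC so the tmax/tmin ordering holds by construction.
    """
    daily, _ = _generate_climate(sites, config)
    return daily


def _generate_climate(sites: pd.DataFrame, config: WorldConfig):
    if len(sites) == 0:
        raise ValueError("sites table is empty")
    rng = _stage_rng(config, "climate")
    temp_anom, prcp_factor, Z, E = _monthly_fields(sites, config, rng)

    years = np.array(config.years)
    site_ids = sites["siteID"].tolist()
    lats = sites["lat"].to_numpy()

    dates = pd.date_range(
        f"{config.first_year}-01-01", f"{config.last_year}-12-31", freq="D"
    )
    n_days = len(dates)
    month_of_day = dates.month.to_numpy()
    year_of_day = dates.year.to_numpy()
    iy_of_day = year_of_day - config.first_year

    frames = []
    for i, site in enumerate(site_ids):
        base = np.array(
            [_baseline_monthly_temp(lats[i], m) for m in range(1, 13)]
        )
        mean_day = (
            base[month_of_day - 1]
            + temp_anom[i, iy_of_day, month_of_day - 1]
            + config.daily_temp_sd * rng.standard_normal(n_days)
        )
        diurnal = rng.uniform(6.0, 14.0, n_days)
        prcp = rng.gamma(0.4, 6.0, n_days) * prcp_factor[
            i, iy_of_day, month_of_day - 1
        ]
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "date": dates,
                    "tmax": np.round(mean_day + diurnal / 2.0, 2),
                    "tmin": np.round(mean_day - diurnal / 2.0, 2),
                    "prcp": np.round(prcp, 2),
                }
            )
        )
    daily = pd.concat(frames, ignore_index=True)

    # July monthly-mean anomaly actually realised in the daily table is the
    # latent monthly anomaly up to averaged daily noise; the latent value is
    # what the abundance model uses (truth), the daily table is what the
    # estimator sees.
    latent = {"temp_anom": temp_anom, "Z": Z, "E": E, "years": years}
    return daily, latent


def _build_truth(sites: pd.DataFrame, latent: dict,
                 config: WorldConfig,
                 rng: np.random.Generator) -> GroundTruth:
    years = latent["years"]
    n_sites = len(sites)
    n_years = len(years)
    july = latent["temp_anom"][:, :, 6]  # (n_sites, n_years)

    # Mast index for mast year y: softplus of the July differential
    # July(y-1) - July(y-2); undefined for the first two years.
    mast = np.full((n_sites, n_years), np.nan)
    if n_years >= 3:
        dT = july[:, 1:] - july[:, :-1]          # diff at year index iy+1
        arg = config.beta_mast * dT[:, :-1]      # differential ending at iy+1
        mast[:, 2:] = np.log1p(np.exp(np.clip(arg, -50, 50)))

    lam = np.full((n_sites, n_years), np.nan)
    for iy, year in enumerate(years):
        if year < config.analysis_start:
            continue
        m_prev = mast[:, iy - 1]
        lam[:, iy] = np.exp(
            config.alpha0
            + config.alpha_mast * m_prev
            + config.alpha_july * july[:, iy]
        )

    site_ids = sites["siteID"].tolist()
    species: dict = {}
    species_factor: dict = {}
    for site in site_ids:
        k = int(rng.integers(config.species_min, config.species_max + 1))
        picks = tuple(sorted(rng.choice(SPECIES_POOL, size=k, replace=False)))
        species[site] = picks
        for sp in picks:
            species_factor[(site, sp)] = float(
                np.exp(rng.normal(0.0, config.species_sd))
            )

    return GroundTruth(
        site_ids=site_ids,
        years=years,
        dipole_loading=latent["E"],
        common_mode=latent["Z"],
        july_anomaly=july,
        mast_index=mast,
        expected_rate=lam,
        species=species,
        species_factor=species_factor,
        config=config,
    )


# ---------------------------------------------------------------------------
# Trapping
# ---------------------------------------------------------------------------

def generate_trapping(sites: pd.DataFrame, truth: GroundTruth,
                      config: WorldConfig) -> pd.DataFrame:
    """NEON-like box-trapping records for all analysis years.

    One row per trap-night.  Columns: ``siteID, plotID, collectDate,
    trapStatus, taxonID, tagID``.  Pathogen grids (three per site) run three
    nights per bout, diversity grids one night; bouts fall in distinct
    calendar months of the April-September season.  Unique individuals per
    (site, species, year) are Poisson (or negative-binomial when
    ``overdispersion > 0``) around functional-trap-night effort times the
    latent rate; about ``recapture_rate`` of individuals are recaptured at
    least once within the year.
    """
    rng = _stage_rng(config, "trapping")
    missing = set(tuple(x) for x in config.missing_year_sites)
    statuses_nonfunctional = np.array(
        [STATUS_NOT_SET, STATUS_DISTURBED, STATUS_SPRUNG_EMPTY]
    )

    col_site: list = []
    col_plot: list = []
    col_date: list = []
    col_status: list = []
    col_taxon: list = []
    col_tag: list = []

    iy_by_year = {int(y): i for i, y in enumerate(truth.years)}

    for i_site, site in enumerate(truth.site_ids):
        for year in config.analysis_years:
            if (site, year) in missing:
                continue
            iy = iy_by_year[year]
            lam = truth.expected_rate[i_site, iy]
            if not np.isfinite(lam):
                raise ValueError(
                    f"ground truth does not cover analysis year {year}"
                )

            n_bouts = int(rng.integers(config.bouts_min, config.bouts_max + 1))
            months = np.sort(
                rng.choice(_BOUT_MONTHS, size=n_bouts, replace=False)
            )
            g = int(rng.integers(config.grids_min, config.grids_max + 1))
            n_pathogen = min(3, g)
            n_diversity = g - n_pathogen
            grid_ids = [f"{site}_G{k:02d}" for k in range(g)]
            nights_per_grid = [3] * n_pathogen + [1] * n_diversity

            # Expand grid-night structure once per bout.
            grid_rep = []
            night_rep = []
            for gi, nn in enumerate(nights_per_grid):
                for night in range(nn):
                    grid_rep.append(gi)
                    night_rep.append(night)
            grid_rep = np.array(grid_rep)
            night_rep = np.array(night_rep)
            rows_per_bout = len(grid_rep) * config.traps_per_grid

            # Per-bout start days; three consecutive nights fit in any month.
            start_days = rng.integers(5, 26, n_bouts)

            sy_dates = []
            sy_plot = []
            for b in range(n_bouts):
                dates = [
                    np.datetime64(
                        f"{year}-{months[b]:02d}-{start_days[b] + n:02d}"
                    )
                    for n in night_rep
                ]
                sy_dates.append(
                    np.repeat(np.array(dates), config.traps_per_grid)
                )
                sy_plot.append(
                    np.repeat(grid_rep, config.traps_per_grid)
                )
            dates_arr = np.concatenate(sy_dates)
            plot_arr = np.concatenate(sy_plot)
            n_rows = n_bouts * rows_per_bout

            status_arr = np.full(n_rows, STATUS_SET_EMPTY, dtype=object)
            bad = rng.random(n_rows) < config.nonfunctional_rate
            status_arr[bad] = rng.choice(statuses_nonfunctional, bad.sum())
            functional = ~bad
            effort = int(functional.sum())

            taxon_arr = np.full(n_rows, "", dtype=object)
            tag_arr = np.full(n_rows, "", dtype=object)

            free = np.flatnonzero(functional)
            rng.shuffle(free)
            cursor = 0
            for sp in truth.species[site]:
                mu = effort * lam * truth.species_factor[(site, sp)]
                if config.overdispersion > 0:
                    shape = 1.0 / config.overdispersion
                    mu = mu * rng.gamma(shape, 1.0 / shape)
                n_ind = int(rng.poisson(mu))
                if n_ind == 0:
                    continue
                extra = np.minimum(rng.geometric(1.0 - config.recapture_rate,
                                                 n_ind) - 1, 3)
                events = 1 + extra
                total = int(events.sum())
                if cursor + total > len(free):
                    total = len(free) - cursor  # physically full (never hit
                    # at realistic rates); truncate the capture list
                    events = events[: np.searchsorted(np.cumsum(events),
                                                      total, side="right")]
                    n_ind = len(events)
                    total = int(events.sum())
                idx = free[cursor: cursor + total]
                cursor += total
                tags = np.repeat(
                    np.array(
                        [f"{site}_{sp}_{year}_{j:04d}" for j in range(n_ind)],
                        dtype=object,
                    ),
                    events,
                )
                status_arr[idx] = STATUS_CAPTURE
                taxon_arr[idx] = sp
                tag_arr[idx] = tags

            col_site.append(np.full(n_rows, site, dtype=object))
            col_plot.append(np.array(grid_ids, dtype=object)[plot_arr])
            col_date.append(dates_arr)
            col_status.append(status_arr)
            col_taxon.append(taxon_arr)
            col_tag.append(tag_arr)

    if not col_site:
        return pd.DataFrame(
            columns=["siteID", "plotID", "collectDate", "trapStatus",
                     "taxonID", "tagID"]
        )
    return pd.DataFrame(
        {
            "siteID": pd.Categorical(np.concatenate(col_site)),
            "plotID": pd.Categorical(np.concatenate(col_plot)),
            "collectDate": np.concatenate(col_date),
            "trapStatus": pd.Categorical(np.concatenate(col_status)),
            "taxonID": pd.Categorical(np.concatenate(col_taxon)),
            "tagID": np.concatenate(col_tag),
        }
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_truth(sites: pd.DataFrame, config: WorldConfig) -> GroundTruth:
    """Latent ground truth (dipole loadings, mast indices, expected rates)."""
    _, latent = _generate_climate(sites, config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[3]
    )
    return _build_truth(sites, latent, config, rng)


def simulate_world(config: WorldConfig | None = None, **kwargs) -> World:
    """Generate a complete world: sites, daily weather, trapping, truth."""
    if config is None:
        config = WorldConfig(**kwargs)
    elif kwargs:
        config = config.replace(**kwargs)
    sites = generate_sites(config)
    daily, latent = _generate_climate(sites, config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[3]
    )
    truth = _build_truth(sites, latent, config, rng)
    trapping = generate_trapping(sites, truth, config)
    return World(config=config, sites=sites, daily_climate=daily,
                 trapping=trapping, truth=truth)
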