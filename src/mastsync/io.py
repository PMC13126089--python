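"""Readers, writers, run configuration, and the end-to-end pipeline.

``run_all`` chains the six stages — simulate, index, climate, synchrony,
correlogram, MRM — writing every intermediate as plain CSV under one output
directory together with a JSON manifest (config hash, per-stage seeds, and
row counts in/out of every filter, so series attrition is auditable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import CLIMATE_VARIABLES, annual_climate, climate_series
from .correlogram import (DEFAULT_EDGES, DEFAULT_LEVEL, DEFAULT_N_BOOT,
                          CorrelogramResult, correlogram, distance_matrix)
from .mrm import (DEFAULT_N_PERM, proximity_from_distance, run_model_suite,
                  suite_table)
from .simulate import WorldConfig, simulate_world
from .synchrony import (DEFAULT_MIN_OVERLAP, build_matrix, conform_to_pairs)
from .trapping import (aggregate_site_series, build_population_series,
                       filter_series, low_capture_filter, series_table,
                       standardize_0_100)

logger = logging.getLogger(__name__)

TRAPPING_COLUMNS = ("siteID", "plotID", "collectDate", "trapStatus",
                    "taxonID", "tagID")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; YAML round-trippable."""

    out_dir: str = "mastsync_out"
    world: WorldConfig = field(default_factory=WorldConfig)
    min_consecutive_years: int = 4
    min_months_per_year: int = 4
    min_overlap: int = DEFAULT_MIN_OVERLAP
    edges: tuple = DEFAULT_EDGES
    n_boot: int = DEFAULT_N_BOOT
    level: float = DEFAULT_LEVEL
    n_perm: int = DEFAULT_N_PERM
    correlogram_seed: int = 1
    mrm_seed: int = 2
    block_bootstrap: bool = False
    include_same_site_pairs: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"]["missing_year_sites"] = [
            list(x) for x in self.world.missing_year_sites
        ]
        d["edges"] = list(self.edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        w = dict(d.pop("world", {}))
        if "missing_year_sites" in w:
            w["missing_year_sites"] = tuple(
                (str(s), int(y)) for s, y in w["missing_year_sites"]
            )
        if "edges" in d:
            d["edges"] = tuple(float(e) for e in d["edges"])
        return cls(world=WorldConfig(**w), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_trapping(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a trapping CSV into a validated record table.

    ``column_map`` renames source columns to the canonical schema (e.g. a
    real NEON export).  Rows with unparseable dates are dropped with a
    warning; missing mandatory columns raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trapping file lacks mandatory columns: {missing}")
    df = df[list(TRAPPING_COLUMNS)]
    dates = pd.to_datetime(df["collectDate"], errors="coerce")
    bad = dates.isna()
    if bad.any():
        logger.warning("dropping %d rows with unparseable dates",
                       int(bad.sum()))
        df = df[~bad]
        dates = dates[~bad]
    df = df.assign(collectDate=dates.to_numpy())
    return df.reset_index(drop=True)


def write_trapping(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["collectDate"] = pd.to_datetime(out["collectDate"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("siteID", "lat", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"sites file lacks columns: {missing}")
    return df


def read_daily_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in ("site", "date", "tmax", "tmin", "prcp")
               if c not in df.columns]
    if missing:
        raise ValueError(f"climate file lacks columns: {missing}")
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_matrix_long(matrix: pd.DataFrame, path,
                      value_name: str = "value") -> None:
    labels = list(matrix.index)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({"label_i": labels[i], "label_j": labels[j],
                         value_name: matrix.iat[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def write_correlogram(result: CorrelogramResult, path) -> None:
    result.bins.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def analyze_world(world, *, min_consecutive_years: int = 4,
                  min_months_per_year: int = 4,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  edges=DEFAULT_EDGES, n_boot: int = DEFAULT_N_BOOT,
                  level: float = DEFAULT_LEVEL,
                  n_perm: int = DEFAULT_N_PERM,
                  seed: int = 0, with_climate: bool = True) -> dict:
    """Run the analysis chain on an in-memory world; no files written.

    Returns a dict with the retained series, the mammal synchrony matrix,
    the mammal correlogram, the proximity matrix and the MRM suite (or the
    space-only model when ``with_climate`` is false).
    """
    series = build_population_series(
        world.trapping, analysis_years=world.config.analysis_years
    )
    kept, _ = filter_series(series, min_consecutive_years,
                            min_months_per_year)
    kept, _ = low_capture_filter(kept)
    if len(kept) < 2:
        raise ValueError("fewer than two series survive the filters")
    mam = build_matrix({s.label: s.index for s in kept},
                       min_overlap=min_overlap)
    series_to_site = {s.label: s.site for s in kept}
    dist_pair = conform_to_pairs(distance_matrix(world.sites), series_to_site)
    seeds = np.random.SeedSequence(seed).spawn(2)
    result = correlogram(mam.rho, dist_pair, edges=edges, n_boot=n_boot,
                         level=level, seed=np.random.default_rng(seeds[0]))
    proximity = proximity_from_distance(dist_pair)
    out = {
        "series": kept,
        "synchrony": mam,
        "distance_pairs": dist_pair,
        "proximity": proximity,
        "correlogram": result,
    }
    if with_climate:
        annual = annual_climate(world.daily_climate,
                                world.config.analysis_years)
        climate_pair = {
            var: conform_to_pairs(
                build_matrix(climate_series(annual, var),
                             min_overlap=min_overlap).rho,
                series_to_site,
            )
            for var in CLIMATE_VARIABLES
        }
        out["annual_climate"] = annual
        out["climate_pairs"] = climate_pair
        mrm_seed = int(seeds[1].generate_state(1)[0] % (2**31))
        out["fits"] = run_model_suite(mam.rho, proximity, climate_pair,
                                      n_perm=n_perm, seed=mrm_seed)
    else:
        from .mrm import mrm_fit
        out["fits"] = {
            "space": mrm_fit(mam.rho, {"proximity": proximity},
                             n_perm=n_perm,
                             seed=np.random.default_rng(seeds[1]),
                             name="space")
        }
    return out

def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline under ``config.out_dir``; return the manifest.

    Stages: simulate -> index -> climate -> synchrony -> correlogram -> mrm.
    Any stage failure aborts with the stage name; partial outputs stay on
    disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }
    stage = "simulate"
    try:
        world = simulate_world(config.world)
        world.sites.to_csv(out / "sites.csv", index=False)
        write_trapping(world.trapping, out / "trapping.csv")
        world.daily_climate.to_csv(out / "daily_climate.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps({
            "dipole_loading": dict(zip(world.truth.site_ids,
                                       world.truth.dipole_loading.tolist())),
            "common_mode": world.truth.common_mode.tolist(),
            "seed": config.world.seed,
        }, indent=1))
        manifest["stages"][stage] = {
            "seed": config.world.seed,
            "n_sites": int(len(world.sites)),
            "n_trap_rows": int(len(world.trapping)),
            "n_climate_rows": int(len(world.daily_climate)),
        }

        stage = "index"
        series = build_population_series(
            world.trapping, analysis_years=config.world.analysis_years
        )
        kept, quantity_report = filter_series(
            series, config.min_consecutive_years, config.min_months_per_year
        )
        kept, capture_report = low_capture_filter(kept)
        report = pd.concat(
            [quantity_report.assign(filter="data_quantity"),
             capture_report.assign(filter="low_capture")],
            ignore_index=True,
        )
        report.to_csv(out / "exclusions.csv", index=False)
        series_table(kept).to_csv(out / "population_series.csv", index=False)
        site_series = {}
        for site in sorted({s.site for s in kept}):
            agg = aggregate_site_series(kept, site)
            if agg.nunique() > 1:
                site_series[site] = agg
        std_rows = []
        for site, agg in site_series.items():
            std = standardize_0_100(agg)
            for year, v in std.items():
                std_rows.append({"site": site, "year": int(year),
                                 "standardized_index": v})
        pd.DataFrame(std_rows).to_csv(out / "standardized_site_series.csv",
                                      index=False, float_format="%.12g")
        manifest["stages"][stage] = {
            "n_series_in": len(series),
            "n_after_quantity_filter": int(quantity_report["retained"].sum()),
            "n_after_low_capture_filter": len(kept),
        }
        if len(kept) < 2:
            raise ValueError("fewer than two series survive the filters")

        stage = "climate"
        annual = annual_climate(world.daily_climate,
                                config.world.analysis_years)
        annual.to_csv(out / "annual_climate.csv", index=False,
                      float_format="%.12g")
        manifest["stages"][stage] = {"n_rows": int(len(annual))}

        stage = "synchrony"
        mam = build_matrix({s.label: s.index for s in kept},
                           min_overlap=config.min_overlap)
        write_matrix(mam.rho, out / "mammal_synchrony.csv")
        write_matrix_long(mam.rho, out / "mammal_synchrony_long.csv", "rho")
        series_to_site = {s.label: s.site for s in kept}
        climate_pair = {}
        for var in CLIMATE_VARIABLES:
            site_mat = build_matrix(climate_series(annual, var),
                                    min_overlap=config.min_overlap)
            climate_pair[var] = conform_to_pairs(site_mat.rho, series_to_site)
            write_matrix(climate_pair[var],
                         out / f"climate_synchrony_{var}.csv")
        manifest["stages"][stage] = {
            "n_series": len(kept),
            "n_pairs": len(kept) * (len(kept) - 1) // 2,
        }

        stage = "correlogram"
        dist_site = distance_matrix(world.sites)
        dist_pair = conform_to_pairs(dist_site, series_to_site)
        result = correlogram(mam.rho, dist_pair, edges=config.edges,
                             n_boot=config.n_boot, level=config.level,
                             seed=config.correlogram_seed,
                             site_of=series_to_site,
                             block_by_site=config.block_bootstrap)
        write_correlogram(result, out / "correlogram_mammal.csv")
        for var in CLIMATE_VARIABLES:
            r = correlogram(climate_pair[var], dist_pair, edges=config.edges,
                            n_boot=config.n_boot, level=config.level,
                            seed=config.correlogram_seed)
            write_correlogram(r, out / f"correlogram_{var}.csv")
        (out / "within_site_synchrony.json").write_text(
            json.dumps(result.within_site, indent=1)
        )
        manifest["stages"][stage] = {
            "seed": config.correlogram_seed,
            "n_pairs_binned": int(result.bins["n_pairs"].sum()),
            "n_within_site_pairs": result.within_site["n"],
        }

        stage = "mrm"
        proximity = proximity_from_distance(dist_pair)
        response = mam.rho
        if not config.include_same_site_pairs:
            from .mrm import exclude_same_site_pairs
            response = exclude_same_site_pairs(response, series_to_site)
        fits = run_model_suite(response, proximity, climate_pair,
                               n_perm=config.n_perm, seed=config.mrm_seed)
        table = suite_table(fits)
        table.to_csv(out / "mrm_table.csv", index=False,
                     float_format="%.12g")
        (out / "mrm_fits.json").write_text(json.dumps({
            m: {
                "coefficients": f.coefficients,
                "coefficient_p": f.coefficient_p,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "model_p": f.model_p,
                "n_pairs": f.n_pairs,
            } for m, f in fits.items()
        }, indent=1))
        manifest["stages"][stage] = {
            "seed": config.mrm_seed,
            "n_perm": config.n_perm,
            "models": list(fits),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
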