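import numpy as np
import pandas as pd
import pytest

from mastsync import WorldConfig, simulate_world
from mastsync.simulate import (STATUS_CAPTURE, STATUS_DISTURBED,
                               STATUS_SET_EMPTY)


def make_records(rows):
    """Build a trapping record table from (site, plot, date, status, taxon,
    tag) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["siteID", "plotID", "collectDate", "trapStatus", "taxonID",
                 "tagID"],
    )
    df["collectDate"] = pd.to_datetime(df["collectDate"])
    return df


def trap_night_rows(site, year, month, n_set, n_disturbed=0, day=10,
                    plot="G00"):
    """n_set functional empty trap-nights plus n_disturbed bad ones."""
    date = f"{year}-{month:02d}-{day:02d}"
    rows = [(site, plot, date, STATUS_SET_EMPTY, "", "")] * n_set
    rows += [(site, plot, date, STATUS_DISTURBED, "", "")] * n_disturbed
    return rows


def capture_row(site, year, month, species, tag, day=10, plot="G00"):
    return (site, plot, f"{year}-{month:02d}-{day:02d}", STATUS_CAPTURE,
            species, tag)


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by read-only tests: 6 sites, light trapping."""
    cfg = WorldConfig(n_sites=6, traps_per_grid=20, grids_min=3, grids_max=4,
                      missing_year_sites=(), seed=11)
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    """One full-size default world (23 sites) reused by read-only tests."""
    return simulate_world(WorldConfig(seed=7))
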