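"""Pairwise Spearman synchrony matrices between annual time series.

Synchrony between two populations (or two sites' climate series) is the
Spearman rank correlation of their annual values over the years both were
observed (pairwise-complete; no imputation).  Pairs with too short an
overlap, or with a constant series on the overlap, are missing rather than
zero.  Site-level matrices (climate synchrony, distance, proximity) can be
conformed to the population-series pair space, where two species at the same
site receive the site's self-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_OVERLAP = 4


@dataclass
class SynchronyMatrix:
    """Labeled symmetric Spearman matrix with per-pair overlap lengths."""

    rho: pd.DataFrame
    overlap: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.rho.index)

    def pairs(self) -> pd.DataFrame:
        """Long format: one row per unordered off-diagonal pair."""
        labels = self.labels
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append(
                    {
                        "label_i": labels[i],
                        "label_j": labels[j],
                        "rho": self.rho.iat[i, j],
                        "overlap": self.overlap.iat[i, j],
                    }
                )
        return pd.DataFrame(rows)


def spearman(x: pd.Series, y: pd.Series,
             min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Spearman rho on the shared years of two annual series.

    Average ranks for ties.  Returns NaN when fewer than ``min_overlap``
    years are shared or either series is constant on the overlap.
    """
    common = x.index.intersection(y.index)
    if len(common) < min_overlap:
        return float("nan")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    return float(stats.spearmanr(xv, yv).statistic)


def build_matrix(series: Mapping[str, pd.Series],
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> SynchronyMatrix:
    """All-pairs Spearman matrix over a labeled set of annual series."""
    labels = list(series.keys())
    if len(labels) < 2:
        raise ValueError("need at least two series")
    n = len(labels)
    rho = np.eye(n)
    ov = np.zeros((n, n), dtype=int)
    for i in range(n):
        ov[i, i] = len(series[labels[i]])
        for j in range(i + 1, n):
            si, sj = series[labels[i]], series[labels[j]]
            common = si.index.intersection(sj.index)
            ov[i, j] = ov[j, i] = len(common)
            r = spearman(si, sj, min_overlap)
            rho[i, j] = rho[j, i] = r
    return SynchronyMatrix(
        rho=pd.DataFrame(rho, index=labels, columns=labels),
        overlap=pd.DataFrame(ov, index=labels, columns=labels),
    )


def conform_to_pairs(site_matrix: pd.DataFrame,
                     series_to_site: Mapping[str, str]) -> pd.DataFrame:
    """Expand a site-level matrix to the population-series pair space.

    Entry (series_i, series_j) is the site-matrix entry for their sites;
    same-site pairs receive the site matrix's diagonal value (1 for a
    synchrony or proximity matrix, 0 for a distance matrix).
    """
    sites = set(site_matrix.index.astype(str))
    unmapped = [s for s, st in series_to_site.items() if str(st) not in sites]
    if unmapped:
        raise KeyError(
            f"series with no site in the matrix: {sorted(unmapped)}"
        )
    labels = list(series_to_site.keys())
    site_of = [str(series_to_site[s]) for s in labels]
    values = site_matrix.loc[site_of, site_of].to_numpy(dtype=float)
    return pd.DataFrame(values, index=labels, columns=labels)
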