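"""Multiple regression on distance matrices (MRM) with permutation tests.

MRM regresses the unfolded lower triangle of a response matrix (here,
pairwise population synchrony) on the unfolded lower triangles of predictor
matrices (site proximity and climate-variable synchrony) by ordinary least
squares.  Because every series enters many pairs, the usual OLS inference is
invalid; significance instead comes from jointly permuting the rows and
columns of the response matrix with the same random relabeling and refitting
— the classical Mantel-family null of exchangeable labels.  Coefficient
p-values are two-tailed on |b|; the whole-model p-value uses R^2.

The standard four-model suite:

* ``space``      — proximity only
* ``direct``     — current-year climate synchrony (July temperature, June
  precipitation, January temperature, January precipitation)
* ``indirect``   — synchrony in the July-temperature differential (the
  mast-seeding surrogate) only
* ``saturated``  — all six predictors
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import CLIMATE_LABELS

DEFAULT_N_PERM = 1000
_CONDITION_LIMIT = 1e8

#: Predictor sets of the four-model suite, in reporting order.
MODEL_SUITE = {
    "space": ("proximity",),
    "direct": ("july_temp", "june_precip", "january_temp", "january_precip"),
    "indirect": ("delta_t",),
    "saturated": ("proximity", "july_temp", "june_precip", "january_temp",
                  "january_precip", "delta_t"),
}


def vectorize_lower(matrix: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Unfold a labeled symmetric matrix into its off-diagonal pairs.

    Returns (values, pairs) where pairs is the canonical list of unordered
    label pairs (i < j in the matrix's label order).  Missing entries stay
    NaN and propagate to case-wise deletion downstream.
    """
    labels = list(matrix.index)
    if list(matrix.columns) != labels:
        raise ValueError("matrix rows and columns must carry the same labels")
    m = matrix.to_numpy(dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return m[iu], pairs


def refold(values: np.ndarray, labels: Sequence) -> pd.DataFrame:
    """Inverse of :func:`vectorize_lower` (diagonal set to NaN)."""
    n = len(labels)
    m = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    m[(iu[1], iu[0])] = values
    return pd.DataFrame(m, index=list(labels), columns=list(labels))


def proximity_from_distance(distances: pd.DataFrame) -> pd.DataFrame:
    """Scale distances to proximity in [0, 1]: ``1 - d / d_max``.

    ``d_max`` is the largest observed between-site distance, so the most
    distant pair maps to 0 and same-site pairs map to 1.
    """
    d = distances.to_numpy(dtype=float)
    d_max = np.nanmax(d)
    if d_max <= 0:
        raise ValueError("need at least one positive distance")
    return pd.DataFrame(1.0 - d / d_max, index=distances.index,
                        columns=distances.columns)


def exclude_same_site_pairs(matrix: pd.DataFrame,
                            series_to_site: Mapping[str, str]) -> pd.DataFrame:
    """Mask same-site species pairs (set to missing) in a pair-space matrix.

    Same-site pairs carry proximity 1 and climate synchrony 1 by
    construction; masking the response before fitting removes them from the
    regression via case-wise deletion.
    """
    out = matrix.copy()
    site = np.array([str(series_to_site[l]) for l in out.index], dtype=object)
    same = site[:, None] == site[None, :]
    np.fill_diagonal(same, False)
    vals = out.to_numpy(dtype=float)
    vals[same] = np.nan
    return pd.DataFrame(vals, index=out.index, columns=out.columns)


@dataclass
class MRMFit:
    """One fitted MRM model with permutation inference."""

    name: str
    predictors: list
    coefficients: dict          # predictor -> OLS coefficient
    coefficient_p: dict         # predictor -> two-tailed permutation p
    intercept: float
    r_squared: float
    model_p: float
    n_pairs: int
    n_perm: int
    seed: object = None
    standardized_coefficients: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.name,
                "variable": CLIMATE_LABELS.get(p, p),
                "coefficient": self.coefficients[p],
                "p_variable": self.coefficient_p[p],
                "p_model": self.model_p,
            }
            for p in self.predictors
        ]
        return pd.DataFrame(rows)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, r2


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] < 2:
        return
    if np.linalg.cond(X - X.mean(axis=0)) < _CONDITION_LIMIT:
        return
    corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
    raise ValueError(
        f"collinear predictors: {names[i]!r} and {names[j]!r} "
        f"(|r| = {abs(corr[i, j]):.4f})"
    )


def mrm_fit(response: pd.DataFrame,
            predictors: Mapping[str, pd.DataFrame],
            n_perm: int = DEFAULT_N_PERM,
            seed=None,
            name: str = "mrm",
            exact: bool = False) -> MRMFit:
    """Fit one MRM model.

    Parameters
    ----------
    response, predictors
        Square symmetric matrices over identical labels.  Pairs missing in
        any matrix are dropped case-wise.
    n_perm
        Number of random label permutations for the null distribution.
        p-values use the add-one rule (observed counted among the
        permutations), so p >= 1/(n_perm + 1).
    exact
        Enumerate all label permutations instead of sampling (feasible for
        small label sets only); p = #{permuted statistic >= observed} / n!
        with the identity permutation included.
    """
    labels = list(response.index)
    names = list(predictors.keys())
    y_full, _ = vectorize_lower(response)
    cols = []
    for nm, mat in predictors.items():
        if list(mat.index) != labels:
            raise ValueError(
                f"predictor {nm!r} labels do not match the response"
            )
        v, _ = vectorize_lower(mat)
        cols.append(v)
    Xp = np.column_stack(cols)

    pred_ok = np.all(np.isfinite(Xp), axis=1)
    obs_mask = pred_ok & np.isfinite(y_full)
    n_cases = int(obs_mask.sum())
    if n_cases <= Xp.shape[1] + 1:
        raise ValueError("not enough complete pairs to fit the model")
    _check_collinearity(Xp[obs_mask], names)

    def fit(y_vec):
        m = pred_ok & np.isfinite(y_vec)
        X = np.column_stack([np.ones(int(m.sum())), Xp[m]])
        return _ols(X, y_vec[m])

    beta_obs, r2_obs = fit(y_full)

    n = len(labels)
    R = response.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)

    if exact:
        perms = itertools.permutations(range(n))
        total = math.factorial(n)
        count_coef = np.zeros(Xp.shape[1])
        count_model = 0
        for perm in perms:
            p = np.array(perm)
            yp = R[np.ix_(p, p)][iu]
            b, r2 = fit(yp)
            count_coef += np.abs(b[1:]) >= np.abs(beta_obs[1:]) - 1e-12
            count_model += r2 >= r2_obs - 1e-12
        coef_p = count_coef / total
        model_p = count_model / total
        n_perm_used = total
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        count_coef = np.zeros(Xp.shape[1])
        count_model = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            yp = R[np.ix_(p, p)][iu]
            b, r2 = fit(yp)
            count_coef += np.abs(b[1:]) >= np.abs(beta_obs[1:])
            count_model += r2 >= r2_obs
        coef_p = (count_coef + 1.0) / (n_perm + 1.0)
        model_p = (count_model + 1.0) / (n_perm + 1.0)
        n_perm_used = n_perm

    # standardized (beta) coefficients on z-scored pair values, reported
    # alongside the raw-scale ones
    y_obs = y_full[obs_mask]
    sx = Xp[obs_mask].std(axis=0, ddof=1)
    sy = y_obs.std(ddof=1)
    std_coef = beta_obs[1:] * sx / sy if sy > 0 else beta_obs[1:] * np.nan

    return MRMFit(
        name=name,
        predictors=names,
        coefficients={nm: float(b) for nm, b in zip(names, beta_obs[1:])},
        standardized_coefficients={
            nm: float(b) for nm, b in zip(names, std_coef)
        },
        coefficient_p={nm: float(p) for nm, p in zip(names, coef_p)},
        intercept=float(beta_obs[0]),
        r_squared=float(r2_obs),
        model_p=float(model_p),
        n_pairs=n_cases,
        n_perm=n_perm_used,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def run_model_suite(response: pd.DataFrame,
                    proximity: pd.DataFrame,
                    climate_synchrony: Mapping[str, pd.DataFrame],
                    n_perm: int = DEFAULT_N_PERM,
                    seed=None) -> dict[str, MRMFit]:
    """Fit the four standard models against one response matrix.

    ``climate_synchrony`` maps the five annual climate variable names to
    series-pair-conformed synchrony matrices.  Each model gets its own
    deterministic child seed.
    """
    pool: dict[str, pd.DataFrame] = {"proximity": proximity,
                                     **dict(climate_synchrony)}
    missing = [
        v for preds in MODEL_SUITE.values() for v in preds if v not in pool
    ]
    if missing:
        raise KeyError(f"missing predictor matrices: {sorted(set(missing))}")
    children = np.random.SeedSequence(seed).spawn(len(MODEL_SUITE))
    fits = {}
    for child, (model, preds) in zip(children, MODEL_SUITE.items()):
        fits[model] = mrm_fit(
            response,
            {p: pool[p] for p in preds},
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            name=model,
        )
    return fits


def suite_table(fits: Mapping[str, MRMFit]) -> pd.DataFrame:
    """Stack the suite into a report table: 1+4+1+6 coefficient rows."""
    frames = [fits[m].to_frame() for m in MODEL_SUITE if m in fits]
    return pd.concat(frames, ignore_index=True)
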