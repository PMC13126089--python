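"""Matrix regression: unfolding, OLS recovery, permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mastsync.mrm import (MODEL_SUITE, exclude_same_site_pairs, mrm_fit,
                          proximity_from_distance, refold, run_model_suite,
                          suite_table, vectorize_lower)


def sym_matrix(values, labels):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    m += m.T
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=labels, columns=labels)


def random_sym(labels, rng, diag=1.0):
    n = len(labels)
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, diag)
    return pd.DataFrame(m, index=labels, columns=labels)


class TestVectorize:
    def test_pair_count(self):
        labels = list("abc")
        v, pairs = vectorize_lower(sym_matrix([1, 2, 3], labels))
        assert len(v) == len(pairs) == 3
        n = 70
        big = sym_matrix(np.arange(n * (n - 1) // 2), [f"s{i}" for i in
                                                       range(n)])
        v, pairs = vectorize_lower(big)
        assert len(v) == 2415

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        labels = [f"s{i}" for i in range(6)]
        m = random_sym(labels, rng)
        v, _ = vectorize_lower(m)
        back = refold(v, labels)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(m.to_numpy()[off], back.to_numpy()[off])

    def test_label_mismatch_rejected(self):
        m = sym_matrix([1, 2, 3], list("abc"))
        bad = m.copy()
        bad.columns = list("abd")
        with pytest.raises(ValueError):
            vectorize_lower(bad)


class TestProximity:
    def test_scaling_to_unit_interval(self):
        labels = list("abc")
        d = pd.DataFrame(
            [[0.0, 1000.0, 4000.0], [1000.0, 0.0, 2000.0],
             [4000.0, 2000.0, 0.0]],
            index=labels, columns=labels,
        )
        p = proximity_from_distance(d)
        assert p.loc["a", "c"] == 0.0        # most distant pair
        assert p.loc["a", "a"] == 1.0        # same site
        assert p.loc["a", "b"] == pytest.approx(0.75)


class TestFit:
    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(3)
        labels = [f"s{i}" for i in range(8)]
        x = random_sym(labels, rng)
        y = pd.DataFrame(1.0 + 2.0 * x.to_numpy(), index=labels,
                         columns=labels)
        fit = mrm_fit(y, {"x": x}, n_perm=9, seed=0)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        labels = [f"s{i}" for i in range(7)]
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        fit = mrm_fit(y, {"x": x}, n_perm=9, seed=0)
        xv, _ = vectorize_lower(x)
        yv, _ = vectorize_lower(y)
        expected = np.cov(xv, yv)[0, 1] / np.var(xv, ddof=1)
        assert fit.coefficients["x"] == pytest.approx(expected, abs=1e-10)

    def test_permutation_p_matches_exact_enumeration(self):
        # Independent oracle: enumerate all 4! = 24 joint row/column
        # permutations of the response and count extreme statistics.
        rng = np.random.default_rng(11)
        labels = list("abcd")
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        fit = mrm_fit(y, {"x": x}, exact=True)

        xv, _ = vectorize_lower(x)
        X = np.column_stack([np.ones(6), xv])
        Y = y.to_numpy()
        iu = np.triu_indices(4, k=1)
        beta_obs = np.linalg.solve(X.T @ X, X.T @ Y[iu])
        resid = Y[iu] - X @ beta_obs
        r2_obs = 1 - (resid @ resid) / ((Y[iu] - Y[iu].mean()) ** 2).sum()
        count_b = count_r = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            yp = Y[np.ix_(p, p)][iu]
            b = np.linalg.solve(X.T @ X, X.T @ yp)
            res = yp - X @ b
            r2 = 1 - (res @ res) / ((yp - yp.mean()) ** 2).sum()
            count_b += abs(b[1]) >= abs(beta_obs[1]) - 1e-12
            count_r += r2 >= r2_obs - 1e-12
        assert fit.coefficient_p["x"] == pytest.approx(count_b / 24)
        assert fit.model_p == pytest.approx(count_r / 24)
        assert fit.n_perm == 24

    def test_permutation_p_invariant_to_relabeling(self):
        rng = np.random.default_rng(9)
        labels = list("abcde")
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        fit1 = mrm_fit(y, {"x": x}, exact=True)
        perm = [3, 1, 4, 0, 2]
        y2 = pd.DataFrame(y.to_numpy()[np.ix_(perm, perm)], index=labels,
                          columns=labels)
        x2 = pd.DataFrame(x.to_numpy()[np.ix_(perm, perm)], index=labels,
                          columns=labels)
        fit2 = mrm_fit(y2, {"x": x2}, exact=True)
        assert fit1.coefficient_p["x"] == pytest.approx(
            fit2.coefficient_p["x"]
        )
        assert fit1.model_p == pytest.approx(fit2.model_p)

    def test_monte_carlo_converges_to_enumeration(self):
        rng = np.random.default_rng(21)
        labels = list("abcde")
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        exact = mrm_fit(y, {"x": x}, exact=True)
        mc = mrm_fit(y, {"x": x}, n_perm=4000, seed=5)
        se = np.sqrt(exact.model_p * (1 - exact.model_p) / 4000)
        assert abs(mc.model_p - exact.model_p) < 4 * se + 2 / 4000

    def test_collinear_predictors_rejected_by_name(self):
        rng = np.random.default_rng(6)
        labels = [f"s{i}" for i in range(6)]
        x = random_sym(labels, rng)
        x2 = pd.DataFrame(2.0 * x.to_numpy(), index=labels, columns=labels)
        y = random_sym(labels, rng)
        with pytest.raises(ValueError, match="collinear"):
            mrm_fit(y, {"a": x, "b": x2}, n_perm=9, seed=0)

    def test_same_site_pairs_can_be_excluded(self):
        rng = np.random.default_rng(15)
        labels = ["A:1", "A:2", "B:1", "C:1"]
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        masked = exclude_same_site_pairs(
            y, {"A:1": "A", "A:2": "A", "B:1": "B", "C:1": "C"}
        )
        assert np.isnan(masked.loc["A:1", "A:2"])
        fit = mrm_fit(masked, {"x": x}, n_perm=9, seed=0)
        assert fit.n_pairs == 6 - 1

    def test_standardized_coefficients_are_scale_free(self):
        rng = np.random.default_rng(16)
        labels = [f"s{i}" for i in range(8)]
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        fit1 = mrm_fit(y, {"x": x}, n_perm=9, seed=0)
        x10 = pd.DataFrame(10.0 * x.to_numpy(), index=labels, columns=labels)
        fit2 = mrm_fit(y, {"x": x10}, n_perm=9, seed=0)
        assert fit1.standardized_coefficients["x"] == pytest.approx(
            fit2.standardized_coefficients["x"]
        )
        assert fit1.coefficients["x"] == pytest.approx(
            10.0 * fit2.coefficients["x"]
        )

    def test_missing_response_pairs_are_dropped_casewise(self):
        rng = np.random.default_rng(13)
        labels = [f"s{i}" for i in range(8)]
        x = random_sym(labels, rng)
        y = random_sym(labels, rng)
        y.iloc[0, 1] = y.iloc[1, 0] = np.nan
        fit = mrm_fit(y, {"x": x}, n_perm=9, seed=0)
        assert fit.n_pairs == 8 * 7 // 2 - 1


class TestSuite:
    def _inputs(self, rng, n=8):
        labels = [f"S{i:02d}:sp" for i in range(n)]
        resp = random_sym(labels, rng)
        dist = random_sym(labels, rng, diag=0.0).abs() * 2000
        prox = proximity_from_distance(dist)
        climate = {
            v: random_sym(labels, rng)
            for v in ("july_temp", "june_precip", "january_temp",
                      "january_precip", "delta_t")
        }
        return resp, prox, climate

    def test_four_models_with_the_standard_predictor_sets(self):
        rng = np.random.default_rng(2)
        resp, prox, climate = self._inputs(rng)
        fits = run_model_suite(resp, prox, climate, n_perm=19, seed=0)
        assert set(fits) == {"space", "direct", "indirect", "saturated"}
        assert fits["space"].predictors == ["proximity"]
        assert fits["indirect"].predictors == ["delta_t"]
        assert len(fits["direct"].predictors) == 4
        assert len(fits["saturated"].predictors) == 6
        table = suite_table(fits)
        assert len(table) == 1 + 4 + 1 + 6

    def test_response_equal_to_proximity_has_unit_r_squared(self):
        rng = np.random.default_rng(14)
        resp, prox, climate = self._inputs(rng)
        fits = run_model_suite(prox, prox, climate, n_perm=19, seed=0)
        assert fits["space"].r_squared == pytest.approx(1.0, abs=1e-10)
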