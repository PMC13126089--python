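"""Abundance-index construction and the inclusion/exclusion filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mastsync import WorldConfig, simulate_world
from mastsync.trapping import (PopulationSeries, aggregate_site_series,
                               build_index, build_population_series,
                               compute_effort, count_unique_individuals,
                               filter_series, low_capture_filter,
                               standardize_0_100)

from conftest import capture_row, make_records, trap_night_rows


def series_from_counts(site, species, years, counts, effort=100, n_months=4):
    data = pd.DataFrame(
        {
            "count": counts,
            "trap_nights": effort,
            "index": np.asarray(counts) / effort,
            "n_months": n_months,
        },
        index=pd.Index(years, name="year"),
    )
    return PopulationSeries(site, species, data)


class TestCounting:
    def test_one_individual_in_three_bouts_counts_once(self):
        rows = [capture_row("A", 2015, m, "PELE", "tag1") for m in (5, 6, 7)]
        recs = make_records(rows)
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 1

    def test_same_tag_in_two_years_counts_in_each(self):
        rows = [
            capture_row("A", 2015, 5, "PELE", "tagA"),
            capture_row("A", 2015, 6, "PELE", "tagB"),
            capture_row("A", 2016, 5, "PELE", "tagA"),
        ]
        recs = make_records(rows)
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 2
        assert count_unique_individuals(recs, "A", "PELE", 2016) == 1

    def test_no_captures_is_zero(self):
        recs = make_records(trap_night_rows("A", 2015, 5, 10))
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 0

    def test_duplicated_rows_leave_counts_unchanged(self):
        rows = [capture_row("A", 2015, 5, "PELE", "tag1")]
        recs = make_records(rows + rows + rows)
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 1

    def test_tag_species_conflict_resolved_by_majority(self):
        rows = [
            capture_row("A", 2015, 5, "PELE", "tagX"),
            capture_row("A", 2015, 6, "PELE", "tagX"),
            capture_row("A", 2015, 7, "PEMA", "tagX"),
        ]
        recs = make_records(rows)
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 1
        assert count_unique_individuals(recs, "A", "PEMA", 2015) == 0

    def test_tag_species_tie_excludes_the_tag(self):
        rows = [
            capture_row("A", 2015, 5, "PELE", "tagX"),
            capture_row("A", 2015, 7, "PEMA", "tagX"),
        ]
        recs = make_records(rows)
        assert count_unique_individuals(recs, "A", "PELE", 2015) == 0
        assert count_unique_individuals(recs, "A", "PEMA", 2015) == 0


class TestEffort:
    def test_all_functional_rows_count(self):
        rows = []
        for day in (10, 11, 12):
            rows += trap_night_rows("A", 2015, 6, 100, day=day)
        recs = make_records(rows)
        assert compute_effort(recs, "A", 2015) == 300

    def test_disturbed_rows_are_excluded(self):
        rows = trap_night_rows("A", 2015, 6, 290, n_disturbed=10)
        recs = make_records(rows)
        assert compute_effort(recs, "A", 2015) == 290

    def test_missing_site_year_raises(self):
        recs = make_records(trap_night_rows("A", 2015, 6, 10))
        with pytest.raises(ValueError):
            compute_effort(recs, "A", 2016)

    def test_records_without_functional_traps_raise(self):
        recs = make_records(trap_night_rows("A", 2015, 6, 0, n_disturbed=5))
        with pytest.raises(ValueError, match="zero functional"):
            compute_effort(recs, "A", 2015)


class TestIndex:
    def test_index_is_count_over_effort(self):
        idx = build_index(pd.Series({2015: 12}), pd.Series({2015: 400}))
        assert idx[2015] == pytest.approx(0.03)
        idx0 = build_index(pd.Series({2015: 0}), pd.Series({2015: 300}))
        assert idx0[2015] == 0.0

    def test_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            build_index(pd.Series({2015: 10}), pd.Series({2015: 0}))

    def test_index_invariant_to_splitting_records_across_bouts(self):
        one_bout = make_records(
            trap_night_rows("A", 2015, 5, 99)
            + [capture_row("A", 2015, 5, "PELE", "t1")]
        )
        split = make_records(
            trap_night_rows("A", 2015, 5, 49)
            + trap_night_rows("A", 2015, 8, 50)
            + [capture_row("A", 2015, 8, "PELE", "t1")]
        )
        s1 = build_population_series(one_bout)[0]
        s2 = build_population_series(split)[0]
        assert s1.index[2015] == s2.index[2015] == 1 / 100

    def test_index_tracks_the_latent_rate_on_synthetic_worlds(self):
        # Spearman(index, lambda) > 0.8 for well-sampled series in at least
        # 90% of replicates.
        ok = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = WorldConfig(n_sites=2, species_min=1, species_max=1,
                              traps_per_grid=30, missing_year_sites=(),
                              alpha0=-4.0, seed=1000 + seed)
            world = simulate_world(cfg)
            series = build_population_series(
                world.trapping, analysis_years=cfg.analysis_years
            )
            good = True
            for s in series:
                if s.counts.mean() < 10:
                    continue
                lam = world.truth.rate_series(s.site, s.species)
                common = s.index.index.intersection(lam.index)
                r = stats.spearmanr(s.index.loc[common],
                                    lam.loc[common]).statistic
                if r <= 0.8:
                    good = False
            ok += good
        assert ok >= 0.9 * n_rep


class TestFilters:
    def test_four_consecutive_qualifying_years_retained(self):
        s = series_from_counts("A", "PELE", [2013, 2014, 2015, 2016],
                               [5, 6, 7, 8])
        kept, report = filter_series([s])
        assert len(kept) == 1
        assert report["retained"].all()

    def test_gap_breaks_the_run(self):
        s = series_from_counts("A", "PELE", [2013, 2014, 2016, 2017],
                               [5, 6, 7, 8])
        kept, report = filter_series([s])
        assert kept == []
        assert not report["retained"].any()

    def test_years_with_too_few_months_do_not_qualify(self):
        data = pd.DataFrame(
            {
                "count": [5, 5, 5, 5, 5],
                "trap_nights": 100,
                "index": 0.05,
                "n_months": [4, 4, 3, 4, 4],
            },
            index=pd.Index(range(2013, 2018), name="year"),
        )
        s = PopulationSeries("A", "PELE", data)
        kept, _ = filter_series([s])
        assert kept == []  # longest qualifying run is 2 years

    def test_series_truncated_to_longest_run_prefers_recent_ties(self):
        years = list(range(2013, 2022))
        n_months = [4, 4, 4, 4, 3, 4, 4, 4, 4]  # two 4-year runs
        data = pd.DataFrame(
            {"count": 5, "trap_nights": 100, "index": 0.05,
             "n_months": n_months},
            index=pd.Index(years, name="year"),
        )
        kept, _ = filter_series([PopulationSeries("A", "PELE", data)])
        assert list(kept[0].years) == [2018, 2019, 2020, 2021]

    def test_low_capture_rule(self):
        dropped = series_from_counts("A", "PELE", range(2013, 2017),
                                     [1, 0, 1, 1])
        kept_s = series_from_counts("B", "PELE", range(2013, 2017),
                                    [1, 1, 5, 0])
        single = series_from_counts("C", "PELE", [2013], [1])
        kept, report = low_capture_filter([dropped, kept_s, single])
        assert [s.site for s in kept] == ["B", "C"]
        assert list(report["retained"]) == [False, True, True]

    def test_filter_report_accounts_for_every_series(self):
        series = [
            series_from_counts("A", "PELE", range(2013, 2018), [3] * 5),
            series_from_counts("A", "PEMA", [2013, 2015], [3, 3]),
        ]
        kept, report = filter_series(series)
        assert len(report) == len(series)
        assert report["retained"].sum() == len(kept)


class TestAggregationAndStandardization:
    def test_site_sum_over_species(self):
        a = series_from_counts("A", "PELE", [2015], [4], effort=200)
        b = series_from_counts("A", "PEMA", [2015], [2], effort=200)
        agg = aggregate_site_series([a, b], "A")
        assert agg[2015] == pytest.approx(6 / 200)

    def test_single_species_is_identity(self):
        a = series_from_counts("A", "PELE", [2015, 2016], [4, 8])
        agg = aggregate_site_series([a], "A")
        pd.testing.assert_series_equal(agg, a.index, check_names=False)

    def test_summing_indices_equals_summing_counts_then_dividing(self):
        a = series_from_counts("A", "PELE", [2015], [4], effort=300)
        b = series_from_counts("A", "PEMA", [2015], [2], effort=300)
        agg = aggregate_site_series([a, b], "A")
        assert agg[2015] == pytest.approx(6 / 300)

    def test_standardize_0_100(self):
        out = standardize_0_100(pd.Series([2.0, 4.0, 6.0]))
        assert list(out) == [0.0, 50.0, 100.0]

    def test_standardize_rejects_constant_series(self):
        with pytest.raises(ValueError):
            standardize_0_100(pd.Series([5.0, 5.0]))

    def test_standardize_preserves_rank_order(self):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(size=12))
        out = standardize_0_100(s)
        assert stats.spearmanr(s, out).statistic == pytest.approx(1.0)
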