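"""Rates, comparisons, criteria and case studies against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdmorph.errors import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDesignError,
)
from rdmorph.phantom import CohortDesign, published_cohort_design, generate_cohort_table
from rdmorph.stats import (
    ALPHA,
    compare_groups,
    evaluate_criteria,
    fit_rate,
    normalize_to_attached,
    normalized_group_mean,
    ols_slope_closed_form,
    rate_from_day_means,
    run_case_study,
    tukey_hsd,
)


def cohort_from_cells(cells, n=6, seed=0):
    """cells: {(region, day): (count_mean, count_sd, ratio_mean, ratio_sd)}"""
    rows = [
        dict(region=r, day=d, count_mean=cm, count_sd=cs,
             ratio_mean=rm, ratio_sd=rs, n=n)
        for (r, d), (cm, cs, rm, rs) in cells.items()
    ]
    return generate_cohort_table(CohortDesign(pd.DataFrame(rows)), seed)


# ---------------------------------------------------------------------------
# rate regression
# ---------------------------------------------------------------------------


class TestRates:
    def test_study_day_means_reproduce_reported_rates(self):
        apex_counts = {0: 1264.00, 1: 984.40, 7: 785.80, 14: 709.20}
        apex_ratio = {0: 1.98, 1: 1.36, 7: 1.05, 14: 1.08}
        assert round(rate_from_day_means(apex_counts), 2) == -33.40
        assert round(rate_from_day_means(apex_ratio), 2) == -0.05

    def test_flat_metric_slope_zero(self):
        cohort = cohort_from_cells(
            {("detached_apex", d): (1000.0, 0.0, 2.0, 0.0) for d in (0, 1, 7, 14)}
        )
        r = fit_rate(cohort, "detached_apex", "onl_count")
        assert r.slope_per_day == pytest.approx(0.0, abs=1e-9)
        assert r.p_value > 0.9  # no trend to detect

    def test_exact_line_recovered(self):
        days = [0, 1, 7, 14]
        rows = [
            dict(animal_id=f"d{d}_a{i}", day=d, region="detached_apex",
                 onl_count=100.0 - 5.0 * d, onl_inl_ratio=1.0)
            for d in days for i in range(3)
        ]
        r = fit_rate(pd.DataFrame(rows), "detached_apex", "onl_count")
        assert r.slope_per_day == pytest.approx(-5.0, abs=1e-9)
        assert r.p_value < 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ys=st.lists(
            st.floats(min_value=-1e4, max_value=1e4), min_size=6, max_size=24
        )
    )
    def test_ols_slope_matches_closed_form(self, ys):
        """The fitted slope always equals sum((x-x̄)(y-ȳ))/sum((x-x̄)^2)."""
        days = np.tile([0, 1, 7], int(np.ceil(len(ys) / 3)))[: len(ys)]
        df = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(len(ys))],
            "day": days, "region": "detached_apex",
            "onl_count": np.abs(ys), "onl_inl_ratio": 1.0,
        })
        r = fit_rate(df, "detached_apex", "onl_count")
        expected = ols_slope_closed_form(days, np.abs(ys))
        assert r.slope_per_day == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_per_sample_equals_day_means_with_equal_n(self):
        cohort = generate_cohort_table(published_cohort_design(6), 3)
        r = fit_rate(cohort, "detached_apex", "onl_count")
        means = (
            cohort[cohort.region == "detached_apex"]
            .groupby("day").onl_count.mean().to_dict()
        )
        assert r.slope_per_day == pytest.approx(rate_from_day_means(means), rel=1e-9)

    def test_recovers_true_rate_over_replicates(self):
        """Mean fitted slope over simulated cohorts within 5% of the truth."""
        design = published_cohort_design(6)
        truth = rate_from_day_means(
            {0: 1264.00, 1: 984.40, 7: 785.80, 14: 709.20}
        )
        slopes = [
            fit_rate(
                generate_cohort_table(design, 9000 + i),
                "detached_apex", "onl_count",
            ).slope_per_day
            for i in range(300)
        ]
        assert np.mean(slopes) == pytest.approx(truth, rel=0.05)

    def test_too_few_days_rejected(self):
        cohort = cohort_from_cells(
            {("detached_apex", d): (1000.0, 10.0, 2.0, 0.1) for d in (0, 14)}
        )
        with pytest.raises(InsufficientDesignError):
            fit_rate(cohort, "detached_apex", "onl_count")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalization:
    def test_reference_region_is_exactly_one(self):
        cohort = generate_cohort_table(published_cohort_design(5), 2)
        norm = normalize_to_attached(cohort)
        ref = norm[norm.region == "attached_central"]
        assert (ref.rd_ar_count == 1.0).all()
        assert (ref.rd_ar_ratio == 1.0).all()

    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (1013.80, 1247.60, 0.81),   # base / central counts
            (1264.00, 1247.60, 1.01),   # apex / central counts
            (79.96, 94.20, 0.85),       # base / central ONL thickness
            (88.99, 94.20, 0.94),       # apex / central ONL thickness
            (1.98, 2.00, 0.99),         # apex / central ONL/INL
        ],
    )
    def test_group_mean_normalizations(self, num, den, expected):
        assert round(normalized_group_mean(num, den), 2) == expected

    def test_missing_reference_tile_skipped_with_warning(self):
        cohort = generate_cohort_table(published_cohort_design(4), 1)
        broken = cohort[
            ~((cohort.animal_id == "d00_a0") & (cohort.region == "attached_central"))
        ]
        with pytest.warns(UserWarning, match="d00_a0"):
            norm = normalize_to_attached(broken)
        assert "d00_a0" not in set(norm.animal_id)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


class TestComparisons:
    def test_identical_groups_t_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_groups({"a": g, "b": g.copy()})
        t = [c for c in out if c.test == "Student t"][0]
        assert t.statistic == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_tukey_flags_only_outlier_group(self):
        """{1,2,3} vs {1,2,3} vs {10,11,12}: only pairs with the third
        group are significant (hand-checkable small ANOVA)."""
        groups = {
            "g1": np.array([1.0, 2.0, 3.0]),
            "g2": np.array([1.0, 2.0, 3.0]),
            "g3": np.array([10.0, 11.0, 12.0]),
        }
        pairs = tukey_hsd(groups)
        assert pairs[("g1", "g2")][1] > ALPHA
        assert pairs[("g1", "g3")][1] < ALPHA
        assert pairs[("g2", "g3")][1] < ALPHA

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        groups = {k: rng.normal(m, 1.0, 6) for k, m in
                  [("a", 0.0), ("b", 0.7), ("c", 2.5)]}
        mine = tukey_hsd(groups)
        ref = pairwise_tukeyhsd(
            np.concatenate(list(groups.values())),
            np.repeat(list(groups), 6),
        )
        for (pair, (_, p)), p_ref in zip(mine.items(), ref.pvalues):
            assert p == pytest.approx(p_ref, abs=2e-4)

    def test_anova_path_reports_shapiro_anova_tukey(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0, 1, 8) for k in "abc"}
        out = compare_groups(groups)
        tests = {c.test for c in out}
        assert {"Shapiro–Wilk", "ANOVA", "Tukey"} <= tests

    def test_welch_flag(self):
        rng = np.random.default_rng(2)
        out = compare_groups(
            {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 5, 5)}, welch=True
        )
        assert any(c.test == "Welch t" for c in out)

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            compare_groups({"a": np.ones(4), "b": np.full(4, 2.0)})


# ---------------------------------------------------------------------------
# degeneration criteria
# ---------------------------------------------------------------------------


def equal_means_cells(sd=60.0, rsd=0.15):
    regions = ("attached_central", "attached_paracentral",
               "detached_apex", "detached_base")
    return {
        (r, d): (1200.0, sd, 2.0, rsd) for r in regions for d in (0, 1, 7, 14)
    }


class TestCriteria:
    def test_no_degeneration_cohort_passes_1_2_fails_3_4(self):
        cohort = cohort_from_cells(equal_means_cells(), n=6, seed=10)
        rep = evaluate_criteria(cohort)
        for region in ("detached_apex", "detached_base"):
            crit = rep.regions[region]
            assert crit["1a"].passed and crit["1b"].passed
            assert crit["2a"].passed and crit["2b"].passed
            assert not crit["3a"].passed and not crit["4a"].passed
            assert not rep.verdicts[region]

    def test_extreme_decline_passes_progression_overwhelmingly(self):
        """Means dropping 10 SDs per timepoint: progression p < 1e-6."""
        cells = equal_means_cells(sd=20.0, rsd=0.02)
        for i, d in enumerate((0, 1, 7, 14)):
            cells[("detached_apex", d)] = (1200.0 - 200.0 * i, 20.0,
                                           2.0 - 0.2 * i, 0.02)
        rep = evaluate_criteria(cohort_from_cells(cells, n=6, seed=11))
        crit = rep.regions["detached_apex"]
        assert crit["3a"].passed and crit["4a"].passed
        assert crit["3a"].p_value < 1e-6
        assert crit["4a"].p_value < 1e-6

    def test_study_design_verdicts(self):
        """Under the published means/SDs the apex is fit and the base is
        unfit to demonstrate progressive degeneration."""
        cohort = generate_cohort_table(published_cohort_design(6), 42)
        rep = evaluate_criteria(cohort)
        assert rep.verdicts["detached_apex"] is True
        assert rep.verdicts["detached_base"] is False
        base = rep.regions["detached_base"]
        assert not (base["3a"].passed or base["3b"].passed)
        assert not (base["4a"].passed or base["4b"].passed)

    def test_report_is_deterministic(self):
        cohort = generate_cohort_table(published_cohort_design(5), 3)
        r1 = evaluate_criteria(cohort).to_dict()
        r2 = evaluate_criteria(cohort.copy()).to_dict()
        assert r1 == r2

    def test_verdict_iff_all_eight_pass(self):
        cohort = generate_cohort_table(published_cohort_design(6), 42)
        rep = evaluate_criteria(cohort)
        for region, crit in rep.regions.items():
            assert rep.verdicts[region] == all(c.passed for c in crit.values())
            assert set(crit) == {"1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b"}

    def test_missing_cells_rejected(self):
        cohort = generate_cohort_table(published_cohort_design(4), 1)
        broken = cohort[~((cohort.region == "detached_base") & (cohort.day == 7))]
        with pytest.raises(IncompleteDesignError, match="detached_base"):
            evaluate_criteria(broken)

    def test_report_text_renders(self):
        cohort = generate_cohort_table(published_cohort_design(4), 2)
        text = evaluate_criteria(cohort).to_text()
        assert "detached_apex" in text and "unfit" in text or "fit" in text


# ---------------------------------------------------------------------------
# case studies
# ---------------------------------------------------------------------------


class TestCaseStudies:
    def test_case3_seeded_shuffle_reproducible(self):
        cohort = generate_cohort_table(published_cohort_design(6), 5)
        r1 = run_case_study(3, cohort, seed=7)
        r2 = run_case_study(3, cohort, seed=7)
        assert r1 == r2
        r3 = run_case_study(3, cohort, seed=8)
        assert r3["days"][7]["allocation"] != r1["days"][7]["allocation"]

    def test_case3_odd_pool_sizes_differ_by_one(self):
        cohort = generate_cohort_table(published_cohort_design(5), 6)
        # drop one tile's base record at day 7: pooled n becomes odd
        drop = (cohort.animal_id == "d07_a0") & (cohort.region == "detached_base")
        r = run_case_study(3, cohort[~drop], seed=1)
        alloc = r["days"][7]["allocation"]
        assert abs(len(alloc["I"]) - len(alloc["II"])) == 1

    def test_case1_base_shows_type_ii(self):
        cohort = generate_cohort_table(published_cohort_design(6), 12)
        r = run_case_study(1, cohort)
        apex = r["regions"]["detached_apex"]["normalized_count"]
        base = r["regions"]["detached_base"]["normalized_count"]
        assert apex["significant"] and apex["error_type"] is None
        assert not base["significant"] and base["error_type"] == "type II"

    def test_case2_apex_detected_base_missed(self):
        cohort = generate_cohort_table(published_cohort_design(6), 13)
        r = run_case_study(2, cohort)
        assert r["regions"]["detached_apex"]["onl_count"]["significant"]
        assert not r["regions"]["detached_base"]["onl_count"]["significant"]

    def test_unknown_case_rejected(self):
        cohort = generate_cohort_table(published_cohort_design(4), 1)
        with pytest.raises(ValueError):
            run_case_study(4, cohort)
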