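"""Mobility rate, transition classification, tenure and survival analyses."""

import numpy as np
import pytest
from scipy import stats

from rankmob.mobility import (
    chi_square_equal,
    classify_transitions,
    compare_slopes,
    extreme_rank_tenure,
    fit_mobility,
    km_upward_time,
    mann_whitney,
    rank_pairs,
    residual_normality,
    tenure_change_correlation,
    tenure_table,
    upward_move_times,
)
from rankmob.simulate import GroupSimConfig, simulate_group
from conftest import make_rank_table


def _chain_table(n_individuals, n_years, sex="F"):
    rows = []
    for year in range(1, n_years + 1):
        for k in range(n_individuals):
            rows.append((f"i{k}", sex, year, k + 1))
    return make_rank_table(rows)


class TestRankPairs:
    def test_chain_length(self):
        table = _chain_table(1, 4)
        assert len(rank_pairs(table, "F")) == 3

    def test_single_year_censored(self):
        table = _chain_table(1, 1)
        assert len(rank_pairs(table, "F")) == 0

    def test_ten_individuals_thirty_years(self):
        table = _chain_table(10, 30)
        assert len(rank_pairs(table, "F")) == 290

    def test_gap_in_presence_breaks_pairs(self):
        rows = [("a", "F", 1, 1), ("a", "F", 3, 1)]  # absent in year 2
        assert len(rank_pairs(make_rank_table(rows), "F")) == 0


class TestFitMobility:
    def test_perfect_stability(self):
        pairs = np.array([[1, 1], [2, 2], [3, 3], [4, 4]])
        fit = fit_mobility(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.rate == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_closed_form_hand_example(self):
        fit = fit_mobility(np.array([[1, 2], [2, 1], [3, 3]]))
        assert fit.slope == pytest.approx(0.5)
        assert fit.rate == pytest.approx(0.5)

    def test_rate_plus_slope_is_one(self):
        rng = np.random.default_rng(0)
        pairs = rng.integers(1, 10, size=(50, 2))
        fit = fit_mobility(pairs)
        assert fit.rate + fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_mobility(np.array([[2, 1], [2, 2], [2, 3]]))

    def test_parameter_recovery_near_generating_slope(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 16, size=200)
        y = 0.84 * x + rng.normal(0, 0.8, size=200)
        fit = fit_mobility(np.column_stack([x, y]))
        assert fit.rate == pytest.approx(0.16, abs=0.04)


class TestCompareSlopes:
    def test_identical_fits_give_zero_t(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 12, size=40)
        pairs = np.column_stack([x, 0.9 * x + rng.normal(0, 0.5, 40)])
        fit = fit_mobility(pairs)
        t, df, p = compare_slopes(fit, fit)
        assert t == pytest.approx(0.0)
        assert df == 2 * fit.n - 4
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(100):
            x = rng.integers(1, 12, size=50)
            fa = fit_mobility(np.column_stack([x, 0.8 * x + rng.normal(0, 1, 50)]))
            x2 = rng.integers(1, 12, size=50)
            fb = fit_mobility(np.column_stack([x2, 0.8 * x2 + rng.normal(0, 1, 50)]))
            if compare_slopes(fa, fb)[2] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / 100 <= 0.10

    def test_power_against_clearly_different_slopes(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 12, size=100)
        fa = fit_mobility(np.column_stack([x, 0.5 * x + rng.normal(0, 0.2, 100)]))
        fb = fit_mobility(np.column_stack([x, 1.0 * x + rng.normal(0, 0.2, 100)]))
        assert compare_slopes(fa, fb)[2] < 0.001


class TestResidualNormality:
    def test_calibration_under_normal_residuals(self):
        rng = np.random.default_rng(4)
        ok = 0
        for _ in range(100):
            x = rng.integers(1, 20, size=500)
            fit = fit_mobility(np.column_stack([x, x + rng.normal(0, 1, 500)]))
            if residual_normality(fit)[1] > 0.05:
                ok += 1
        assert ok >= 90

    def test_sensitivity_to_heavy_tails(self):
        rng = np.random.default_rng(6)
        detected = 0
        for _ in range(100):
            x = rng.integers(1, 20, size=500)
            fit = fit_mobility(np.column_stack([x, x + rng.standard_t(2, 500)]))
            if residual_normality(fit)[1] < 0.005:
                detected += 1
        assert detected >= 90

    def test_degenerate_residuals_rejected(self):
        fit = fit_mobility(np.array([[k, k] for k in range(1, 12)]))
        with pytest.raises(ValueError, match="constant"):
            residual_normality(fit)

    def test_too_few_residuals_rejected(self):
        fit = fit_mobility(np.array([[1, 2], [2, 1], [3, 3]]))
        with pytest.raises(ValueError, match="at least 8"):
            residual_normality(fit)


class TestClassifyTransitions:
    def test_upward_definition_and_magnitude(self):
        counts = classify_transitions(np.array([[3, 1]]))
        assert counts.n_up == 1 and counts.n_down == 0
        assert counts.magnitudes == {2: 1}

    def test_direct_counts(self):
        counts = classify_transitions(np.array([[1, 1], [2, 2], [3, 2]]))
        assert (counts.n_same, counts.n_up, counts.n_down) == (2, 1, 0)

    def test_counts_conserved(self):
        rng = np.random.default_rng(8)
        pairs = rng.integers(1, 10, size=(300, 2))
        counts = classify_transitions(pairs)
        assert counts.n_pairs == 300
        assert sum(counts.magnitudes.values()) == counts.n_change

    def test_simulated_up_fraction_tracks_generator(self):
        """Pooled over replicates the realized up:(up+down) fraction sits
        within +-0.05 of the generating up_given_move = 0.75."""
        ups = downs = 0
        for seed in range(30):
            cfg = GroupSimConfig(seed=seed, interactions_per_dyad_per_year=0)
            table = simulate_group(cfg).rank_table()
            for sex in ("F", "M"):
                c = classify_transitions(rank_pairs(table, sex))
                ups, downs = ups + c.n_up, downs + c.n_down
        assert ups + downs >= 1000
        assert ups / (ups + downs) == pytest.approx(0.75, abs=0.05)


class TestChiSquareEqual:
    @pytest.mark.parametrize(
        "a,b,expected", [(50, 50, 0.0), (75, 25, 25.0), (0, 100, 100.0)]
    )
    def test_hand_computed_statistics(self, a, b, expected):
        chi2, df, p = chi_square_equal(a, b)
        assert chi2 == pytest.approx(expected)
        assert df == 1

    def test_exact_null_has_p_one(self):
        assert chi_square_equal(50, 50)[2] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi_square_equal(0, 0)


class TestTenureTable:
    def test_stasis_gives_all_no_change(self):
        table = _chain_table(4, 5)
        tt = tenure_table(table, "F", thresholds=(1, 2, 3))
        assert (tt["p_no_change"] == 1.0).all()
        assert (tt["p_upward"] == 0.0).all()

    def test_staggered_example_direct_classification(self, staggered_table):
        tt = tenure_table(staggered_table, "F", thresholds=(1, 3))
        k1 = tt[tt["min_tenure"] == 1].iloc[0]
        assert (k1["p_upward"], k1["p_downward"], k1["p_no_change"]) == (
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
        )
        k3 = tt[tt["min_tenure"] == 3].iloc[0]
        assert (k3["p_upward"], k3["p_downward"], k3["p_no_change"]) == (1.0, 0.0, 0.0)

    def test_rows_sum_to_one_and_nest(self, staggered_table):
        tt = tenure_table(staggered_table, "F", thresholds=(1, 2, 3, 4))
        filled = tt[tt["n"] > 0]
        assert np.allclose(
            filled[["p_upward", "p_downward", "p_no_change"]].sum(axis=1), 1.0
        )
        assert (tt["n"].diff().dropna() <= 0).all()  # nested subsets

    def test_threshold_beyond_all_tenures_flagged_empty(self, staggered_table):
        tt = tenure_table(staggered_table, "F", thresholds=(10,))
        assert tt.iloc[0]["n"] == 0 and np.isnan(tt.iloc[0]["p_upward"])

    def test_unsorted_thresholds_rejected(self, staggered_table):
        with pytest.raises(ValueError):
            tenure_table(staggered_table, "F", thresholds=(3, 1))


class TestTenureChangeCorrelation:
    def test_colinear_adults_give_r_one(self):
        # tenures 1..4 with improvements 0..3, built as valid permutations
        rows = [
            ("z", "F", 1, 4), ("y", "F", 1, 3), ("x", "F", 1, 2), ("w", "F", 1, 1),
            ("x", "F", 2, 1), ("y", "F", 2, 2), ("z", "F", 2, 3),
            ("y", "F", 3, 1), ("z", "F", 3, 2),
            ("z", "F", 4, 1),
        ]
        r, df, p = tenure_change_correlation(make_rank_table(rows), "F")
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_degenerate_variance_rejected(self):
        table = _chain_table(4, 3)
        with pytest.raises(ValueError, match="zero variance"):
            tenure_change_correlation(table, "F")

    def test_simulated_groups_show_positive_correlation(self):
        """Longer-tenured adults inherit more vacated ranks, so tenure and
        net improvement correlate positively in the generator's regime."""
        rs = []
        for seed in range(8):
            cfg = GroupSimConfig(seed=seed, interactions_per_dyad_per_year=0)
            table = simulate_group(cfg).rank_table()
            for sex in ("F", "M"):
                try:
                    r, _, _ = tenure_change_correlation(table, sex)
                    rs.append(r)
                except ValueError:
                    pass
        assert len(rs) >= 10
        assert np.mean(rs) > 0.2


class TestExtremeRankTenure:
    def test_single_unbroken_alpha_spell(self):
        table = _chain_table(3, 30)
        spells = extreme_rank_tenure(table, "F")
        assert spells["alpha"].spells == (30,)
        assert spells["omega"].spells == (30,)

    def test_hand_enumerated_spells(self):
        # alpha sequence A, A, B, A over 4 years
        rows = [
            ("A", "F", 1, 1), ("B", "F", 1, 2),
            ("A", "F", 2, 1), ("B", "F", 2, 2),
            ("B", "F", 3, 1), ("A", "F", 3, 2),
            ("A", "F", 4, 1), ("B", "F", 4, 2),
        ]
        spells = extreme_rank_tenure(make_rank_table(rows), "F")
        assert sorted(spells["alpha"].spells) == [1, 1, 2]
        assert spells["alpha"].mean == pytest.approx(4 / 3)

    def test_empty_table_gives_empty_summary(self):
        table = _chain_table(2, 3, sex="M")
        spells = extreme_rank_tenure(table, "F")
        assert spells["alpha"].spells == ()
        assert np.isnan(spells["alpha"].mean)


class TestMannWhitney:
    def test_identical_samples_midpoint_u(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p > 0.99

    def test_fully_separated_samples(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=25)
            b = rng.normal(size=30)
            if mann_whitney(a, b)[1] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.08


class TestUpwardTimes:
    def test_event_and_censoring_hand_case(self):
        rows = [
            ("A", "F", 1, 1), ("B", "F", 1, 2),
            ("B", "F", 2, 1), ("A", "F", 2, 2),
        ]
        d, e = upward_move_times(make_rank_table(rows), "F")
        # sorted by id: A censored at duration 1; B event at duration 1
        assert list(d) == [1.0, 1.0]
        assert list(e) == [0, 1]

    def test_all_censored_curve_stays_at_one(self):
        table = _chain_table(3, 5)
        result = km_upward_time(table, ["F"])
        kmf = result.fitters["F"]
        assert float(kmf.survival_function_.iloc[-1].iloc[0]) == pytest.approx(1.0)

    def test_logrank_calibrated_under_identical_hazard(self):
        rng = np.random.default_rng(10)
        from lifelines.statistics import logrank_test

        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            d1 = rng.exponential(5, size=30).round() + 1
            d2 = rng.exponential(5, size=30).round() + 1
            e1 = rng.random(30) < 0.7
            e2 = rng.random(30) < 0.7
            res = logrank_test(d1, d2, event_observed_A=e1, event_observed_B=e2)
            if res.p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_sexes_compared_when_both_present(self):
        rows = []
        rng = np.random.default_rng(12)
        cfg = GroupSimConfig(seed=13, n_years=15, interactions_per_dyad_per_year=0)
        table = simulate_group(cfg).rank_table()
        result = km_upward_time(table)
        assert result.logrank_p is not None
        assert 0.0 <= result.logrank_p <= 1.0
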