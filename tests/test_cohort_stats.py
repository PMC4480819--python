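"""Response pooling, survival analysis, contingency and rank tests."""

import numpy as np
import pytest

from hepadose import (
    PatientRecord,
    ResponseTable,
    chi_squared_rxc,
    km_curve,
    load_outcome_counts,
    logrank,
    pooled_response_rate,
    rank_compare,
    reild_band_summary,
    response_table_from_counts,
    toxicity_grade_change,
)


class TestPooledResponse:
    def test_validation_cohort_3_month_rate(self):
        counts = load_outcome_counts()
        table = response_table_from_counts(counts, "3m")
        out = pooled_response_rate(table)
        assert (out["responders"], out["evaluable"]) == (30, 74)
        assert round(out["rate_percent"]) == 41

    def test_validation_cohort_6_month_rate(self):
        table = response_table_from_counts(load_outcome_counts(), "6m")
        out = pooled_response_rate(table)
        assert (out["responders"], out["evaluable"]) == (21, 44)
        assert round(out["rate_percent"]) == 48

    def test_zero_responders(self):
        out = pooled_response_rate(ResponseTable({"g": (0, 10)}))
        assert out["rate_percent"] == 0.0

    def test_zero_evaluable_rejected(self):
        with pytest.raises(ValueError):
            pooled_response_rate(ResponseTable({"g": (0, 0)}))

    def test_invariant_to_ordering_and_merging(self):
        split = ResponseTable({"a": (3, 10), "b": (4, 12), "c": (1, 5)})
        merged = ResponseTable({"ab": (7, 22), "c": (1, 5)})
        reordered = ResponseTable({"c": (1, 5), "b": (4, 12), "a": (3, 10)})
        assert (
            pooled_response_rate(split)["rate_percent"]
            == pooled_response_rate(merged)["rate_percent"]
            == pooled_response_rate(reordered)["rate_percent"]
        )


class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        out = km_curve([1, 2, 3], [True, True, True])
        lookup = dict(zip(out["times"], out["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert out["median"] == pytest.approx(2.0)

    def test_no_events_median_not_reached(self):
        out = km_curve([4, 8, 15], [False, False, False])
        assert np.all(out["survival"] == 1.0)
        assert out["median"] is None

    def test_censoring_removes_subject_from_risk_set(self):
        out = km_curve([1, 2, 3], [True, False, True])
        lookup = dict(zip(out["times"], out["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)  # risk set of 1 at t=3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    def test_uncensored_curve_equals_empirical_survival(self, rng):
        times = rng.exponential(10.0, size=60)
        out = km_curve(times, np.ones(60, bool))
        for t, s in zip(out["times"], out["survival"]):
            if t == 0.0:
                continue
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)


def brute_force_logrank_2group(times_a, times_b):
    """Hypergeometric O-E/V tabulation over the pooled event times
    (all subjects are events)."""
    all_times = sorted(set(times_a) | set(times_b))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        n = n_a + n_b
        d = sum(1 for x in times_a if x == t) + sum(1 for x in times_b if x == t)
        o_a = sum(1 for x in times_a if x == t)
        e_a = d * n_a / n
        o_minus_e += o_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        g = ([1, 2, 3], [True, True, True])
        out = logrank([g, g])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_brute_force_hypergeometric(self):
        a, b = [1, 2, 3], [10, 20, 30]
        expected = brute_force_logrank_2group(a, b)
        out = logrank([(a, [True] * 3), (b, [True] * 3)])
        assert out["statistic"] == pytest.approx(expected, rel=1e-9)
        assert out["df"] == 1

    def test_single_stratum_equals_unstratified(self):
        groups = [([1, 3, 5, 7], [1, 1, 0, 1]), ([2, 4, 6], [1, 0, 1])]
        plain = logrank(groups)
        strat = logrank(groups, strata=[np.zeros(4), np.zeros(3)])
        assert strat["statistic"] == pytest.approx(plain["statistic"], rel=1e-9)

    def test_stratification_pools_over_strata(self, rng):
        """A group effect confined to strata means stratified != pooled."""
        t1 = rng.exponential(5, 40)
        t2 = rng.exponential(15, 40)
        groups = [(t1, np.ones(40, bool)), (t2, np.ones(40, bool))]
        strata = [rng.integers(0, 2, 40), rng.integers(0, 2, 40)]
        plain = logrank(groups)
        strat = logrank(groups, strata=strata)
        assert strat["p"] < 0.05  # real effect survives stratification
        assert strat["statistic"] != pytest.approx(plain["statistic"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([([1, 2], [1, 1]), ([], [])])
        with pytest.raises(ValueError):
            logrank([([1, 2], [1, 1])])


def brute_force_chi2(table):
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestChiSquared:
    def test_homogeneous_table_gives_null(self):
        out = chi_squared_rxc([[10, 10], [10, 10]])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(25):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 30, size=(r, c))
            out = chi_squared_rxc(table)
            assert out["statistic"] == pytest.approx(brute_force_chi2(table), rel=1e-12)
            assert out["df"] == (r - 1) * (c - 1)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_rxc([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            chi_squared_rxc([[1, 2, 3]])


class TestRankCompare:
    def test_identical_groups_give_p_one(self):
        out = rank_compare([[1, 2, 3], [1, 2, 3]])
        assert out["test"] == "mann-whitney"
        assert out["p"] == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        out = rank_compare([[1, 2], [3, 4]])
        assert out["statistic"] == 0.0
        assert out["p"] == pytest.approx(1 / 3)  # 2/6 rank assignments as extreme

    def test_three_groups_use_kruskal_wallis(self, rng):
        out = rank_compare([rng.normal(size=20), rng.normal(size=20), rng.normal(size=20)])
        assert out["test"] == "kruskal-wallis"
        assert 0.0 <= out["p"] <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_compare([[1, 2], []])


class TestToxicityGradeChange:
    @pytest.mark.parametrize(
        "baseline, followup, expected",
        [
            ({"bili": 1}, {"bili": 3}, 2),
            ({"bili": 3, "ast": 2}, {"bili": 2, "ast": 1}, 0),  # improvement floors at 0
            ({"bili": 0, "ast": 2}, {"bili": 1, "ast": 2}, 1),
            ({}, {}, 0),
        ],
    )
    def test_max_per_lab_increase(self, baseline, followup, expected):
        assert toxicity_grade_change(baseline, followup) == expected

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError):
            toxicity_grade_change({"bili": 5}, {"bili": 2})

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            toxicity_grade_change({"bili": 1}, {"ast": 1})


def make_record(d_fl_tot, prior=0.0, reild=False):
    return PatientRecord(cell_type="CRC", d_t=40.0, d_fl_tot=d_fl_tot,
                         prior_liver_dose=prior, reild=reild)


class TestReildBands:
    def test_high_band_incidence(self):
        records = [make_record(70.0, reild=(i < 5)) for i in range(13)]
        out = reild_band_summary(records)
        assert out["gt60"]["n"] == 13
        assert out["gt60"]["reild"] == 5
        assert round(out["gt60"]["incidence_percent"], 1) == 38.5

    def test_prior_dose_enters_cumulative(self):
        out = reild_band_summary([make_record(41.2, prior=23.6, reild=True)])
        assert out["gt60"]["n"] == 1  # 64.8 Gy cumulative

    def test_band_boundaries_closed_in_middle(self):
        out = reild_band_summary([make_record(30.0), make_record(60.0)])
        assert out["30to60"]["n"] == 2

    def test_empty_band_reports_missing(self):
        out = reild_band_summary([make_record(10.0)])
        assert out["gt60"]["incidence_percent"] is None
        assert out["30to60"]["incidence_percent"] is None

    def test_no_reild_gives_zero_incidence(self):
        records = [make_record(d) for d in (10, 40, 70)]
        out = reild_band_summary(records)
        assert all(b["incidence_percent"] == 0.0 for b in out.values())
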