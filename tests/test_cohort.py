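"""Cohort statistics: worked examples, oracle equivalence, null calibration."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from refcast import (
    ContingencyTable,
    bartlett,
    benjamini_hochberg,
    default_periods,
    distribution_checks,
    dunn_posthoc,
    kruskal_wallis,
    pearson_chi_square,
    period_summary,
)
from refcast.cohort import grade_contingency_table
from refcast.errors import DegenerateInputError, InvalidArgumentError
from refcast.synthetic import ReferralRecord

GRADE_BY_PERIOD = np.array([[23, 30, 31], [50, 22, 28], [8, 10, 6]])


class TestChiSquare:
    def test_grade_by_period_worked_example(self):
        """The 3x3 grade-by-period table: statistic 11.9, df 4."""
        res = pearson_chi_square(GRADE_BY_PERIOD)
        assert res["statistic"] == pytest.approx(11.9, abs=0.05)
        assert res["df"] == 4
        assert res["p_value"] < 0.05

    def test_pre_vs_during_subtable(self):
        res = pearson_chi_square(GRADE_BY_PERIOD[:, :2])
        assert res["statistic"] == pytest.approx(9.7, abs=0.05)
        assert res["df"] == 2

    def test_pre_vs_post_subtable(self):
        res = pearson_chi_square(GRADE_BY_PERIOD[:, [0, 2]])
        assert res["statistic"] == pytest.approx(6.0, abs=0.05)
        assert res["df"] == 2

    def test_identical_proportions_zero(self):
        assert pearson_chi_square([[10, 20], [5, 10]])["statistic"] == pytest.approx(0.0)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi_square([[0, 0], [3, 4]])

    def test_matches_brute_force_and_scipy(self, rng):
        """Double-loop oracle and scipy agreement to 1e-10 on random tables."""
        for _ in range(100):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 60, size=shape).astype(float)
            res = pearson_chi_square(table)
            # brute-force double loop
            row, col, tot = table.sum(1), table.sum(0), table.sum()
            brute = 0.0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    e = row[i] * col[j] / tot
                    brute += (table[i, j] - e) ** 2 / e
            assert abs(res["statistic"] - brute) < 1e-10
            ref = sps.chi2_contingency(table, correction=False)
            assert abs(res["statistic"] - ref.statistic) < 1e-10
            assert abs(res["p_value"] - ref.pvalue) < 1e-10


class TestKruskalWallis:
    def test_closed_form_rank_sums(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6/15/24 give H = 7.2."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res["statistic"] == pytest.approx(7.2)
        assert res["df"] == 2

    def test_identical_groups_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_convention(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res["statistic"] == 0.0 and res["p_value"] == 1.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            groups = [rng.integers(0, 8, size=rng.integers(5, 20)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            mine = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert abs(mine["statistic"] - ref.statistic) < 1e-10
            assert abs(mine["p_value"] - ref.pvalue) < 1e-10

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(loc, 1, 30) for loc in (0.0, 0.5, 1.0)]
        base = kruskal_wallis(groups)["statistic"]
        transformed = kruskal_wallis([np.exp(g) for g in groups])["statistic"]
        assert transformed == pytest.approx(base, abs=1e-10)

    def test_type_one_error_calibrated(self, rng):
        """Null rejections at alpha = 0.05 lie in [0.03, 0.07] (2000 replicates)."""
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            rejections += kruskal_wallis(groups)["p_value"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestDunn:
    def test_pairwise_z_matches_two_group_h(self, rng):
        """For an isolated pair without ties, z^2 equals the 2-group H."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        h = kruskal_wallis([a, b])["statistic"]
        # independent closed-form z on the pair
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        z = (ranks[:12].mean() - ranks[12:].mean()) / np.sqrt(
            n * (n + 1) / 12 * (1 / 12 + 1 / 15))
        assert z**2 == pytest.approx(h, rel=1e-10)

    def test_separated_pair_has_largest_z(self, rng):
        near1 = rng.normal(0, 1, 25)
        near2 = rng.normal(0.3, 1, 25)
        far = rng.normal(6, 1, 25)
        table = dunn_posthoc([near1, near2, far])
        zmax = table.loc[table["z"].abs().idxmax()]
        assert {int(zmax["group_i"]), int(zmax["group_j"])} != {0, 1}

    def test_null_family_wise_behaviour(self, rng):
        """Identical distributions: BH-adjusted p < 0.05 rarely (<= 5% of runs)."""
        false_positive_runs = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            table = dunn_posthoc(groups)
            false_positive_runs += (table["p_adjusted"] < 0.05).any()
        assert false_positive_runs <= 0.05 * n_rep + 3 * np.sqrt(n_rep * 0.05 * 0.95)

    def test_two_groups_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dunn_posthoc([[1, 2], [3, 4]])


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        """p = {0.01, 0.02, 0.03, 0.04} at q = 0.05: p_(4) <= 4q/4, all rejected."""
        res = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert res["rejected"].all()

    def test_all_ones(self):
        res = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not res["rejected"].any()
        np.testing.assert_array_equal(res["adjusted"], 1.0)

    def test_single_p_reduces_to_raw_threshold(self):
        res = benjamini_hochberg([0.04], q=0.05)
        assert res["rejected"][0]
        assert res["adjusted"][0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            benjamini_hochberg([0.5, 1.5])

    def test_adjusted_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 25)
        mine = benjamini_hochberg(p)
        _, adj, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine["adjusted"], adj, atol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15),
        st.floats(min_value=0.01, max_value=0.4),
        st.floats(min_value=0.01, max_value=0.5),
    )
    def test_rejections_monotone_in_q(self, pvals, q_low, q_extra):
        """Raising q never un-rejects a hypothesis."""
        low = benjamini_hochberg(pvals, q=q_low)["rejected"]
        high = benjamini_hochberg(pvals, q=min(q_low + q_extra, 0.99))["rejected"]
        assert (high | ~low).all()


class TestBartlettAndKs:
    def test_matches_scipy(self, rng):
        for _ in range(30):
            groups = [rng.normal(0, s, rng.integers(8, 30))
                      for s in rng.uniform(0.5, 3.0, rng.integers(2, 5))]
            mine = bartlett(groups)
            ref = sps.bartlett(*groups)
            assert abs(mine["statistic"] - ref.statistic) < 1e-10
            assert abs(mine["p"] - ref.pvalue) < 1e-10

    def test_equal_variances_small_statistic(self, rng):
        groups = [rng.normal(m, 1.0, 200) for m in (0, 5, 10)]
        assert bartlett(groups)["statistic"] < 10

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            bartlett([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])

    def test_ks_normal_sample_usually_passes(self, rng):
        passes = sum(
            distribution_checks(rng.normal(0, 1, 1000))["ks_normality_p"] > 0.05
            for _ in range(100)
        )
        # estimated parameters make the test conservative: well above 90/100
        assert passes >= 90

    def test_ks_rejects_heavy_skew(self, rng):
        res = distribution_checks(rng.exponential(1.0, 1000))
        assert res["ks_normality_p"] < 0.01


class TestPeriodSummary:
    def _record(self, date, grade="resident", urgency="urgent", duration=3,
                site="site_01"):
        return ReferralRecord(date, grade, "endocrinology", urgency, 15, duration, site)

    def test_constructed_medians_reproduced(self):
        recs = []
        for m, dur in (("2019-03", 3), ("2019-04", 3), ("2019-05", 7)):
            y, mo = (int(v) for v in m.split("-"))
            recs.append(self._record(datetime.date(y, mo, 10), duration=dur))
        out = period_summary(recs, None, default_periods())
        row = out["summary"].set_index("period").loc["pre_covid"]
        assert row["median_symptom_duration"] == 3.0
        assert row["n_records"] == 3

    def test_all_records_in_one_period(self):
        recs = [self._record(datetime.date(2019, 6, 1))]
        out = period_summary(recs, None, default_periods())
        summary = out["summary"].set_index("period")
        assert not summary.loc["pre_covid", "missing"]
        assert summary.loc["covid", "missing"]

    def test_grade_counts_flow_into_chi_square(self):
        """Constructed grade counts reproduce the directly computed statistic."""
        periods = default_periods()
        counts = {"pre_covid": ("2019-06", [4, 9, 2]),
                  "covid": ("2020-06", [6, 5, 3]),
                  "post_covid": ("2021-06", [5, 4, 1])}
        recs = []
        for _, (month, (n_i, n_r, n_a)) in counts.items():
            y, mo = (int(v) for v in month.split("-"))
            day = datetime.date(y, mo, 5)
            recs += [self._record(day, grade="intern")] * n_i
            recs += [self._record(day, grade="resident")] * n_r
            recs += [self._record(day, grade="attending")] * n_a
        table = grade_contingency_table(recs, periods)
        expected = np.array([[4, 6, 5], [9, 5, 4], [2, 3, 1]], dtype=float)
        np.testing.assert_array_equal(table.counts, expected)
        out = period_summary(recs, None, periods)
        assert out["grade_chi_square"]["statistic"] == pytest.approx(
            pearson_chi_square(expected)["statistic"])

    def test_volume_battery_runs_on_series(self, referral_series):
        out = period_summary([], referral_series, default_periods())
        assert "volume_kruskal_wallis" in out
        assert out["volume_kruskal_wallis"]["df"] == 3
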