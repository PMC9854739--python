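"""Metrics, descriptive statistics, ANOVA and exact Wilcoxon tests.

Where an independent route exists (scipy's implementations, brute-force
enumeration, direct binomial tails), the package's own computation is
checked against it rather than against itself.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from adscfgwo.stats import (
    ConfusionCounts,
    anova_from_summary,
    compute_metrics,
    confusion_from_predictions,
    describe_runs,
    f1_from_precision_recall,
    load_run_matrix,
    median_ci,
    one_way_anova,
    reconstruct_confusion,
    run_matrix_report,
    wilcoxon_signed_rank,
)

# printed per-method accuracy summaries (mean, sd) over 11 runs
TABLE_MEANS = [0.9998, 0.9777, 0.9695, 0.9653, 0.9619, 0.9564]
TABLE_SDS = [0.0, 0.00306, 0.001195, 0.0, 0.00462, 0.004649]


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion_from_predictions([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_negative_predictions(self):
        c = confusion_from_predictions([1, 1], [0, 0])
        assert c.fn == 2 and c.tp == 0

    def test_empty_and_non_binary_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([], [])
        with pytest.raises(ValueError):
            confusion_from_predictions([0, 2], [0, 1])


class TestMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        rep = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        for value in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv, rep.f1):
            assert value == pytest.approx(1.0)
        assert not rep.undefined

    def test_f1_matches_published_cnn_row_to_six_decimals(self):
        assert f1_from_precision_recall(0.966183575, 0.975609756) == pytest.approx(
            0.970874, abs=5e-7
        )

    def test_f1_matches_published_dt_row_to_six_decimals(self):
        assert f1_from_precision_recall(0.943396226, 0.947867299) == pytest.approx(
            0.945626, abs=5e-7
        )

    def test_reconstructed_svm_counts_imply_published_accuracy(self):
        c = reconstruct_confusion(0.956937799, 0.977198697, decimals=9)
        assert (c.tp, c.fn, c.tn, c.fp) == (200, 9, 300, 7)
        rep = compute_metrics(c)
        assert rep.accuracy == pytest.approx(0.968992248, abs=5e-10)
        assert rep.sensitivity == pytest.approx(0.956937799, abs=5e-10)
        assert rep.specificity == pytest.approx(0.977198697, abs=5e-10)

    def test_zero_denominators_are_flagged_not_zeroed(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(rep.sensitivity) and "sensitivity" in rep.undefined
        assert math.isnan(rep.ppv) and "ppv" in rep.undefined

    def test_total_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestReconstruction:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            (1.0, 1.0, (1, 0, 1, 0)),
            (0.5, 0.5, (1, 1, 1, 1)),
        ],
    )
    def test_minimal_cases(self, sens, spec, expected):
        c = reconstruct_confusion(sens, spec, decimals=9)
        assert (c.tp, c.fn, c.tn, c.fp) == expected

    def test_round_trip_on_random_printed_rates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos, neg = rng.integers(2, 400, size=2)
            tp = int(rng.integers(0, pos + 1))
            tn = int(rng.integers(0, neg + 1))
            sens, spec = round(tp / pos, 9), round(tn / neg, 9)
            c = reconstruct_confusion(sens, spec, decimals=9)
            assert round(c.tp / (c.tp + c.fn), 9) == sens
            assert round(c.tn / (c.tn + c.fp), 9) == spec
            assert c.total <= pos + neg  # minimality never exceeds the source

    def test_unreachable_rate_fails_explicitly(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(0.123456789, 0.5, decimals=9, cap=50)


class TestDescribeRuns:
    def test_constant_vector_collapses_all_intervals(self):
        d = describe_runs([0.9998] * 11)
        assert d.mean == pytest.approx(0.9998)
        assert d.sd == 0.0
        assert d.cv_percent == pytest.approx(0.0)
        assert d.range == 0.0
        assert d.mean_ci_lower == d.mean_ci_upper == pytest.approx(0.9998)
        assert d.sum == pytest.approx(11 * 0.9998)
        assert math.isnan(d.skewness) and "skewness" in d.flags

    def test_order_statistics_of_one_to_eleven(self):
        d = describe_runs(list(range(1, 12)))
        assert d.median == 6 and d.minimum == 1 and d.maximum == 11

    def test_all_mean_variants_agree_on_constant_data(self):
        d = describe_runs([2.5] * 5)
        for m in (d.mean, d.geometric_mean, d.harmonic_mean, d.quadratic_mean):
            assert m == pytest.approx(2.5)

    def test_nonpositive_values_flag_log_means(self):
        d = describe_runs([-1.0, 0.5, 2.0])
        assert math.isnan(d.geometric_mean)
        assert "geometric_mean" in d.flags

    def test_skewness_and_kurtosis_match_adjusted_sample_estimators(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=40)
        d = describe_runs(x)
        assert d.skewness == pytest.approx(sps.skew(x, bias=False))
        assert d.kurtosis == pytest.approx(sps.kurtosis(x, bias=False))


class TestMedianCI:
    def test_eleven_runs_use_second_order_statistics_at_9883_percent(self):
        m = median_ci(list(range(1, 12)))
        assert m.k == 2
        assert (m.lower, m.upper) == (2.0, 10.0)
        assert m.actual_level == pytest.approx(0.9883, abs=5e-5)
        assert not m.below_target

    def test_five_values_cannot_reach_95_percent(self):
        m = median_ci([1.0, 2.0, 3.0, 4.0, 5.0])
        assert m.actual_level == pytest.approx(1 - 2 / 32)
        assert m.below_target
        assert (m.lower, m.upper) == (1.0, 5.0)

    def test_constant_data_collapses_to_the_constant(self):
        m = median_ci([3.3] * 11)
        assert m.lower == m.upper == 3.3

    @pytest.mark.parametrize("n", range(2, 51))
    def test_coverage_matches_direct_binomial_tails(self, n):
        m = median_ci(np.arange(n, dtype=float))
        # direct tail computation from the binomial pmf
        k = m.k
        tail = sum(math.comb(n, j) for j in range(k)) / 2.0 ** n
        assert m.actual_level == pytest.approx(1.0 - 2.0 * tail, abs=1e-12)
        if not m.below_target:
            # minimal coverage >= 0.95: one order statistic tighter must fail
            tighter = sum(math.comb(n, j) for j in range(k + 1)) / 2.0 ** n
            assert 1.0 - 2.0 * tighter < 0.95


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.ss_between == pytest.approx(0.0, abs=1e-12)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_six_groups_of_eleven_have_df_5_and_60(self):
        rng = np.random.default_rng(0)
        res = one_way_anova([rng.normal(size=11) for _ in range(6)])
        assert (res.df_between, res.df_within) == (5, 60)

    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        res = one_way_anova([a, b])
        t_stat, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t_stat**2, rel=1e-10)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc, 1.0, size=9) for loc in (0.0, 0.3, 0.8)]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f_stat == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_summary_form_matches_raw_form_to_1e10(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            groups = rng.normal(size=(4, 11)) * rng.uniform(0.5, 2) + rng.normal(size=(4, 1))
            raw = one_way_anova(list(groups))
            summ = anova_from_summary(
                groups.mean(axis=1), groups.std(axis=1, ddof=1), 11
            )
            assert summ.ss_between == pytest.approx(raw.ss_between, rel=1e-10)
            assert summ.ss_within == pytest.approx(raw.ss_within, rel=1e-10)
            assert summ.f_stat == pytest.approx(raw.f_stat, rel=1e-10)

    def test_published_summaries_reproduce_published_table(self):
        res = anova_from_summary(TABLE_MEANS, TABLE_SDS, 11)
        assert res.ss_between == pytest.approx(0.01323, rel=0.005)
        assert res.ss_within == pytest.approx(0.0005374, rel=0.005)
        assert res.f_stat == pytest.approx(295.4, rel=0.005)
        assert (res.df_between, res.df_within) == (5, 60)
        assert res.p_value < 0.0001

    def test_zero_within_variance_flags_infinite_f(self):
        res = anova_from_summary([1.0, 2.0], [0.0, 0.0], 5)
        assert res.degenerate and math.isinf(res.f_stat)


def wilcoxon_enumeration_oracle(values, mu0=0.0):
    """Literal 2^n enumeration of sign patterns (independent oracle)."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    lo, hi = min(w_pos, w_neg), max(w_pos, w_neg)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            count += 1
    return count / 2.0**n


class TestWilcoxon:
    def test_eleven_positive_values_give_w66(self):
        res = wilcoxon_signed_rank([0.9998] * 11, mu0=0.0)
        assert (res.w_pos, res.w_neg, res.w_signed) == (66.0, 0.0, 66.0)
        assert res.exact

    def test_eleven_positive_values_exact_p_is_2_over_2048(self):
        res = wilcoxon_signed_rank(np.linspace(0.9, 1.0, 11), mu0=0.0)
        assert res.p_two_tailed == pytest.approx(2.0 / 2048.0)

    def test_single_value_has_p_one(self):
        res = wilcoxon_signed_rank([1.0], mu0=0.0)
        assert res.w_signed == 1.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_all_values_at_hypothesized_median_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.5, 0.5], mu0=0.5)

    def test_zero_differences_are_dropped_before_ranking(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, -1.5], mu0=0.0)
        assert res.n_used == 3

    @pytest.mark.parametrize("n", range(1, 13))
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            # integer magnitudes force ties and midranks
            vals = rng.integers(-4, 5, size=n).astype(float)
            vals[vals == 0] = 1.0
            res = wilcoxon_signed_rank(vals, mu0=0.0)
            assert res.exact
            assert res.p_two_tailed == pytest.approx(
                wilcoxon_enumeration_oracle(vals), abs=1e-12
            )

    def test_agrees_with_scipy_exact_mode(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0.3, 1.0, size=14)
        res = wilcoxon_signed_rank(vals, mu0=0.0)
        ref = sps.wilcoxon(vals, alternative="two-sided", mode="exact")
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0.2, 1.0, size=40)
        res = wilcoxon_signed_rank(vals, mu0=0.0)
        assert not res.exact
        ref = sps.wilcoxon(vals, alternative="two-sided", mode="approx", correction=True)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=0.02)


class TestRunMatrixReport:
    def _toy_frame(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for m, loc in (("A", 0.99), ("B", 0.95)):
            for run, v in enumerate(rng.normal(loc, 0.004, size=11)):
                rows.append({"method": m, "run": run, "accuracy": float(np.clip(v, 0, 1))})
        return pd.DataFrame(rows)

    def test_report_contains_description_anova_and_wilcoxon(self):
        report = run_matrix_report(self._toy_frame())
        assert set(report["description"]) == {"A", "B"}
        assert report["anova"]["df_between"] == 1
        assert report["wilcoxon"]["A"]["w_pos"] == 66.0

    def test_unequal_run_counts_skip_anova_but_keep_descriptions(self):
        df = self._toy_frame().iloc[:-1]
        report = run_matrix_report(df)
        assert report["anova"] is None
        assert "anova_warning" in report
        assert set(report["description"]) == {"A", "B"}

    def test_empty_matrix_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "runs.csv"
        pd.DataFrame(columns=["method", "run", "accuracy"]).to_csv(path, index=False)
        with pytest.raises(ValueError):
            load_run_matrix(path)
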