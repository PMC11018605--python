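"""Diagnostic analysis: changes, Wilcoxon, ROC/AUC, bootstrap, frequency selection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbnpdet.errors import InsufficientDataError, InvalidInputError
from lbnpdet.levels import (
    CONSECUTIVE_PAIRS,
    baseline_variability,
    bootstrap_auc_ci,
    eis_best_frequency,
    relative_change,
    roc_auc,
    run_relative_analysis,
    spec_at_full_sens,
    wilcoxon_compare,
)
from lbnpdet.metrics import MetricSeries
from lbnpdet.protocol import generate_protocol


def _table(rows):
    return pd.DataFrame(rows, columns=["subject", "metric", "level", "mean", "sd",
                                       "n", "frequency_hz"])


def _row(subject, metric, level, mean):
    return {"subject": subject, "metric": metric, "level": level, "mean": mean,
            "sd": 0.0, "n": 10, "frequency_hz": None}


class TestRelativeChange:
    def test_percent_change_hundred_to_101_09(self):
        t = _table([_row("a", "EIT_thx", 0, 100.0), _row("a", "EIT_thx", 15, 101.09)])
        ch = relative_change(t, "EIT_thx", 0, 15, as_percent=True)
        assert ch["value"].iloc[0] == pytest.approx(1.09)

    def test_identical_means_give_zero(self):
        t = _table([_row("a", "HR", 0, 70.0), _row("a", "HR", 15, 70.0)])
        assert relative_change(t, "HR", 0, 15)["value"].iloc[0] == 0.0

    def test_antisymmetry_in_absolute_mode(self, rng):
        rows = []
        for s in "abcd":
            rows += [_row(s, "MAP", 0, rng.normal(90, 5)),
                     _row(s, "MAP", 15, rng.normal(90, 5))]
        t = _table(rows)
        fwd = relative_change(t, "MAP", 0, 15)["value"].to_numpy()
        bwd = relative_change(t, "MAP", 15, 0)["value"].to_numpy()
        assert np.allclose(fwd, -bwd)

    def test_random_table_matches_per_subject_recompute(self, rng):
        rows, expected = [], {}
        for s in ["s1", "s2", "s3", "s4", "s5"]:
            a, b = rng.uniform(50, 150, 2)
            rows += [_row(s, "HR", 15, a), _row(s, "HR", 30, b)]
            expected[s] = 100.0 * (b - a) / a
        ch = relative_change(_table(rows), "HR", 15, 30, as_percent=True)
        for _, r in ch.iterrows():
            assert r["value"] == pytest.approx(expected[r["subject"]])

    def test_missing_level_skips_subject_with_warning(self):
        t = _table([_row("a", "HR", 0, 70.0), _row("a", "HR", 15, 72.0),
                    _row("b", "HR", 0, 60.0)])
        with pytest.warns(UserWarning):
            ch = relative_change(t, "HR", 0, 15)
        assert list(ch["subject"]) == ["a"]

    def test_percent_of_zero_mean_rejected(self):
        t = _table([_row("a", "HR", 0, 0.0), _row("a", "HR", 15, 1.0)])
        with pytest.raises(InvalidInputError):
            relative_change(t, "HR", 0, 15, as_percent=True)


class TestBaselineVariability:
    def test_constant_baseline_gives_zero(self):
        p = generate_protocol(60)
        t = np.arange(0, 300.0, 1.0)
        s = MetricSeries("HR", t, np.full_like(t, 65.0))
        assert baseline_variability(s, p) == pytest.approx(0.0)

    def test_linear_drift_gives_slope_times_half_duration(self):
        """For a ramp of slope s over the baseline of duration D, the
        half-means differ by s*D/2."""
        p = generate_protocol(60)
        slope = 0.02
        t = np.arange(0, 300.0, 0.5)
        s = MetricSeries("HR", t, 10.0 + slope * t)
        D = 300.0
        assert baseline_variability(s, p) == pytest.approx(slope * D / 2, rel=1e-2)

    def test_percent_mode_scales_by_first_half_mean(self):
        p = generate_protocol(60)
        t = np.arange(0, 300.0, 1.0)
        v = np.where(t < 150.0, 100.0, 103.0)
        s = MetricSeries("EIT_thx", t, v)
        assert baseline_variability(s, p, as_percent=True) == pytest.approx(3.0)

    def test_empty_half_window_errors(self):
        p = generate_protocol(60)
        t = np.arange(200.0, 300.0, 1.0)  # second half only
        with pytest.raises(InsufficientDataError):
            baseline_variability(MetricSeries("HR", t, np.ones_like(t)), p)

    def test_zero_mean_noise_nulls_out_over_many_subjects(self, rng):
        p = generate_protocol(60)
        t = np.arange(0, 300.0, 1.0)
        vals = [baseline_variability(
            MetricSeries("HR", t, rng.normal(0, 1, t.size)), p)
            for _ in range(200)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se


def _ranksum_exact_p(a, b):
    """Exhaustive permutation distribution of the rank-sum statistic."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(a)
    observed = ranks[:na].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), na)]
    sums = np.asarray(sums)
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return p


class TestWilcoxon:
    def test_identical_samples_p_one_degenerate(self):
        r = wilcoxon_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0 and r.degenerate

    def test_separated_triplets_match_exhaustive_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        r = wilcoxon_compare(a, b)
        assert r.exact
        assert r.p_value == pytest.approx(_ranksum_exact_p(a, b))
        assert r.p_value == pytest.approx(2 / 20)  # 2 extreme of C(6,3) assignments

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5)
        b = rng.normal(0.5, 1.0, size=6)
        r = wilcoxon_compare(a, b)
        assert r.p_value == pytest.approx(_ranksum_exact_p(a, b), abs=1e-9)

    def test_paired_variant_available(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.5, 2.5, 3.1, 4.4, 5.9]
        r = wilcoxon_compare(a, b, paired=True)
        assert 0 < r.p_value < 1

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_compare([1.0], [2.0, 3.0])


class TestROC:
    def test_perfect_separation_auc_1(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_scores_equal_auc_half(self):
        r = roc_auc([5.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_all_pairs_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(2, 9, 2)
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # induces ties
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        r = roc_auc(scores, labels)
        pos, neg = scores[:n_pos], scores[n_pos:]
        wins = sum(p > n for p in pos for n in neg)
        ties = sum(p == n for p in pos for n in neg)
        assert r.auc == pytest.approx((wins + 0.5 * ties) / (n_pos * n_neg))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=14)
        labels = np.r_[np.ones(7, int), np.zeros(7, int)]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(2.0 * scores) + 3.0, labels).auc
        assert a1 == pytest.approx(a2)

    def test_curve_monotone_from_origin_to_one_one(self, rng):
        r = roc_auc(rng.normal(size=30), rng.integers(0, 2, 30) | np.r_[1, np.zeros(29, int)])
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


class TestBootstrapCI:
    def test_perfect_separation_ci_is_one_one(self):
        scores = [1, 2, 3, 4, 10, 11, 12, 13]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        assert bootstrap_auc_ci(scores, labels, seed=1) == (1.0, 1.0)

    def test_same_seed_identical_interval(self, rng):
        scores = rng.normal(size=32)
        labels = np.r_[np.ones(16, int), np.zeros(16, int)]
        assert bootstrap_auc_ci(scores, labels, seed=9) == \
            bootstrap_auc_ci(scores, labels, seed=9)

    def test_interval_brackets_point_estimate(self, rng):
        scores = np.r_[rng.normal(1.0, 1, 16), rng.normal(0, 1, 16)]
        labels = np.r_[np.ones(16, int), np.zeros(16, int)]
        lo, hi = bootstrap_auc_ci(scores, labels, seed=2)
        auc = roc_auc(scores, labels).auc
        assert lo <= auc <= hi


class TestOperatingPoints:
    def test_perfect_separation_full_spec_at_full_sens(self):
        r = roc_auc([0, 1, 10, 11], [0, 0, 1, 1])
        assert spec_at_full_sens(r) == 1.0

    def test_all_equal_scores_zero_spec(self):
        r = roc_auc([5.0] * 8, [0, 1] * 4)
        assert spec_at_full_sens(r) == 0.0

    def test_fourteen_of_sixteen_negatives_below_min_positive(self, rng):
        neg = np.concatenate([rng.uniform(0, 1, 14), [2.5, 3.0]])
        pos = rng.uniform(2, 2.4, 16)  # min positive 2.0 > 14 negatives
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(16, int), np.zeros(16, int)]
        assert spec_at_full_sens(roc_auc(scores, labels)) == pytest.approx(14 / 16)


class TestBestFrequency:
    def _roc(self, auc):
        r = roc_auc([0, 1, 10, 11], [0, 0, 1, 1])
        r.auc = auc
        return r

    def test_single_frequency_returned(self):
        f, r = eis_best_frequency({1000.0: self._roc(0.7)})
        assert f == 1000.0

    def test_higher_auc_wins(self):
        f, _ = eis_best_frequency({100.0: self._roc(0.7), 5000.0: self._roc(0.9)})
        assert f == 5000.0

    def test_ties_break_to_lowest_frequency(self):
        f, _ = eis_best_frequency({5000.0: self._roc(0.8), 100.0: self._roc(0.8)})
        assert f == 100.0

    def test_empty_map_rejected(self):
        with pytest.raises(InvalidInputError):
            eis_best_frequency({})


class TestRelativeAnalysisPlumbing:
    def test_positive_changes_vs_centred_baseline_dominate_zero_threshold(
            self, small_metrics):
        """If every EIT_thx change is positive and baseline changes straddle 0,
        AUC must be at least the specificity of a threshold at zero."""
        rep = run_relative_analysis(small_metrics, n_boot=50, seed=0)
        row = rep[(rep["metric"] == "EIT_thx") & (rep["from_level"] == 0)].iloc[0]
        assert row["auc"] >= 0.5
        assert row["ci_low"] <= row["auc"] <= row["ci_high"]

    def test_report_covers_all_metrics_and_pairs(self, small_metrics):
        rep = run_relative_analysis(small_metrics, n_boot=50, seed=0)
        assert set(rep["metric"]) == {"MAP", "HR", "PlethA", "EIT_thx", "EIT_ab",
                                      "EIS_thx", "EIS_ab", "EIS_arm"}
        for metric, grp in rep.groupby("metric"):
            assert len(grp) == len(CONSECUTIVE_PAIRS)

    def test_eis_rows_flag_selection_bias_and_carry_frequency(self, small_metrics):
        rep = run_relative_analysis(small_metrics, n_boot=50, seed=0)
        eis = rep[rep["metric"].str.startswith("EIS")]
        assert eis["selection_biased"].all()
        assert eis["frequency_hz"].notna().all()
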