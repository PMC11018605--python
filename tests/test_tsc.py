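"""Slope features, fold construction, forest evaluation, and majority fusion."""

import numpy as np
import pandas as pd
import pytest

from lbnpdet.errors import InsufficientDataError, InvalidInputError
from lbnpdet.metrics import MetricSeries, SubjectMetrics
from lbnpdet.protocol import generate_protocol
from lbnpdet.tsc import (
    ForestConfig,
    augment_baseline,
    build_dataset,
    class_imbalance,
    fuse_majority,
    make_folds,
    slope_samples,
    train_eval_technology,
)


def _subject(values_per_minute, subject_id="T1", tolerance=60, step_duration=300.0):
    """SubjectMetrics with a single 1 Hz MAP channel holding given minute values."""
    p = generate_protocol(tolerance, step_duration=step_duration)
    t = np.arange(0.0, p.total_duration, 1.0)
    minute = np.floor(t / 60.0).astype(int)
    vals = np.asarray(values_per_minute, dtype=float)[np.clip(minute, 0, len(values_per_minute) - 1)]
    series = {"MAP": MetricSeries("MAP", t, vals)}
    return SubjectMetrics(subject_id=subject_id, protocol=p, series=series,
                          eis={}, hrv=pd.DataFrame())


class TestSlopeFeatures:
    def test_linear_minutes_give_unit_slopes(self):
        sm = _subject(np.arange(40.0))
        df = slope_samples(sm, "MAP", window_points=3)
        assert len(df) > 0
        for f in df["features"]:
            assert f[0] == pytest.approx(1.0)

    def test_constant_series_gives_zero_slopes(self):
        sm = _subject(np.full(40, 7.0))
        df = slope_samples(sm, "MAP", window_points=4)
        for f in df["features"]:
            assert f[0] == pytest.approx(0.0)

    def test_slopes_match_normal_equations_oracle(self, rng):
        vals = rng.normal(size=40)
        sm = _subject(vals)
        df = slope_samples(sm, "MAP", window_points=5)
        for _, row in df.iterrows():
            i = row["start_minute"]
            w = vals[i:i + 5]
            t = np.arange(5.0)
            A = np.vstack([t, np.ones(5)]).T
            slope_oracle = np.linalg.lstsq(A, w, rcond=None)[0][0]
            assert row["features"][0] == pytest.approx(slope_oracle)

    def test_class0_only_from_baseline(self):
        sm = _subject(np.arange(40.0))
        df = slope_samples(sm, "MAP", window_points=2)
        c0 = df[df["class"] == 0]
        assert (c0["start_minute"] < 5).all()
        assert c0["change"].isna().all()

    def test_class1_windows_attributed_to_consecutive_pairs(self):
        sm = _subject(np.arange(40.0))
        df = slope_samples(sm, "MAP", window_points=7)
        c1 = df[df["class"] == 1]
        assert set(c1["change"]) <= {(0, 15), (15, 30), (30, 45), (45, 60)}
        # a 7-point window must reach into the upper step of its pair
        for _, r in c1.iterrows():
            lo, hi = r["change"]
            s_hi = sm.protocol.step_for_level(hi)
            assert (r["start_minute"] + 7) * 60.0 > s_hi.start_time

    def test_seven_point_windows_give_four_per_change(self):
        sm = _subject(np.arange(40.0))
        df = slope_samples(sm, "MAP", window_points=7)
        counts = df[df["class"] == 1].groupby("change").size()
        assert all(counts == 4)

    def test_window_shorter_than_two_points_rejected(self):
        with pytest.raises(InvalidInputError):
            slope_samples(_subject(np.arange(40.0)), "MAP", window_points=1)


class TestAugmentBaseline:
    @pytest.mark.parametrize("m", range(4, 11))
    def test_count_formula_m_minus_1_2_3(self, m):
        # baseline of m minutes via a stretched protocol step
        sm = _subject(np.arange(9 * m, dtype=float), step_duration=60.0 * m)
        df = augment_baseline(sm, "MAP")
        assert len(df) == (m - 1) + (m - 2) + (m - 3)
        assert (df["class"] == 0).all()

    def test_short_baseline_warns_and_uses_available_lengths(self):
        sm = _subject(np.arange(27.0), step_duration=180.0)  # 3-minute baseline
        with pytest.warns(UserWarning):
            df = augment_baseline(sm, "MAP")
        assert len(df) == 2 + 1  # only 2- and 3-point windows fit

    def test_cohort_count_is_additive_over_subjects(self, small_metrics):
        per_subject = [len(augment_baseline(sm, "MAP"))
                       for sm in small_metrics.subjects]
        ds = build_dataset(small_metrics, "MAP", window_points=7)
        assert (ds["class"] == 0).sum() == sum(per_subject)
        assert all(c == 9 for c in per_subject)  # 5-min baseline: 4+3+2


class TestClassImbalance:
    def test_printed_sample_counts(self):
        assert class_imbalance(111, 257) == pytest.approx(43.2, abs=0.05)
        assert class_imbalance(111, 284) == pytest.approx(39.1, abs=0.05)

    def test_balanced_is_100(self):
        assert class_imbalance(50, 50) == 100.0

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidInputError):
            class_imbalance(0, 10)


class TestFolds:
    def test_sixteen_subjects_13_train_3_test_disjoint(self):
        subjects = [f"S{i:02d}" for i in range(16)]
        folds = make_folds(subjects, seed=1)
        assert len(folds) == 15
        for f in folds:
            assert len(f.train_subjects) == 13
            assert len(f.test_subjects) == 3
            assert not set(f.train_subjects) & set(f.test_subjects)
            assert set(f.train_subjects) | set(f.test_subjects) == set(subjects)

    def test_test_triples_distinct_across_folds(self):
        folds = make_folds([f"S{i}" for i in range(16)], seed=2)
        triples = {tuple(sorted(f.test_subjects)) for f in folds}
        assert len(triples) == 15  # C(16,3)=560 >= 15 distinct draws

    def test_same_seed_reproducible(self):
        a = make_folds([f"S{i}" for i in range(16)], seed=3)
        b = make_folds([f"S{i}" for i in range(16)], seed=3)
        assert a == b

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidInputError):
            make_folds(["a", "b", "c", "d"], n_test=3)


def _toy_samples(rng, n_subjects=8, sep=8.0, n_feat=3):
    """Separable two-class slope samples across subjects."""
    rows = []
    for i in range(n_subjects):
        sid = f"P{i}"
        for k in range(6):
            rows.append({"subject": sid, "technology": "TOY", "window_points": 3,
                         "start_minute": k, "class": 0, "change": None,
                         "features": rng.normal(0, 1, n_feat)})
            rows.append({"subject": sid, "technology": "TOY", "window_points": 7,
                         "start_minute": 10 + k, "class": 1, "change": (0, 15),
                         "features": rng.normal(sep, 1, n_feat)})
    return pd.DataFrame(rows)


class TestForestEvaluation:
    def test_separable_features_perfect_scores(self, rng):
        samples = _toy_samples(rng)
        folds = make_folds(samples["subject"].unique(), n_folds=6, n_test=2, seed=0)
        ev = train_eval_technology(samples, folds, ForestConfig(n_trees=50, seed=0))
        assert ev.mean_f1 == pytest.approx(1.0)
        assert ev.mean_auc == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self, rng):
        samples = _toy_samples(rng, sep=3.0)
        samples["class"] = rng.permutation(samples["class"].to_numpy())
        folds = make_folds(samples["subject"].unique(), n_folds=8, n_test=2, seed=1)
        ev = train_eval_technology(samples, folds, ForestConfig(n_trees=100, seed=1))
        assert 0.35 < ev.mean_auc < 0.65

    def test_no_test_subject_in_training_predictions(self, rng):
        samples = _toy_samples(rng)
        folds = make_folds(samples["subject"].unique(), n_folds=6, n_test=2, seed=2)
        ev, preds = train_eval_technology(samples, folds,
                                          ForestConfig(n_trees=20, seed=0),
                                          return_predictions=True)
        by_fold = {f.fold_id: f for f in folds}
        for fold_id, grp in preds.groupby("fold_id"):
            fold = by_fold[fold_id]
            assert set(grp["subject"]) <= set(fold.test_subjects)
            assert not set(grp["subject"]) & set(fold.train_subjects)

    def test_duplicated_feature_columns_similar_eval(self, rng):
        samples = _toy_samples(rng, sep=2.0)
        dup = samples.copy()
        dup["features"] = dup["features"].apply(lambda f: np.concatenate([f, f]))
        folds = make_folds(samples["subject"].unique(), n_folds=6, n_test=2, seed=3)
        cfg = ForestConfig(n_trees=100, seed=5)
        e1 = train_eval_technology(samples, folds, cfg)
        e2 = train_eval_technology(dup, folds, cfg)
        assert abs(e1.mean_f1 - e2.mean_f1) < 0.1

    def test_empty_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            train_eval_technology(pd.DataFrame(), [], ForestConfig())


class TestMajorityFusion:
    def test_two_to_one_vote(self):
        fused = fuse_majority({"a": [1], "b": [1], "c": [0]})
        assert fused.tolist() == [1]

    def test_even_tie_resolves_to_class_1(self):
        fused = fuse_majority({"a": [1, 0], "b": [0, 0]})
        assert fused.tolist() == [1, 0]

    def test_matches_counting_oracle(self, rng):
        votes = {f"t{i}": rng.integers(0, 2, 40) for i in range(5)}
        fused = fuse_majority(votes)
        for j in range(40):
            n1 = sum(votes[t][j] for t in votes)
            expected = 1 if n1 >= len(votes) - n1 else 0
            assert fused[j] == expected

    def test_fusing_identical_predictors_is_identity(self, rng):
        v = rng.integers(0, 2, 25)
        fused = fuse_majority({"a": v, "b": v, "c": v})
        assert np.array_equal(fused, v)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            fuse_majority({"a": [1, 0], "b": [1]})
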