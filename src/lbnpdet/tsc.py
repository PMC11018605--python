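"""Slope-feature time-series classification of hypovolemia.

Each technology's minute-level feature series (one column for MAP, HR,
Pleth_A and each EIT belt; 20 columns for HRV; a frequency subset for each
EIS site) is turned into rolling-window ordinary-least-squares slopes.
Windows fully inside the baseline step are normovolemic (class 0) and, to
enlarge the scarce normovolemic set, class-0 slopes are pooled across 2-,
3- and 4-point windows (the baseline is stable, so window length does not
change the expected slope).  Hypovolemic windows (class 1) are attributed
to a consecutive LBNP change (L1, L2) when they lie fully inside the two
steps of the change and reach into the upper step, so each per-change model
sees windows that witness that change.

Per technology, a random forest (500 trees, Gini splits, unlimited depth)
is trained and evaluated under subject-wise cross-validation: 15 folds,
each holding out 3 randomly drawn subjects (13 train).  With 16 subjects,
15 disjoint test triples cannot partition the cohort, so folds are
independent random draws with distinct test sets.  Out-of-sample AUC is
computed from forest vote fractions and F1 (hypovolemia positive) at the
0.5 vote threshold.  Technology ensembles fuse per-sample binary
predictions by majority vote, ties resolved toward hypovolemia (the alarm
context favours sensitivity); the fused vote fraction serves as the score
for the fused AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score

from .errors import InsufficientDataError, InvalidInputError
from .metrics import CohortMetrics, SubjectMetrics, minute_average
from .levels import CONSECUTIVE_PAIRS

TECHNOLOGIES = ("MAP", "HR", "HRV", "PlethA",
                "EIT_thx", "EIT_ab", "EIS_thx", "EIS_ab", "EIS_arm")
VITAL_TECHNOLOGIES = ("MAP", "HR", "HRV", "PlethA")
IMPEDANCE_TECHNOLOGIES = ("EIT_thx", "EIT_ab", "EIS_thx", "EIS_ab", "EIS_arm")
FUSIONS = {
    "Fused_Vitals": VITAL_TECHNOLOGIES,
    "Fused_EIT,EIS": IMPEDANCE_TECHNOLOGIES,
    "Fused_All": TECHNOLOGIES,
}

#: indices into the 100-point EIS grid used as default EIS features
EIS_FEATURE_FREQ_IDX = tuple(range(0, 100, 10))

BASELINE_WINDOW_POINTS = (2, 3, 4)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_depth: int | None = None
    criterion: str = "gini"
    seed: int = 0


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise InvalidInputError("train/test subject overlap in fold")


# ---------------------------------------------------------------------------
# feature matrices and slope samples


def technology_matrix(sm: SubjectMetrics, technology: str
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(minute_times, minutes x features matrix, feature names) for one subject."""
    t_end = sm.protocol.total_duration
    if technology == "HRV":
        X = sm.hrv.to_numpy(float)
        times = sm.hrv.index.to_numpy(float)
        names = list(sm.hrv.columns)
    elif technology.startswith("EIS_"):
        site = technology.split("_", 1)[1]
        mags = sm.eis[site]
        cols = []
        for j in EIS_FEATURE_FREQ_IDX:
            ms = minute_average(mags.series_at(j), t_end)
            cols.append(ms.values)
            times = ms.times
        X = np.column_stack(cols)
        names = [f"{technology}_f{mags.freqs[j]:.0f}Hz" for j in EIS_FEATURE_FREQ_IDX]
    else:
        ms = minute_average(sm.series[technology], t_end)
        times = ms.times
        X = ms.values[:, None]
        names = [technology]
    return times, X, names


def _ols_slopes(X: np.ndarray) -> np.ndarray:
    """Least-squares slope per column over the window's minute index.

    Columns with missing minutes use their finite points only; a column
    with fewer than 2 finite points yields NaN (the window is then dropped).
    """
    n = X.shape[0]
    t = np.arange(n, dtype=float)
    if np.all(np.isfinite(X)):
        tc = t - t.mean()
        return (tc @ (X - X.mean(axis=0))) / np.sum(tc ** 2)
    out = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        ok = np.isfinite(X[:, j])
        if ok.sum() < 2:
            continue
        tj = t[ok]
        tc = tj - tj.mean()
        out[j] = tc @ (X[ok, j] - X[ok, j].mean()) / np.sum(tc ** 2)
    return out


def _window_assignment(protocol, t_start: float, t_end: float,
                       pairs=CONSECUTIVE_PAIRS):
    """Class and change attribution for a window spanning [t_start, t_end)."""
    base = protocol.step_for_level(0)
    if t_start >= base.start_time and t_end <= base.end_time:
        return 0, None
    for lo, hi in pairs:
        if lo not in protocol.levels or hi not in protocol.levels:
            continue
        s_lo = protocol.step_for_level(lo)
        s_hi = protocol.step_for_level(hi)
        if t_start >= s_lo.start_time and t_end <= s_hi.end_time and t_end > s_hi.start_time:
            return 1, (lo, hi)
    return None, None


def slope_samples(sm: SubjectMetrics, technology: str, window_points: int,
                  pairs=CONSECUTIVE_PAIRS) -> pd.DataFrame:
    """Rolling-window slope samples (stride one minute) for one subject.

    Windows of ``window_points`` consecutive minute points; windows
    containing missing minutes, or not attributable to the baseline or to a
    single consecutive change, are dropped.
    """
    if window_points < 2:
        raise InvalidInputError("a slope needs at least 2 points")
    times, X, names = technology_matrix(sm, technology)
    rows = []
    for i in range(0, X.shape[0] - window_points + 1):
        w = X[i:i + window_points]
        slopes = _ols_slopes(w)
        if not np.all(np.isfinite(slopes)):
            continue
        t_start = times[i] - 30.0           # minute-start of first point
        t_end = times[i + window_points - 1] + 30.0  # minute-end of last point
        cls, change = _window_assignment(sm.protocol, t_start, t_end, pairs)
        if cls is None:
            continue
        rows.append({
            "subject": sm.subject_id, "technology": technology,
            "window_points": window_points, "start_minute": int(round(t_start / 60.0)),
            "class": cls, "change": change,
            "features": slopes,
        })
    return pd.DataFrame(rows)


def augment_baseline(sm: SubjectMetrics, technology: str,
                     window_points=BASELINE_WINDOW_POINTS) -> pd.DataFrame:
    """Class-0 slope samples pooled over 2-, 3- and 4-point windows.

    For m usable baseline minutes this yields (m-1) + (m-2) + (m-3) samples
    per subject; shorter baselines use whatever window lengths fit, with a
    warning.
    """
    times, X, _ = technology_matrix(sm, technology)
    base = sm.protocol.step_for_level(0)
    in_base = (times - 30.0 >= base.start_time) & (times + 30.0 <= base.end_time)
    m = int(np.sum(in_base & np.all(np.isfinite(X), axis=1)))
    usable = [w for w in window_points if w <= m]
    if len(usable) < len(window_points):
        warnings.warn(f"{technology}: only {m} usable baseline minutes for "
                      f"{sm.subject_id}; window lengths {usable} used", stacklevel=2)
    frames = [slope_samples(sm, technology, w) for w in usable]
    if not frames:
        return pd.DataFrame(columns=["subject", "technology", "window_points",
                                     "start_minute", "class", "change", "features"])
    df = pd.concat(frames, ignore_index=True)
    return df[df["class"] == 0].reset_index(drop=True)


def build_dataset(cohort: CohortMetrics, technology: str, window_points: int,
                  change: tuple[int, int] | None = None) -> pd.DataFrame:
    """Full sample table for one technology: augmented class 0 + class 1.

    Class-1 samples use ``window_points``-point windows; when ``change`` is
    given only windows attributed to that consecutive pair are kept.
    """
    frames = []
    for sm in cohort.subjects:
        frames.append(augment_baseline(sm, technology))
        hyp = slope_samples(sm, technology, window_points)
        hyp = hyp[hyp["class"] == 1]
        if change is not None:
            hyp = hyp[hyp["change"].apply(lambda c: c == tuple(change))]
        frames.append(hyp)
    return pd.concat(frames, ignore_index=True)


def class_imbalance(n_class0: int, n_class1: int) -> float:
    """Minority-to-majority percent ratio of the two class counts."""
    if n_class0 <= 0 or n_class1 <= 0:
        raise InvalidInputError("both class counts must be positive")
    return 100.0 * min(n_class0, n_class1) / max(n_class0, n_class1)


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(subject_ids, n_folds: int = 15, n_test: int = 3,
               seed: int = 0) -> list[FoldSpec]:
    """Independent random test draws: ``n_test`` held-out subjects per fold.

    Test sets are distinct across folds whenever the cohort admits enough
    distinct combinations.  This is not a partition — with 16 subjects and
    15 x 3 held-out slots, subjects necessarily recur across folds.
    """
    subjects = tuple(sorted(map(str, subject_ids)))
    if len(subjects) < n_test + 2:
        raise InvalidInputError(
            f"need at least {n_test + 2} subjects for {n_test}-subject test folds")
    rng = np.random.default_rng(seed)
    from math import comb
    distinct_possible = comb(len(subjects), n_test) >= n_folds
    seen: set[tuple[str, ...]] = set()
    folds = []
    for fold_id in range(1, n_folds + 1):
        for _ in range(10_000):
            test = tuple(sorted(rng.choice(len(subjects), size=n_test, replace=False)))
            key = tuple(subjects[i] for i in test)
            if not distinct_possible or key not in seen:
                seen.add(key)
                break
        train = tuple(s for s in subjects if s not in key)
        folds.append(FoldSpec(fold_id=fold_id, train_subjects=train, test_subjects=key))
    return folds


@dataclass
class ModelEval:
    name: str                      # technology or fusion name
    change: tuple[int, int] | None
    window_points: int
    fold_auc: np.ndarray
    fold_f1: np.ndarray
    skipped_folds: list[int] = field(default_factory=list)

    @staticmethod
    def _ci(x: np.ndarray) -> tuple[float, float]:
        x = x[np.isfinite(x)]
        if x.size < 2:
            return (np.nan, np.nan)
        half = 1.96 * np.std(x, ddof=1) / np.sqrt(x.size)
        return (float(np.mean(x) - half), float(np.mean(x) + half))

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.fold_auc))

    @property
    def mean_f1(self) -> float:
        return float(np.nanmean(self.fold_f1))

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self._ci(self.fold_auc)

    @property
    def f1_ci(self) -> tuple[float, float]:
        return self._ci(self.fold_f1)

    def as_row(self) -> dict:
        return {"name": self.name,
                "change": f"{self.change[0]}-{self.change[1]}" if self.change else "all",
                "window_points": self.window_points,
                "mean_auc": self.mean_auc, "mean_f1": self.mean_f1,
                "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1],
                "f1_ci_low": self.f1_ci[0], "f1_ci_high": self.f1_ci[1],
                "n_folds": int(np.isfinite(self.fold_f1).sum())}


def _fit_predict_fold(samples: pd.DataFrame, fold: FoldSpec, forest: ForestConfig,
                      rf_seed: int) -> pd.DataFrame | None:
    train = samples[samples["subject"].isin(fold.train_subjects)]
    test = samples[samples["subject"].isin(fold.test_subjects)]
    assert not set(test["subject"]) & set(train["subject"])  # no leakage, ever
    if train.empty or test.empty or train["class"].nunique() < 2:
        return None
    Xtr = np.vstack(train["features"].to_numpy())
    ytr = train["class"].to_numpy(int)
    Xte = np.vstack(test["features"].to_numpy())
    clf = RandomForestClassifier(
        n_estimators=forest.n_trees, criterion=forest.criterion,
        max_depth=forest.max_depth, random_state=rf_seed, n_jobs=1)
    clf.fit(Xtr, ytr)
    proba = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
    out = test[["subject", "window_points", "start_minute", "class"]].copy()
    out["vote_fraction"] = proba
    out["pred"] = (proba >= 0.5).astype(int)
    out["fold_id"] = fold.fold_id
    return out


def _score_folds(preds: pd.DataFrame, name: str, change, window_points: int,
                 n_folds: int, skipped: list[int]) -> ModelEval:
    auc = np.full(n_folds, np.nan)
    f1 = np.full(n_folds, np.nan)
    for fold_id, grp in preds.groupby("fold_id"):
        i = int(fold_id) - 1
        y = grp["class"].to_numpy(int)
        f1[i] = f1_score(y, grp["pred"], pos_label=1, zero_division=0)
        if np.unique(y).size == 2:
            auc[i] = roc_auc_score(y, grp["vote_fraction"])
    return ModelEval(name=name, change=change, window_points=window_points,
                     fold_auc=auc, fold_f1=f1, skipped_folds=skipped)


def train_eval_technology(samples: pd.DataFrame, folds: list[FoldSpec],
                          forest: ForestConfig, name: str | None = None,
                          change=None, window_points: int | None = None,
                          return_predictions: bool = False):
    """Subject-wise cross-validated random-forest evaluation of one technology.

    Folds whose training split has a single class are skipped with a warning
    and recorded.  AUC uses forest vote fractions; F1 thresholds votes at 0.5.
    """
    if samples.empty:
        raise InsufficientDataError("no samples to train on")
    name = name or str(samples["technology"].iloc[0])
    window_points = window_points or int(samples["window_points"].max())
    all_preds = []
    skipped = []
    for fold in folds:
        preds = _fit_predict_fold(samples, fold, forest,
                                  rf_seed=forest.seed + fold.fold_id)
        if preds is None:
            warnings.warn(f"{name}: fold {fold.fold_id} skipped "
                          "(single-class or empty split)", stacklevel=2)
            skipped.append(fold.fold_id)
            continue
        all_preds.append(preds)
    if not all_preds:
        raise InsufficientDataError(f"{name}: every fold was skipped")
    preds = pd.concat(all_preds, ignore_index=True)
    ev = _score_folds(preds, name, change, window_points, len(folds), skipped)
    return (ev, preds) if return_predictions else ev


# ---------------------------------------------------------------------------
# fusion


def fuse_majority(per_technology_predictions: dict[str, np.ndarray],
                  subset=None) -> np.ndarray:
    """Majority vote over technologies; ties resolve to class 1.

    All vote vectors must be aligned on the same sample index.
    """
    subset = tuple(subset) if subset is not None else tuple(per_technology_predictions)
    votes = [np.asarray(per_technology_predictions[t], dtype=int) for t in subset]
    lengths = {v.size for v in votes}
    if len(lengths) != 1:
        raise InvalidInputError("technologies predict on mismatched sample indices")
    stacked = np.vstack(votes)
    n_pos = stacked.sum(axis=0)
    return (2 * n_pos >= stacked.shape[0]).astype(int)


_SAMPLE_KEY = ["subject", "window_points", "start_minute", "fold_id"]


def fuse_predictions(pred_frames: dict[str, pd.DataFrame], subset,
                     name: str, change, window_points: int,
                     n_folds: int) -> ModelEval:
    """Fuse per-technology fold predictions on their shared sample index."""
    subset = tuple(subset)
    merged = None
    for t in subset:
        df = pred_frames[t][_SAMPLE_KEY + ["class", "pred", "vote_fraction"]].rename(
            columns={"pred": f"pred_{t}", "vote_fraction": f"vf_{t}"})
        merged = df if merged is None else merged.merge(
            df, on=_SAMPLE_KEY + ["class"], how="inner")
    if merged is None or merged.empty:
        raise InvalidInputError("no shared samples to fuse")
    fused_pred = fuse_majority({t: merged[f"pred_{t}"].to_numpy() for t in subset})
    merged["pred"] = fused_pred
    merged["vote_fraction"] = merged[[f"pred_{t}" for t in subset]].mean(axis=1)
    return _score_folds(merged, name, change, window_points, n_folds, [])


# ---------------------------------------------------------------------------
# pipeline


def run_ml_pipeline(cohort: CohortMetrics, window_points: int = 7,
                    forest: ForestConfig | None = None, seed: int = 0,
                    technologies=TECHNOLOGIES, fusions: dict | None = None,
                    changes=CONSECUTIVE_PAIRS, folds: list[FoldSpec] | None = None,
                    ) -> pd.DataFrame:
    """Per-technology and fused cross-validated evaluation per LBNP change.

    Returns one row per (model, change) with mean AUC/F1 and fold-wise 95%
    CIs.  The 7-point window is the headline setting; callers may sweep
    ``window_points`` over 2..7.
    """
    forest = forest or ForestConfig(seed=seed)
    fusions = FUSIONS if fusions is None else fusions
    subject_ids = [sm.subject_id for sm in cohort.subjects]
    folds = folds or make_folds(subject_ids, seed=seed)
    rows = []
    for change in changes:
        pred_frames: dict[str, pd.DataFrame] = {}
        for t in technologies:
            ds = build_dataset(cohort, t, window_points, change=change)
            ev, preds = train_eval_technology(
                ds, folds, forest, name=t, change=change,
                window_points=window_points, return_predictions=True)
            pred_frames[t] = preds
            rows.append(ev.as_row())
        for fname, subset in fusions.items():
            usable = [t for t in subset if t in pred_frames]
            if len(usable) < 2:
                continue
            ev = fuse_predictions(pred_frames, usable, fname, change,
                                  window_points, len(folds))
            rows.append(ev.as_row())
    return pd.DataFrame(rows)
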