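"""Absolute and relative diagnostic evaluation of per-level metrics.

The *absolute* analysis asks whether the raw value of a metric at one LBNP
level separates hypovolemia (LBNP > 0) from normovolemia (baseline).  The
*relative* analysis asks whether the metric's *change* across a consecutive
level pair separates from its change over the baseline period (baseline
variability) — the clinically interesting question, since it needs no
calibrated healthy reference.

Statistics: two-sided Wilcoxon tests (rank-sum between groups, signed-rank
within subjects), trapezoidal ROC/AUC with the Mann-Whitney tie-handling
convention, stratified percentile bootstrap CIs (500 resamples), the
specificity attainable at 100% sensitivity, and per-frequency evaluation of
EIS metrics followed by max-AUC frequency selection (flagged as
optimistically biased, since the selection peeks at the labels).

Score orientation is fixed a priori from the known physiological sign of
each effect (impedance and HR rise under hypovolemia, MAP and pleth area
fall); auto-flipping per dataset would inflate AUCs and is deliberately not
done.  No multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import InsufficientDataError, InvalidInputError
from .metrics import CohortMetrics, MetricSeries
from .protocol import ANALYSIS_LEVELS, ProtocolTimeline

#: a priori score orientation: +1 if the metric rises under hypovolemia
METRIC_SIGN: dict[str, int] = {
    "MAP": -1, "HR": +1, "PlethA": -1,
    "EIT_thx": +1, "EIT_ab": +1, "EIS_thx": +1, "EIS_ab": +1, "EIS_arm": +1,
}

#: consecutive level pairs of the occult range
CONSECUTIVE_PAIRS: tuple[tuple[int, int], ...] = ((0, 15), (15, 30), (30, 45), (45, 60))

#: metrics whose changes are expressed as percent of the lower level
PERCENT_METRICS = ("EIT_thx", "EIT_ab", "EIS_thx", "EIS_ab", "EIS_arm")


# ---------------------------------------------------------------------------
# change samples


def relative_change(table: pd.DataFrame, metric: str, from_level: int, to_level: int,
                    as_percent: bool = False,
                    frequency_hz: float | None = None) -> pd.DataFrame:
    """Per-subject change of a metric between two levels.

    ``value = mean(to) - mean(from)``, or ``100 * (mean(to) - mean(from)) /
    mean(from)`` in percent mode.  Subjects missing either level are skipped
    with a warning.
    """
    sel = (table["metric"] == metric)
    if frequency_hz is not None:
        sel &= np.isclose(table["frequency_hz"].astype(float), frequency_hz)
    sub = table[sel]
    rows = []
    for subject, grp in sub.groupby("subject"):
        by_level = grp.set_index("level")["mean"]
        if from_level not in by_level.index or to_level not in by_level.index:
            warnings.warn(f"{metric}: subject {subject} missing level "
                          f"{from_level} or {to_level}; skipped", stacklevel=2)
            continue
        a, b = float(by_level[from_level]), float(by_level[to_level])
        if as_percent:
            if a == 0:
                raise InvalidInputError(
                    f"{metric}: percent change undefined, mean({from_level})=0 "
                    f"for subject {subject}")
            value = 100.0 * (b - a) / a
        else:
            value = b - a
        rows.append({"subject": subject, "metric": metric, "kind": "level_change",
                     "from_level": from_level, "to_level": to_level,
                     "value": value, "frequency_hz": frequency_hz})
    return pd.DataFrame(rows)


def baseline_variability(series: MetricSeries, protocol: ProtocolTimeline,
                         as_percent: bool = False) -> float:
    """Metric change over the 5-min baseline period of one subject.

    Defined as the mean over the second half of the baseline step minus the
    mean over the first half (percent of the first-half mean in percent
    mode).  This is the negative-class analogue of a consecutive-level
    change: same metric, same averaging, no applied suction.
    """
    step = protocol.step_for_level(0)
    mid = 0.5 * (step.start_time + step.end_time)
    first = (series.times >= step.start_time) & (series.times < mid)
    second = (series.times >= mid) & (series.times < step.end_time)
    v1 = series.values[first]
    v2 = series.values[second]
    v1, v2 = v1[np.isfinite(v1)], v2[np.isfinite(v2)]
    if v1.size == 0 or v2.size == 0:
        raise InsufficientDataError(
            f"{series.metric_name}: baseline too short for two half-windows")
    m1, m2 = float(np.mean(v1)), float(np.mean(v2))
    if as_percent:
        if m1 == 0:
            raise InvalidInputError(f"{series.metric_name}: percent baseline "
                                    "variability undefined (first-half mean 0)")
        return 100.0 * (m2 - m1) / m1
    return m2 - m1


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    degenerate: bool = False
    exact: bool = False


def wilcoxon_compare(group_a, group_b, paired: bool = False) -> WilcoxonResult:
    """Two-sided Wilcoxon comparison of two samples.

    Unpaired uses the rank-sum (Mann-Whitney) test; paired uses the
    signed-rank test for within-subject contrasts.  The exact null
    distribution is used at small n without ties; otherwise the normal
    approximation with tie/continuity correction.  Identical samples are a
    degenerate case reported as p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if paired and a.size != b.size:
        raise InvalidInputError("paired comparison needs equal-length groups")

    if paired:
        d = a - b
        if np.all(d == 0):
            return WilcoxonResult(p_value=1.0, statistic=0.0, degenerate=True)
        nz = d[d != 0]
        no_ties = np.unique(np.abs(nz)).size == nz.size
        exact = nz.size <= 12 and no_ties
        res = stats.wilcoxon(a, b, alternative="two-sided",
                             method="exact" if exact else "approx",
                             correction=not exact, zero_method="wilcox")
        return WilcoxonResult(p_value=float(res.pvalue), statistic=float(res.statistic),
                              exact=exact)

    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return WilcoxonResult(p_value=1.0, statistic=a.size * b.size / 2.0,
                              degenerate=True)
    no_ties = np.unique(pooled).size == pooled.size
    exact = min(a.size, b.size) <= 12 and no_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=not exact)
    return WilcoxonResult(p_value=float(res.pvalue), statistic=float(res.statistic),
                          exact=exact)


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def operating_points(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.tpr,
                             "specificity": 1.0 - self.fpr})


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC; ties get the half-credit convention.

    The trapezoidal AUC over the full (non-dropped) curve equals the
    Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise InvalidInputError("scores and labels must be equal-length, non-empty")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise InvalidInputError(f"labels must contain both classes 0 and 1, got {classes}")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr,
                     n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()))


def _auc_only(pos: np.ndarray, neg: np.ndarray) -> float:
    # Mann-Whitney formulation, half credit for ties
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def bootstrap_auc_ci(scores, labels, n_boot: int = 500, seed: int = 0,
                     alpha: float = 0.05, expand: bool = True) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Resampling within each class keeps every replicate two-class;
    reproducible from the seed.  By default the quantile levels carry the
    small-sample expansion of Hesterberg (t-quantile widening of the
    percentile interval): the plain percentile interval undercovers at
    study-scale group sizes (~92% instead of 95% at n = 16 + 16), and the
    expanded interval restores near-nominal coverage without changing the
    resampling scheme.  ``expand=False`` gives the plain percentile interval.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both classes required for a bootstrap CI")
    if expand:
        n_eff = min(pos.size, neg.size)
        if n_eff > 1:
            tq = stats.t.ppf(1.0 - alpha / 2.0, n_eff - 1)
            alpha = 2.0 * stats.norm.cdf(-tq * np.sqrt(n_eff / (n_eff - 1.0)))
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    # vectorised in blocks: pairwise comparison tensors stay modest at study n
    block = max(1, int(5e6 // max(pos.size * neg.size, 1)))
    done = 0
    while done < n_boot:
        b = min(block, n_boot - done)
        pi = rng.integers(0, pos.size, size=(b, pos.size))
        ni = rng.integers(0, neg.size, size=(b, neg.size))
        p = pos[pi][:, :, None]
        n = neg[ni][:, None, :]
        gt = (p > n).sum(axis=(1, 2))
        eq = (p == n).sum(axis=(1, 2))
        aucs[done:done + b] = (gt + 0.5 * eq) / (pos.size * neg.size)
        done += b
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def spec_at_full_sens(roc: ROCResult) -> float:
    """Maximum specificity among operating points with sensitivity = 1.

    With positives oriented as higher scores this is the fraction of
    negatives strictly below the smallest positive score.
    """
    at_full = roc.tpr >= 1.0
    if not at_full.any():
        return 0.0
    return float(1.0 - np.min(roc.fpr[at_full]))


def eis_best_frequency(per_frequency_rocs: dict[float, ROCResult]
                       ) -> tuple[float, ROCResult]:
    """Frequency with maximal AUC; ties break toward the lowest frequency.

    The selected AUC is optimistically biased (max over ~100 correlated
    candidates); reports carry a ``selection_biased`` flag.
    """
    if not per_frequency_rocs:
        raise InvalidInputError("no frequencies evaluated")
    best_f = None
    best_auc = -np.inf
    for f in sorted(per_frequency_rocs):
        a = per_frequency_rocs[f].auc
        if a > best_auc:
            best_auc, best_f = a, f
    return best_f, per_frequency_rocs[best_f]


# ---------------------------------------------------------------------------
# full analyses


def _oriented(values: np.ndarray, metric: str) -> np.ndarray:
    return METRIC_SIGN.get(metric, 1) * np.asarray(values, dtype=float)


def _roc_with_ci(pos_vals, neg_vals, metric, n_boot, seed) -> ROCResult:
    scores = _oriented(np.concatenate([pos_vals, neg_vals]), metric)
    labels = np.concatenate([np.ones(len(pos_vals), dtype=int),
                             np.zeros(len(neg_vals), dtype=int)])
    roc = roc_auc(scores, labels)
    roc.ci_low, roc.ci_high = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return roc


def _metric_level_means(table: pd.DataFrame, metric: str, level: int,
                        frequency_hz: float | None = None) -> pd.Series:
    sel = (table["metric"] == metric) & (table["level"] == level)
    if frequency_hz is not None:
        sel &= np.isclose(table["frequency_hz"].astype(float), frequency_hz)
    return table[sel].set_index("subject")["mean"]


def _paired(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = a.index.intersection(b.index)
    return a[common].to_numpy(float), b[common].to_numpy(float)


def run_absolute_analysis(table: pd.DataFrame, n_boot: int = 500,
                          seed: int = 0) -> pd.DataFrame:
    """Absolute analysis: per metric x level, level values vs baseline values.

    Wilcoxon signed-rank p-values (same subjects) against baseline and
    against the previous level, plus ROC/AUC with bootstrap CI of level
    values against baseline values.  EIS metrics are evaluated per frequency
    and the max-AUC frequency is reported (flagged as selection-biased).
    """
    if 0 not in table["level"].unique():
        raise InvalidInputError("table must contain baseline (level 0) entries")
    rows = []
    metrics = sorted(table["metric"].unique())
    prev_of = {15: 0, 30: 15, 45: 30, 60: 45}
    for mi, metric in enumerate(metrics):
        is_eis = metric.startswith("EIS")
        freqs = (sorted(table.loc[table["metric"] == metric, "frequency_hz"]
                        .dropna().unique()) if is_eis else [None])
        for li, level in enumerate(lv for lv in ANALYSIS_LEVELS if lv != 0):
            cand: dict[float, dict] = {}
            for f in freqs:
                base = _metric_level_means(table, metric, 0, f)
                cur = _metric_level_means(table, metric, level, f)
                prev = _metric_level_means(table, metric, prev_of[level], f)
                b, c = _paired(base, cur)
                if b.size < 2:
                    continue
                roc = roc_auc(_oriented(np.concatenate([c, b]), metric),
                              np.concatenate([np.ones(c.size, int), np.zeros(b.size, int)]))
                cand[f if f is not None else 0.0] = {
                    "roc": roc, "base": b, "cur": c,
                    "prev_pair": _paired(prev, cur),
                }
            if not cand:
                continue
            if is_eis:
                best_f, _ = eis_best_frequency({f: d["roc"] for f, d in cand.items()})
                chosen_f, d = best_f, cand[best_f]
            else:
                chosen_f, d = None, cand[0.0]
            b, c = d["base"], d["cur"]
            pv, cv = d["prev_pair"]
            roc = d["roc"]
            roc.ci_low, roc.ci_high = bootstrap_auc_ci(
                _oriented(np.concatenate([c, b]), metric),
                np.concatenate([np.ones(c.size, int), np.zeros(b.size, int)]),
                n_boot=n_boot, seed=seed + 1000 * mi + li)
            rows.append({
                "metric": metric, "level": int(level),
                "frequency_hz": chosen_f,
                "p_vs_baseline": wilcoxon_compare(c, b, paired=True).p_value,
                "p_vs_prev": (wilcoxon_compare(cv, pv, paired=True).p_value
                              if pv.size >= 2 else np.nan),
                "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "n_pos": roc.n_pos, "n_neg": roc.n_neg,
                "selection_biased": bool(is_eis),
            })
    return pd.DataFrame(rows)


def baseline_variability_table(cohort: CohortMetrics, metric: str,
                               as_percent: bool,
                               frequency_index: int | None = None) -> pd.DataFrame:
    """Baseline-variability change samples, one per subject."""
    rows = []
    for sm in cohort.subjects:
        if metric.startswith("EIS"):
            site = metric.split("_", 1)[1]
            series = sm.eis[site].series_at(frequency_index)
        else:
            series = sm.series[metric]
        try:
            v = baseline_variability(series, sm.protocol, as_percent=as_percent)
        except InsufficientDataError as e:
            warnings.warn(str(e), stacklevel=2)
            continue
        rows.append({"subject": sm.subject_id, "metric": metric,
                     "kind": "baseline_variability", "from_level": 0, "to_level": 0,
                     "value": v,
                     "frequency_hz": series.frequency_hz})
    return pd.DataFrame(rows)


def run_relative_analysis(cohort: CohortMetrics, n_boot: int = 500, seed: int = 0,
                          percent_metrics: tuple[str, ...] = PERCENT_METRICS,
                          pairs: tuple[tuple[int, int], ...] = CONSECUTIVE_PAIRS,
                          ) -> pd.DataFrame:
    """Relative analysis: consecutive-level changes vs baseline variability.

    Per metric and consecutive pair: Wilcoxon rank-sum p, ROC/AUC with
    bootstrap CI, and the specificity at 100% sensitivity.  Impedance-metric
    changes are expressed in percent of the lower level; vital-sign changes
    in native units.  EIS metrics are screened per frequency by AUC and the
    best frequency reported (selection-biased, flagged).
    """
    table = cohort.level_table()
    rows = []
    scalar_metrics = [m for m in METRIC_SIGN if not m.startswith("EIS")
                      and m in set(table["metric"])]
    eis_metrics = [m for m in METRIC_SIGN if m.startswith("EIS")
                   and m in set(table["metric"])]

    for mi, metric in enumerate(scalar_metrics):
        as_pct = metric in percent_metrics
        basevar = baseline_variability_table(cohort, metric, as_pct)
        for pi, (lo, hi) in enumerate(pairs):
            ch = relative_change(table, metric, lo, hi, as_percent=as_pct)
            if len(ch) < 2 or len(basevar) < 2:
                continue
            roc = _roc_with_ci(ch["value"].to_numpy(), basevar["value"].to_numpy(),
                               metric, n_boot, seed + 100 * mi + pi)
            rows.append({
                "metric": metric, "from_level": lo, "to_level": hi,
                "as_percent": as_pct, "frequency_hz": None,
                "p_value": wilcoxon_compare(ch["value"], basevar["value"]).p_value,
                "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "spec_at_full_sens": spec_at_full_sens(roc),
                "n_pos": roc.n_pos, "n_neg": roc.n_neg, "selection_biased": False,
            })

    for mi, metric in enumerate(eis_metrics):
        site = metric.split("_", 1)[1]
        as_pct = metric in percent_metrics
        res = _eis_relative(cohort, site, as_pct, pairs, n_boot,
                            seed + 10_000 + 100 * mi)
        rows.extend(res)
    return pd.DataFrame(rows)


def _eis_relative(cohort: CohortMetrics, site: str, as_percent: bool,
                  pairs, n_boot: int, seed: int) -> list[dict]:
    """Vectorised per-frequency relative analysis for one EIS site."""
    metric = f"EIS_{site}"
    # per-subject per-level per-frequency stable means
    level_means: dict[str, dict[int, np.ndarray]] = {}
    basevar: dict[str, np.ndarray] = {}
    freqs = None
    for sm in cohort.subjects:
        if site not in sm.eis:
            warnings.warn(f"{metric}: subject {sm.subject_id} has no {site} "
                          "spectra; skipped", stacklevel=2)
            continue
        mags = sm.eis[site]
        freqs = mags.freqs
        per_level = {}
        for level in ANALYSIS_LEVELS:
            if level not in sm.protocol.levels:
                continue
            lo_t, hi_t = sm.protocol.stable_window(level, cohort.transition_skip)
            sel = (mags.times >= lo_t) & (mags.times <= hi_t)
            if sel.any():
                per_level[level] = mags.mag[sel].mean(axis=0)
        level_means[sm.subject_id] = per_level
        step = sm.protocol.step_for_level(0)
        mid = 0.5 * (step.start_time + step.end_time)
        h1 = (mags.times >= step.start_time) & (mags.times < mid)
        h2 = (mags.times >= mid) & (mags.times < step.end_time)
        if h1.any() and h2.any():
            m1 = mags.mag[h1].mean(axis=0)
            m2 = mags.mag[h2].mean(axis=0)
            basevar[sm.subject_id] = (100.0 * (m2 - m1) / m1) if as_percent else m2 - m1

    neg = np.vstack([basevar[s] for s in sorted(basevar)])  # (n_subj, n_freq)
    out = []
    for pi, (lo, hi) in enumerate(pairs):
        pos_rows = []
        for s in sorted(level_means):
            pl = level_means[s]
            if lo in pl and hi in pl:
                d = pl[hi] - pl[lo]
                pos_rows.append(100.0 * d / pl[lo] if as_percent else d)
        if len(pos_rows) < 2:
            continue
        pos = np.vstack(pos_rows)
        aucs = np.array([_auc_only(pos[:, j], neg[:, j]) for j in range(pos.shape[1])])
        best_j = int(np.argmax(aucs))  # argmax takes the first (lowest) frequency on ties
        roc = _roc_with_ci(pos[:, best_j], neg[:, best_j], metric, n_boot, seed + pi)
        out.append({
            "metric": metric, "from_level": lo, "to_level": hi,
            "as_percent": as_percent, "frequency_hz": float(freqs[best_j]),
            "p_value": wilcoxon_compare(pos[:, best_j], neg[:, best_j]).p_value,
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "spec_at_full_sens": spec_at_full_sens(roc),
            "n_pos": roc.n_pos, "n_neg": roc.n_neg, "selection_biased": True,
        })
    return out
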