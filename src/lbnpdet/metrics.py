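"""Reduction of raw channels to per-level diagnostic metrics.

Nine named metrics are consumed downstream: MAP, HR, Pleth_A (trough-to-
trough pulse area), mean belt impedance from EIT on thorax and abdomen
(EIT_thx, EIT_ab), and EIS impedance magnitude at three sites (EIS_thx,
EIS_ab, EIS_arm; one candidate metric per frequency, with frequency
selection deferred to the diagnostic analysis).  Each metric is reduced to
one value per subject per LBNP level by averaging over the stable period of
the step (the part after the pressure transition), and to minute-level
series for the time-series-classification stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InvalidInputError
from .protocol import ANALYSIS_LEVELS, ProtocolTimeline
from .synth import EIS_FREQS, EITFrames, EISSpectra, SubjectRecording

#: scalar (non-spectral) metric names
SCALAR_METRICS = ("MAP", "HR", "PlethA", "EIT_thx", "EIT_ab")
EIS_METRICS = ("EIS_thx", "EIS_ab", "EIS_arm")
ALL_METRICS = SCALAR_METRICS + EIS_METRICS


@dataclass
class MetricSeries:
    """A timestamped scalar metric series (one frequency for EIS metrics)."""

    metric_name: str
    times: np.ndarray
    values: np.ndarray
    frequency_hz: float | None = None
    sd: np.ndarray | None = None  # per-sample spread where defined (EIT frames)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must have identical shape")
        if np.any(np.diff(self.times) < 0):
            raise InvalidInputError("series times must be non-decreasing")


@dataclass
class EISMagnitudes:
    """|Z| over the canonical frequency grid at one site, one row per spectrum."""

    site: str
    times: np.ndarray          # (n,)
    freqs: np.ndarray          # (100,)
    mag: np.ndarray            # (n, 100) Ohm

    def series_at(self, freq_index: int) -> MetricSeries:
        return MetricSeries(
            metric_name=f"EIS_{self.site}",
            times=self.times,
            values=self.mag[:, freq_index],
            frequency_hz=float(self.freqs[freq_index]),
        )


# ---------------------------------------------------------------------------
# vital-sign metrics


def hr_from_rpeaks(rpeak_times: np.ndarray) -> MetricSeries:
    """Beat-to-beat heart rate from R-peak times.

    HR_i = 60 / (t_{i+1} - t_i) bpm, timestamped at the interval midpoint.
    """
    t = np.asarray(rpeak_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 R-peaks for heart rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidInputError("R-peak times must be strictly increasing")
    return MetricSeries(metric_name="HR", times=t[:-1] + dt / 2.0, values=60.0 / dt)


def pleth_area(pleth_waveform: tuple[np.ndarray, np.ndarray],
               smooth_s: float = 0.25, refractory_s: float = 0.3,
               median_window_s: float = 2.0) -> MetricSeries:
    """Trough-to-trough area under the pleth waveform, one value per beat.

    Troughs are local minima of a lightly smoothed waveform lying below a
    rolling-median threshold; per beat the trapezoidal integral of the
    signal minus the straight line joining the bounding trough values is
    taken over the trough-to-trough interval (baseline removal makes the
    metric robust to DC drift).  Values are timestamped at interval midpoints.
    """
    times, values = (np.asarray(a, dtype=float) for a in pleth_waveform)
    if times.size < 3:
        raise InsufficientDataError("waveform too short for trough detection")
    fs = 1.0 / np.median(np.diff(times))
    k = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(k) / k
    smoothed = np.convolve(values, kernel, mode="same")
    mw = max(int(round(median_window_s * fs)), 3)
    rolling_median = (
        pd.Series(smoothed).rolling(mw, center=True, min_periods=1).median().to_numpy()
    )
    candidates, _ = find_peaks(-smoothed, distance=max(int(refractory_s * fs), 1))
    troughs = candidates[smoothed[candidates] <= rolling_median[candidates]]
    if troughs.size < 2:
        raise InsufficientDataError("fewer than 2 troughs found in pleth waveform")
    areas = np.empty(troughs.size - 1)
    mids = np.empty(troughs.size - 1)
    for i, (a, b) in enumerate(zip(troughs[:-1], troughs[1:])):
        seg_t = times[a:b + 1]
        seg_v = values[a:b + 1]
        baseline = np.interp(seg_t, [seg_t[0], seg_t[-1]], [values[a], values[b]])
        areas[i] = np.trapezoid(seg_v - baseline, seg_t)
        mids[i] = 0.5 * (seg_t[0] + seg_t[-1])
    return MetricSeries(metric_name="PlethA", times=mids, values=areas)


# ---------------------------------------------------------------------------
# impedance metrics


@dataclass(frozen=True)
class ValidityRules:
    """Channel validity checks applied before belt averaging."""

    enabled: bool = True
    use_contact_flags: bool = True
    mad_multiplier: float = 5.0
    saturation_ohm: float = 1e4


@dataclass
class ValidityReport:
    """Excluded (channel, frame) pairs with a reason code per exclusion."""

    exclusions: pd.DataFrame  # columns: channel, frame, reason
    n_frames: int = 0
    n_channels: int = 0

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def eit_mean_impedance(frames: EITFrames, rules: ValidityRules | None = None,
                       metric_name: str = "EIT") -> tuple[MetricSeries, ValidityReport]:
    """Per-frame mean +/- SD of valid channel magnitudes of one EIT belt.

    Channels failing the contact flag are excluded wholesale ("contact");
    per frame, channels beyond ``mad_multiplier`` times the median absolute
    deviation from the cross-channel median are excluded ("outlier"), and
    values above the saturation limit are excluded ("saturation").  Frames
    with no valid channel left become NaN (missing).
    """
    rules = rules or ValidityRules()
    vals = np.abs(np.asarray(frames.values, dtype=float))
    n_frames, n_ch = vals.shape
    mask = np.ones_like(vals, dtype=bool)
    rows: list[tuple[int, int, str]] = []

    if rules.enabled:
        if rules.use_contact_flags:
            bad = ~np.asarray(frames.channel_valid, dtype=bool)
            for ch in np.nonzero(bad)[0]:
                mask[:, ch] = False
                rows.append((int(ch), -1, "contact"))  # frame -1: whole channel
        sat = mask & (vals > rules.saturation_ohm)
        for fr, ch in zip(*np.nonzero(sat)):
            mask[fr, ch] = False
            rows.append((int(ch), int(fr), "saturation"))
        # robust cross-channel outlier rule, frame by frame
        work = np.where(mask, vals, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
            med = np.nanmedian(work, axis=1, keepdims=True)
            mad = np.nanmedian(np.abs(work - med), axis=1, keepdims=True)
        dev = np.abs(work - med)
        out = mask & np.where(mad > 0, dev > rules.mad_multiplier * mad, dev > 0)
        for fr, ch in zip(*np.nonzero(out)):
            mask[fr, ch] = False
            rows.append((int(ch), int(fr), "outlier"))

    work = np.where(mask, vals, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames -> NaN
        mean = np.nanmean(work, axis=1)
        sd = np.nanstd(work, axis=1, ddof=0)
    report = ValidityReport(
        exclusions=pd.DataFrame(rows, columns=["channel", "frame", "reason"]),
        n_frames=n_frames, n_channels=n_ch,
    )
    return MetricSeries(metric_name=metric_name, times=frames.times,
                        values=mean, sd=sd), report


def eis_magnitude(spectra: EISSpectra, site: str | None = None) -> EISMagnitudes:
    """|Z| per frequency per spectrum time; no frequency selection here."""
    freqs = np.asarray(spectra.freqs, dtype=float)
    if freqs.shape != EIS_FREQS.shape:
        raise InvalidInputError(
            f"EIS spectra at site {site!r} have {freqs.size} frequencies; the "
            f"canonical grid has {EIS_FREQS.size}")
    if not np.allclose(freqs, EIS_FREQS, rtol=1e-6):
        bad = freqs[~np.isclose(freqs, EIS_FREQS, rtol=1e-6)]
        raise InvalidInputError(
            f"EIS spectra at site {site!r} are off the canonical log grid "
            f"(offending frequencies: {bad[:3]} Hz)")
    return EISMagnitudes(site=site or "", times=np.asarray(spectra.times, dtype=float),
                         freqs=freqs, mag=np.abs(np.asarray(spectra.z)))


# ---------------------------------------------------------------------------
# stable-period averaging and minute-level reduction


def stable_period_average(series: MetricSeries, protocol: ProtocolTimeline,
                          transition_skip: float | None = None,
                          levels=ANALYSIS_LEVELS,
                          min_valid_fraction: float = 0.5) -> list[dict]:
    """Mean and SD of a metric during each retained level's stable period.

    Samples with timestamps in ``[step_start + transition_skip, step_end]``
    contribute; NaN samples are dropped.  A level whose stable window is
    empty, or where more than half of the in-window samples are missing,
    yields no entry (a warning is emitted rather than a silent zero).
    """
    rows = []
    for level in levels:
        if level not in protocol.levels:
            continue
        lo, hi = protocol.stable_window(level, transition_skip)
        sel = (series.times >= lo) & (series.times <= hi)
        vals = series.values[sel]
        ok = np.isfinite(vals)
        if vals.size == 0 or ok.sum() == 0 or ok.mean() < min_valid_fraction:
            warnings.warn(
                f"metric {series.metric_name}: level {level} mmHg stable window has "
                f"{ok.sum() if vals.size else 0}/{vals.size} valid samples; entry skipped",
                stacklevel=2)
            continue
        rows.append({
            "metric": series.metric_name,
            "level": int(level),
            "mean": float(np.mean(vals[ok])),
            "sd": float(np.std(vals[ok], ddof=0)),
            "n": int(ok.sum()),
            "frequency_hz": series.frequency_hz,
        })
    return rows


def minute_average(series: MetricSeries, t_end: float) -> MetricSeries:
    """Minute-level means on the grid [60k, 60(k+1)); empty minutes are NaN."""
    n_min = int(np.floor(t_end / 60.0))
    idx = np.floor(series.times / 60.0).astype(int)
    vals = np.full(n_min, np.nan)
    for k in range(n_min):
        sel = (idx == k) & np.isfinite(series.values)
        if sel.any():
            vals[k] = np.mean(series.values[sel])
    return MetricSeries(metric_name=series.metric_name,
                        times=60.0 * np.arange(n_min) + 30.0,
                        values=vals, frequency_hz=series.frequency_hz)


# ---------------------------------------------------------------------------
# per-subject and cohort extraction


@dataclass
class SubjectMetrics:
    """All reduced metrics for one subject."""

    subject_id: str
    protocol: ProtocolTimeline
    series: dict[str, MetricSeries]            # scalar metrics
    eis: dict[str, EISMagnitudes]              # per-site spectral magnitudes
    hrv: pd.DataFrame                          # minute-level HRV features
    validity: dict[str, ValidityReport] = field(default_factory=dict)


@dataclass
class CohortMetrics:
    subjects: list[SubjectMetrics]
    transition_skip: float | None = None

    def level_table(self, as_percent_unused=None) -> pd.DataFrame:
        """Tidy subject x metric x level table (EIS rows carry a frequency)."""
        rows = []
        for sm in self.subjects:
            for name, series in sm.series.items():
                for r in stable_period_average(series, sm.protocol, self.transition_skip):
                    rows.append({"subject": sm.subject_id, **r})
            for site, mags in sm.eis.items():
                rows.extend(_eis_level_rows(sm.subject_id, mags, sm.protocol,
                                            self.transition_skip))
        return pd.DataFrame(rows)


def _eis_level_rows(subject_id: str, mags: EISMagnitudes, protocol: ProtocolTimeline,
                    transition_skip: float | None) -> list[dict]:
    rows = []
    for level in ANALYSIS_LEVELS:
        if level not in protocol.levels:
            continue
        lo, hi = protocol.stable_window(level, transition_skip)
        sel = (mags.times >= lo) & (mags.times <= hi)
        if not sel.any():
            warnings.warn(f"EIS_{mags.site}: no spectra in stable window of "
                          f"{level} mmHg for {subject_id}", stacklevel=2)
            continue
        m = mags.mag[sel]
        means = m.mean(axis=0)
        sds = m.std(axis=0, ddof=0)
        for j, f in enumerate(mags.freqs):
            rows.append({"subject": subject_id, "metric": f"EIS_{mags.site}",
                         "level": int(level), "mean": float(means[j]),
                         "sd": float(sds[j]), "n": int(sel.sum()),
                         "frequency_hz": float(f)})
    return rows


def extract_subject(rec: SubjectRecording, transition_skip: float | None = None,
                    eit_rules: ValidityRules | None = None,
                    compute_hrv: bool = True) -> SubjectMetrics:
    """Reduce one recording to its metric series (HRV included by default)."""
    from .hrv import hrv_features  # local import to keep module load light

    series: dict[str, MetricSeries] = {}
    validity: dict[str, ValidityReport] = {}

    t_map, v_map = rec.map_series
    series["MAP"] = MetricSeries(metric_name="MAP", times=np.asarray(t_map),
                                 values=np.asarray(v_map))
    series["HR"] = hr_from_rpeaks(rec.rpeak_times)
    series["PlethA"] = pleth_area(rec.pleth_waveform)
    for site, frames in rec.eit_frames.items():
        s, rep = eit_mean_impedance(frames, eit_rules, metric_name=f"EIT_{site}")
        series[f"EIT_{site}"] = s
        validity[f"EIT_{site}"] = rep
    eis = {site: eis_magnitude(spectra, site=site)
           for site, spectra in rec.eis_spectra.items()}
    hrv = (hrv_features(rec.rpeak_times) if compute_hrv
           else pd.DataFrame())
    return SubjectMetrics(subject_id=rec.subject_id, protocol=rec.protocol,
                          series=series, eis=eis, hrv=hrv, validity=validity)


def extract_cohort(recordings: list[SubjectRecording],
                   transition_skip: float | None = None,
                   eit_rules: ValidityRules | None = None,
                   compute_hrv: bool = True) -> CohortMetrics:
    subjects = [extract_subject(r, transition_skip, eit_rules, compute_hrv)
                for r in recordings]
    return CohortMetrics(subjects=subjects, transition_skip=transition_skip)
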