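"""Minute-level heart-rate-variability features.

Twenty features per 60 s window, spanning the three conventional domains:

time domain (8)
    mean_rr_ms, sdnn_ms, rmssd_ms, pnn50_pct, pnn20_pct, mean_hr_bpm,
    sd_hr_bpm, cv_rr_pct
frequency domain (7, Welch periodogram of the 4 Hz-resampled RR series)
    vlf_power_ms2 (0.0033-0.04 Hz), lf_power_ms2 (0.04-0.15 Hz),
    hf_power_ms2 (0.15-0.4 Hz), total_power_ms2, lf_hf_ratio, lf_norm, hf_norm
nonlinear (5)
    sd1_ms, sd2_ms (Poincare), sd1_sd2, sampen (m=2, r=0.2*SDNN),
    dfa_alpha1 (detrended fluctuation, box sizes 4-16)

Windows with fewer than 2 RR intervals produce a NaN row (missing, never
zero).  The exact feature inventory of any given study is a configuration
detail; this set is a conventional default and callers may subset or extend
it via the ``features`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import welch

from .errors import InsufficientDataError

HRV_FEATURES: tuple[str, ...] = (
    "mean_rr_ms", "sdnn_ms", "rmssd_ms", "pnn50_pct", "pnn20_pct",
    "mean_hr_bpm", "sd_hr_bpm", "cv_rr_pct",
    "vlf_power_ms2", "lf_power_ms2", "hf_power_ms2", "total_power_ms2",
    "lf_hf_ratio", "lf_norm", "hf_norm",
    "sd1_ms", "sd2_ms", "sd1_sd2", "sampen", "dfa_alpha1",
)

_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


def _time_domain(rr_ms: np.ndarray) -> dict[str, float]:
    d = np.diff(rr_ms)
    hr = 60000.0 / rr_ms
    mean_rr = float(np.mean(rr_ms))
    sdnn = float(np.std(rr_ms, ddof=1)) if rr_ms.size > 1 else np.nan
    return {
        "mean_rr_ms": mean_rr,
        "sdnn_ms": sdnn,
        "rmssd_ms": float(np.sqrt(np.mean(d ** 2))) if d.size else np.nan,
        "pnn50_pct": float(100.0 * np.mean(np.abs(d) > 50.0)) if d.size else np.nan,
        "pnn20_pct": float(100.0 * np.mean(np.abs(d) > 20.0)) if d.size else np.nan,
        "mean_hr_bpm": float(np.mean(hr)),
        "sd_hr_bpm": float(np.std(hr, ddof=1)) if hr.size > 1 else np.nan,
        "cv_rr_pct": float(100.0 * sdnn / mean_rr) if mean_rr > 0 else np.nan,
    }


def _frequency_domain(t_ms: np.ndarray, rr_ms: np.ndarray, fs: float = 4.0
                      ) -> dict[str, float]:
    out = {k: np.nan for k in ("vlf_power_ms2", "lf_power_ms2", "hf_power_ms2",
                               "total_power_ms2", "lf_hf_ratio", "lf_norm", "hf_norm")}
    if rr_ms.size < 4 or t_ms[-1] <= t_ms[0]:
        return out
    grid = np.arange(t_ms[0], t_ms[-1], 1000.0 / fs)
    rr_i = np.interp(grid, t_ms, rr_ms)
    rr_i = rr_i - np.mean(rr_i)
    nper = min(rr_i.size, 256)
    f, pxx = welch(rr_i, fs=fs, nperseg=nper)
    powers = {}
    for band, (lo, hi) in _BANDS.items():
        sel = (f >= lo) & (f < hi)
        powers[band] = float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() > 1 else 0.0
    total = sum(powers.values())
    lf, hf = powers["lf"], powers["hf"]
    out.update({
        "vlf_power_ms2": powers["vlf"], "lf_power_ms2": lf, "hf_power_ms2": hf,
        "total_power_ms2": total,
        "lf_hf_ratio": lf / hf if hf > 0 else np.nan,
        "lf_norm": 100.0 * lf / (lf + hf) if (lf + hf) > 0 else np.nan,
        "hf_norm": 100.0 * hf / (lf + hf) if (lf + hf) > 0 else np.nan,
    })
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy with tolerance r = r_frac * SD; 0 for a constant series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        return np.nan
    sd = np.std(x, ddof=0)
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def count_matches(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distance between all template pairs, self-matches excluded
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        iu = np.triu_indices(templ.shape[0], k=1)
        return int(np.sum(d[iu] <= r))

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def dfa_alpha1(rr_ms: np.ndarray, min_box: int = 4, max_box: int = 16) -> float:
    """Short-term detrended fluctuation exponent of the RR series."""
    x = np.asarray(rr_ms, dtype=float)
    if x.size < max_box:
        return np.nan
    y = np.cumsum(x - np.mean(x))
    sizes = np.arange(min_box, min(max_box, x.size // 2) + 1)
    flucts = []
    for n in sizes:
        n_boxes = y.size // n
        if n_boxes < 2:
            continue
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box linear detrend
        tm = t - t.mean()
        denom = np.sum(tm ** 2)
        slopes = seg @ tm / denom
        trends = seg.mean(axis=1, keepdims=True) + slopes[:, None] * tm[None, :]
        flucts.append(np.sqrt(np.mean((seg - trends) ** 2)))
    flucts = np.asarray(flucts)
    ok = flucts > 0
    if ok.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(np.log(sizes[: flucts.size][ok]), np.log(flucts[ok]), 1)
    return float(slope)


def _nonlinear(rr_ms: np.ndarray) -> dict[str, float]:
    d = np.diff(rr_ms)
    out = {"sd1_ms": np.nan, "sd2_ms": np.nan, "sd1_sd2": np.nan,
           "sampen": np.nan, "dfa_alpha1": np.nan}
    if d.size >= 2:
        sd1 = float(np.std(d, ddof=1) / np.sqrt(2.0))
        var_rr = np.var(rr_ms, ddof=1)
        sd2_sq = max(2.0 * var_rr - sd1 ** 2, 0.0)
        sd2 = float(np.sqrt(sd2_sq))
        out["sd1_ms"] = sd1
        out["sd2_ms"] = sd2
        out["sd1_sd2"] = sd1 / sd2 if sd2 > 0 else (0.0 if sd1 == 0 else np.nan)
    out["sampen"] = sample_entropy(rr_ms)
    out["dfa_alpha1"] = dfa_alpha1(rr_ms)
    return out


def hrv_window_features(rpeak_times: np.ndarray) -> dict[str, float]:
    """All 20 features on one window of R-peak times (seconds)."""
    t = np.asarray(rpeak_times, dtype=float)
    if t.size < 3:  # < 2 intervals
        return {k: np.nan for k in HRV_FEATURES}
    rr_ms = np.diff(t) * 1000.0
    t_ms = t[1:] * 1000.0  # each interval timestamped at its end
    feats = {}
    feats.update(_time_domain(rr_ms))
    feats.update(_frequency_domain(t_ms, rr_ms))
    feats.update(_nonlinear(rr_ms))
    return {k: feats[k] for k in HRV_FEATURES}


def hrv_features(rpeak_times: np.ndarray, window_s: float = 60.0,
                 features: tuple[str, ...] = HRV_FEATURES) -> pd.DataFrame:
    """Per-window HRV feature table over consecutive ``window_s`` windows.

    Returns a DataFrame indexed by window-centre time (s) with one column
    per feature; windows with fewer than 2 RR intervals are NaN rows.
    """
    t = np.asarray(rpeak_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 R-peaks for HRV features")
    unknown = set(features) - set(HRV_FEATURES)
    if unknown:
        raise ValueError(f"unknown HRV features requested: {sorted(unknown)}")
    t_end = t[-1]
    n_win = int(np.floor(t_end / window_s))
    rows = []
    centers = []
    for k in range(n_win):
        lo, hi = k * window_s, (k + 1) * window_s
        w = t[(t >= lo) & (t < hi)]
        rows.append(hrv_window_features(w))
        centers.append(lo + window_s / 2.0)
    df = pd.DataFrame(rows, index=pd.Index(centers, name="time_s"))
    return df[list(features)]
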