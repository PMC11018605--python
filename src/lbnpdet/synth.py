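"""Synthetic multi-modal LBNP cohort generator.

Generates per-subject recordings with the statistical structure the
downstream analyses assume, so the whole pipeline is testable without any
access to real recordings.  Channels produced:

* ``rpeak_times`` — ECG surrogate: R-peak event times whose instantaneous
  rate follows the level-dependent HR effect plus slow wander and beat-to-beat
  jitter.  No waveform morphology is synthesised.
* ``map_series`` — 1 Hz mean arterial pressure with level offsets, slow
  wander and measurement noise.
* ``pleth_waveform`` — a raised-cosine pulse train locked to the R-peaks,
  amplitude-modulated by the level-dependent Pleth attenuation; only the
  trough-to-trough pulse area is consumed downstream.
* ``eit_frames`` — per belt (thorax, abdomen): 1 Hz frames of 208 transfer
  impedance channels (adjacent drive / adjacent measure geometry of a
  16-electrode belt) with per-channel gains, a common-mode cumulative
  per-step percent increase, cardiac (~1 Hz) and respiratory (~0.25 Hz)
  oscillations, slow common-mode drift, and per-channel white noise.
* ``eis_spectra`` — per site (thorax, abdomen, arm): one complex Cole-model
  spectrum per minute on the canonical 100-point log grid (100 Hz – 1 MHz),
  with the relative effect concentrated in a mid-frequency band.
* ``lbnp_series`` — 1 Hz suction magnitude following the step protocol with
  linear ramps over the transition window.

Effects enter multiplicatively for impedance channels: the per-subject
percent increase of step *k* is drawn as ``floor_k + (median_k - floor_k) *
exp(sigma * z)`` with standard-normal ``z``, a shifted lognormal whose
cohort median equals ``median_k`` and whose support respects the floor.
A per-subject lognormal scale multiplies all absolute impedances to emulate
body-habitus variation.  All randomness flows from a single integer seed;
identical ``(config, seed)`` give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EffectConfig
from .errors import InvalidConfigError
from .protocol import (
    LBNP_LEVELS,
    STOP_LEVELS,
    ProtocolTimeline,
    generate_protocol,
)

EIS_FREQS: np.ndarray = np.logspace(2.0, 6.0, 100)  # Hz, canonical grid
EIT_SITES = ("thx", "ab")
EIS_SITES = ("thx", "ab", "arm")
#: adjacent drive / adjacent measure on a 16-electrode belt: 16 injection
#: pairs x 13 non-injecting measurement pairs
EIT_N_CHANNELS = 16 * 13

EIT_BASE_OHM = {"thx": 30.0, "ab": 40.0}
COLE_PARAMS = {  # (R0, Rinf, fc_Hz, alpha) per EIS site
    "thx": (60.0, 20.0, 50e3, 0.85),
    "ab": (80.0, 30.0, 50e3, 0.85),
    "arm": (120.0, 40.0, 60e3, 0.85),
}

MAP_FS = 1.0       # Hz
EIT_FRAME_FS = 1.0  # Hz
PLETH_FS = 40.0    # Hz
EIS_PERIOD_S = 60.0


@dataclass
class EITFrames:
    times: np.ndarray            # (n_frames,) s
    values: np.ndarray           # (n_frames, n_channels) Ohm, magnitudes
    channel_valid: np.ndarray    # (n_channels,) bool


@dataclass
class EISSpectra:
    times: np.ndarray    # (n_spectra,) s
    freqs: np.ndarray    # (100,) Hz
    z: np.ndarray        # (n_spectra, 100) complex Ohm


@dataclass
class SubjectRecording:
    subject_id: str
    protocol: ProtocolTimeline
    rpeak_times: np.ndarray                  # (n_beats,) s, strictly increasing
    map_series: tuple[np.ndarray, np.ndarray]     # (times s, mmHg)
    pleth_waveform: tuple[np.ndarray, np.ndarray]  # (times s, a.u.)
    eit_frames: dict[str, EITFrames]
    eis_spectra: dict[str, EISSpectra]
    lbnp_series: tuple[np.ndarray, np.ndarray]    # (times s, mmHg)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level building blocks


def _ou_process(rng: np.random.Generator, n: int, dt: float, sd: float,
                tau: float = 300.0) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path: slow physiological wander."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    x[0] = sd * rng.standard_normal()
    shocks = b * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + shocks[i - 1]
    return x


def _ramp_knots(protocol: ProtocolTimeline, values_by_level: dict[int, float]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear knots: hold each level's value, ramp over transitions."""
    trans = protocol.transition_duration
    t: list[float] = []
    v: list[float] = []
    prev = float(values_by_level.get(0, 0.0))
    t += [0.0]
    v += [prev]
    for s in protocol.steps[1:]:
        cur = float(values_by_level.get(s.level, prev))
        t += [s.start_time, s.start_time + trans, s.end_time]
        v += [prev, cur, cur]
        prev = cur
    t.append(protocol.total_duration)
    v.append(prev)
    tt = np.asarray(t)
    vv = np.asarray(v)
    keep = np.concatenate(([True], np.diff(tt) > 0))
    return tt[keep], vv[keep]


def _effect_at(times: np.ndarray, protocol: ProtocolTimeline,
               values_by_level: dict[int, float]) -> np.ndarray:
    t, v = _ramp_knots(protocol, values_by_level)
    return np.interp(times, t, v)


def draw_step_percents(config: EffectConfig, rng: np.random.Generator,
                       n_changes: int, scale: float = 1.0) -> np.ndarray:
    """Per-step impedance percent increases for one subject (shifted lognormal)."""
    z = rng.standard_normal(n_changes)
    pct = np.empty(n_changes)
    for k in range(n_changes):
        med = config.step_median_pct(k) * scale
        flo = config.step_floor_pct(k) * scale
        pct[k] = flo + (med - flo) * np.exp(config.effect_sigma * z[k])
    return pct


def _impedance_multiplier(times: np.ndarray, protocol: ProtocolTimeline,
                          step_pcts: np.ndarray) -> np.ndarray:
    """Cumulative multiplicative effect, ramped linearly over transitions."""
    mult = np.cumprod(1.0 + np.asarray(step_pcts) / 100.0)
    by_level = {0: 1.0}
    for s, m in zip(protocol.steps[1:], mult):
        by_level[s.level] = float(m)
    return _effect_at(times, protocol, by_level)


def eis_band_weight(freqs: np.ndarray, band: tuple[float, float],
                    weight_floor: float = 0.15) -> np.ndarray:
    """Log-frequency Gaussian weight, ~1 inside the band, >= weight_floor everywhere."""
    f_lo, f_hi = band
    center = np.sqrt(f_lo * f_hi)
    half_width = 0.5 * np.log10(f_hi / f_lo)
    sigma = half_width / np.sqrt(2.0 * np.log(2.0))  # half weight at band edges
    w = np.exp(-0.5 * ((np.log10(freqs) - np.log10(center)) / sigma) ** 2)
    return weight_floor + (1.0 - weight_floor) * w


def _cole_spectrum(site: str, freqs: np.ndarray) -> np.ndarray:
    r0, rinf, fc, alpha = COLE_PARAMS[site]
    jw = (1j * freqs / fc) ** alpha
    return rinf + (r0 - rinf) / (1.0 + jw)


# ---------------------------------------------------------------------------
# channel synthesis


def _synth_rpeaks(rng, protocol, config, hr0: float) -> np.ndarray:
    T = protocol.total_duration
    grid = np.arange(0.0, T + 1.0, 1.0)
    hr_eff = _effect_at(grid, protocol, dict(config.hr_effect_by_level))
    hr_slow = _ou_process(rng, grid.size, 1.0, config.noise("hr_slow_bpm"))
    rr_frac = config.noise("rr_frac")
    beats = [0.0]
    t = 0.0
    # jitter draws are consumed one per beat; pre-drawing a generous block
    # keeps the rng stream stable regardless of the realised beat count
    jitter = rng.standard_normal(int(T * 4) + 16)
    i = 0
    while True:
        hr = hr0 + np.interp(t, grid, hr_eff) + np.interp(t, grid, hr_slow)
        hr = max(hr, 30.0)
        rr = 60.0 / hr * (1.0 + rr_frac * jitter[min(i, jitter.size - 1)])
        rr = max(rr, 0.25)
        t += rr
        if t > T:
            break
        beats.append(t)
        i += 1
    return np.asarray(beats)


def _synth_map(rng, protocol, config, map0: float):
    T = protocol.total_duration
    times = np.arange(0.0, T, 1.0 / MAP_FS)
    eff = _effect_at(times, protocol, dict(config.map_effect_by_level))
    slow = _ou_process(rng, times.size, 1.0 / MAP_FS, config.noise("map_slow_mmhg"))
    fast = config.noise("map_fast_mmhg") * rng.standard_normal(times.size)
    return times, map0 + eff + slow + fast


def _synth_pleth(rng, protocol, config, rpeaks: np.ndarray, amp0: float = 1.0):
    T = protocol.total_duration
    times = np.arange(0.0, T, 1.0 / PLETH_FS)
    signal = np.zeros_like(times)
    eff = _effect_at(rpeaks, protocol, dict(config.pleth_a_effect_by_level))
    slow_grid = np.arange(0.0, T + 1.0, 1.0)
    slow = _ou_process(rng, slow_grid.size, 1.0, config.noise("pleth_slow_frac"))
    beat_jit = config.noise("pleth_beat_frac") * rng.standard_normal(rpeaks.size)
    onsets = rpeaks + 0.15
    widths = np.empty_like(rpeaks)
    widths[:-1] = 0.45 * np.diff(rpeaks)
    widths[-1] = widths[-2] if rpeaks.size > 1 else 0.4
    for k in range(rpeaks.size):
        a = amp0 * (1.0 + eff[k]) * (1.0 + np.interp(rpeaks[k], slow_grid, slow)) \
            * (1.0 + beat_jit[k])
        a = max(a, 0.05 * amp0)
        t0, w = onsets[k], max(widths[k], 0.1)
        i0 = int(np.ceil(t0 * PLETH_FS))
        i1 = min(int(np.floor((t0 + w) * PLETH_FS)), times.size - 1)
        if i1 <= i0:
            continue
        tt = times[i0:i1 + 1]
        signal[i0:i1 + 1] += 0.5 * a * (1.0 - np.cos(2.0 * np.pi * (tt - t0) / w))
    return times, signal


def _synth_eit(rng, protocol, config, site: str, subject_scale: float,
               step_pcts_thx: np.ndarray) -> EITFrames:
    T = protocol.total_duration
    times = np.arange(0.0, T, 1.0 / EIT_FRAME_FS)
    scale = 1.0 if site == "thx" else config.eit_ab_scale
    pcts = step_pcts_thx * scale
    mult = _impedance_multiplier(times, protocol, pcts)
    slow = _ou_process(rng, times.size, 1.0 / EIT_FRAME_FS, config.noise("eit_slow_frac"))
    card = config.noise("eit_cardiac_frac") * np.sin(2.0 * np.pi * 1.1 * times
                                                     + rng.uniform(0, 2 * np.pi))
    resp = config.noise("eit_resp_frac") * np.sin(2.0 * np.pi * 0.25 * times
                                                  + rng.uniform(0, 2 * np.pi))
    common = mult * (1.0 + slow + card + resp)
    gains = EIT_BASE_OHM[site] * np.exp(0.5 * rng.standard_normal(EIT_N_CHANNELS))
    white = config.noise("eit_channel_frac") * rng.standard_normal(
        (times.size, EIT_N_CHANNELS))
    values = subject_scale * gains[None, :] * common[:, None] * (1.0 + white)
    return EITFrames(times=times, values=values,
                     channel_valid=np.ones(EIT_N_CHANNELS, dtype=bool))


def _synth_eis(rng, protocol, config, site: str, subject_scale: float) -> EISSpectra:
    T = protocol.total_duration
    times = np.arange(EIS_PERIOD_S / 2.0, T, EIS_PERIOD_S)
    base = _cole_spectrum(site, EIS_FREQS) * subject_scale
    pcts = draw_step_percents(config, rng, len(protocol.steps) - 1,
                              scale=float(config.eis_site_scale[site]))
    mult = _impedance_multiplier(times, protocol, pcts)
    w = eis_band_weight(EIS_FREQS, config.eis_effect_band)
    effect = 1.0 + (mult[:, None] - 1.0) * w[None, :]
    slow = _ou_process(rng, times.size, EIS_PERIOD_S, config.noise("eis_slow_frac"))
    white = config.noise("eis_point_frac") * rng.standard_normal((times.size, EIS_FREQS.size))
    z = base[None, :] * effect * (1.0 + slow[:, None]) * (1.0 + white)
    return EISSpectra(times=times, freqs=EIS_FREQS.copy(), z=z)


def _synth_lbnp(protocol: ProtocolTimeline):
    T = protocol.total_duration
    times = np.arange(0.0, T, 1.0)
    levels = _effect_at(times, protocol, {s.level: float(s.level) for s in protocol.steps})
    return times, levels


# ---------------------------------------------------------------------------
# public API


def synth_subject(config: EffectConfig, subject_id: str, seed: int,
                  tolerance: int | None = None) -> SubjectRecording:
    """Generate one subject's full multi-modal recording.

    ``tolerance`` (stop level, mmHg) is sampled uniformly from the stop
    levels inside ``config.tolerance_range`` when not given.  The same
    ``(config, subject_id, seed)`` always produce an identical recording.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 0xE17]))
    lo, hi = config.tolerance_range
    allowed = [lv for lv in STOP_LEVELS if lo <= lv <= hi]
    if tolerance is None:
        tolerance = int(rng.choice(allowed))
    elif tolerance not in allowed:
        raise InvalidConfigError(
            f"tolerance {tolerance} mmHg outside configured range {config.tolerance_range}")
    protocol = generate_protocol(tolerance, transition_duration=config.transition_duration)

    subject_scale = float(np.exp(config.subject_scale_sd * rng.standard_normal()))
    hr0 = 65.0 + 5.0 * rng.standard_normal()
    map0 = 90.0 + 8.0 * rng.standard_normal()

    step_pcts_thx = draw_step_percents(config, rng, len(protocol.steps) - 1)

    rpeaks = _synth_rpeaks(rng, protocol, config, hr0)
    map_series = _synth_map(rng, protocol, config, map0)
    pleth = _synth_pleth(rng, protocol, config, rpeaks)
    eit = {site: _synth_eit(rng, protocol, config, site, subject_scale, step_pcts_thx)
           for site in EIT_SITES}
    eis = {site: _synth_eis(rng, protocol, config, site, subject_scale)
           for site in EIS_SITES}
    lbnp = _synth_lbnp(protocol)

    return SubjectRecording(
        subject_id=str(subject_id),
        protocol=protocol,
        rpeak_times=rpeaks,
        map_series=map_series,
        pleth_waveform=pleth,
        eit_frames=eit,
        eis_spectra=eis,
        lbnp_series=lbnp,
        meta={"seed": int(seed), "tolerance_mmhg": int(tolerance),
              "subject_scale": subject_scale, "hr0_bpm": hr0, "map0_mmhg": map0,
              "step_pcts_thx": step_pcts_thx.tolist()},
    )


def synth_cohort(config: EffectConfig, n_subjects: int, seed: int,
                 min_levels_through: int | None = None) -> list[SubjectRecording]:
    """Generate ``n_subjects`` recordings with independently sampled tolerances.

    ``min_levels_through`` (mmHg) forces every subject's tolerance to be at
    least that level; the diagnostic analyses need all subjects to reach
    60 mmHg, which every valid tolerance already satisfies.
    """
    if n_subjects < 1:
        raise InvalidConfigError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(int(seed) % (2 ** 31))
    child_seeds = ss.generate_state(n_subjects).astype(np.int64) % (2 ** 31)
    recs = []
    for i in range(n_subjects):
        rec = synth_subject(config, f"S{i + 1:02d}", int(child_seeds[i]))
        if min_levels_through is not None and rec.protocol.stop_level < min_levels_through:
            rec = synth_subject(config, f"S{i + 1:02d}", int(child_seeds[i]),
                                tolerance=min_levels_through)
        recs.append(rec)
    return recs
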