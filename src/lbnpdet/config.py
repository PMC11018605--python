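"""Effect and noise configuration for the synthetic cohort generator.

The generator is phenomenological: it injects level-dependent effects into
each channel on top of realistic noise, without a biophysical forward model.
Default effect sizes are calibrated to the 16-subject stepped-LBNP study
conditions this pipeline targets:

* thoracic EIT impedance rises by small but consistent per-step percentages
  (cohort medians ~1.09/0.89/0.83/0.79 % for the four occult changes, with
  a hard floor at the observed minima 0.36/0.24/0.31/0.29 %);
* EIS magnitude shows its strongest relative effect in a mid-frequency band
  (8–27 kHz);
* HR rises appreciably only at high suction, Pleth pulse area declines from
  mid suction, MAP stays near-stable in the occult range;
* absolute impedance varies strongly across subjects (body habitus), which
  is why absolute impedance metrics discriminate poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidConfigError
from .protocol import STOP_LEVELS

#: Default per-step median percent increase of thoracic EIT impedance for
#: consecutive changes (0-15, 15-30, 30-45, 45-60 mmHg); reused for higher steps.
DEFAULT_EIT_THX_MEDIANS = (1.09, 0.89, 0.83, 0.79)
#: Default per-step minimum (floor) percent increases for the same changes.
DEFAULT_EIT_FLOORS = (0.36, 0.24, 0.31, 0.29)

DEFAULT_NOISE_SD: dict[str, float] = {
    # fast (sample-to-sample) noise
    "map_fast_mmhg": 1.5,
    "rr_frac": 0.03,            # fractional RR-interval jitter
    "pleth_beat_frac": 0.05,    # per-beat amplitude jitter
    "eit_channel_frac": 0.01,   # per-channel per-frame white noise
    "eis_point_frac": 0.002,    # per-frequency per-spectrum white noise
    # slow physiological wander (Ornstein-Uhlenbeck, ~5 min time constant)
    "map_slow_mmhg": 2.0,
    "hr_slow_bpm": 2.5,
    "pleth_slow_frac": 0.06,
    "eit_slow_frac": 0.004,
    "eis_slow_frac": 0.0045,
    # oscillatory contamination of impedance channels
    "eit_cardiac_frac": 0.003,
    "eit_resp_frac": 0.008,
}


@dataclass(frozen=True)
class EffectConfig:
    """Injected effect sizes and noise levels for the synthetic generator."""

    eit_thx_median_pct_step: tuple[float, ...] = DEFAULT_EIT_THX_MEDIANS
    eit_pct_floor: tuple[float, ...] = DEFAULT_EIT_FLOORS
    eit_ab_scale: float = 0.6
    #: per-site scale of the EIS relative effect (relative to the thoracic EIT draw)
    eis_site_scale: Mapping[str, float] = field(
        default_factory=lambda: {"thx": 0.8, "ab": 0.7, "arm": 0.25}
    )
    #: frequency band (Hz) where the relative EIS effect is maximal
    eis_effect_band: tuple[float, float] = (8e3, 27e3)
    #: dispersion (lognormal sigma) of the per-subject per-step impedance effect
    effect_sigma: float = 0.4
    hr_effect_by_level: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 15: 0.5, 30: 1.5, 45: 5.0, 60: 12.0,
                                 70: 18.0, 80: 24.0, 90: 30.0, 100: 36.0}
    )
    #: relative attenuation of the pleth pulse amplitude (-0.1 = 10% smaller)
    pleth_a_effect_by_level: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 15: -0.03, 30: -0.12, 45: -0.22, 60: -0.35,
                                 70: -0.45, 80: -0.55, 90: -0.62, 100: -0.68}
    )
    map_effect_by_level: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 15: -0.5, 30: -1.0, 45: -2.0, 60: -4.0,
                                 70: -7.0, 80: -11.0, 90: -17.0, 100: -25.0}
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    #: lognormal sigma of the subject-level multiplicative impedance scale
    subject_scale_sd: float = 0.2
    tolerance_range: tuple[int, int] = (60, 100)
    transition_duration: float = 48.0

    def __post_init__(self) -> None:
        med = np.asarray(self.eit_thx_median_pct_step, dtype=float)
        flo = np.asarray(self.eit_pct_floor, dtype=float)
        if not np.all(np.isfinite(med)) or not np.all(np.isfinite(flo)):
            raise InvalidConfigError("EIT percent effects must be finite")
        if med.size == 0 or flo.size == 0:
            raise InvalidConfigError("EIT effect lists must be non-empty")
        if np.min(flo) > np.min(med):
            raise InvalidConfigError("eit_pct_floor must not exceed the smallest median")
        n = min(med.size, flo.size)
        if np.any(flo[:n] > med[:n]):
            raise InvalidConfigError("each per-step floor must be <= its median")
        lo, hi = self.tolerance_range
        if lo not in STOP_LEVELS or hi not in STOP_LEVELS or lo > hi:
            raise InvalidConfigError(
                f"tolerance_range {self.tolerance_range} must span valid stop levels {STOP_LEVELS}"
            )
        unknown = set(self.noise_sd) - set(DEFAULT_NOISE_SD)
        if unknown:
            raise InvalidConfigError(f"unknown noise_sd keys: {sorted(unknown)}")
        if any(v < 0 for v in self.noise_sd.values()):
            raise InvalidConfigError("noise SDs must be non-negative")

    # -- calibration helpers -------------------------------------------------

    def step_median_pct(self, change_index: int) -> float:
        """Median percent increase for the ``change_index``-th consecutive change."""
        seq = self.eit_thx_median_pct_step
        return float(seq[min(change_index, len(seq) - 1)])

    def step_floor_pct(self, change_index: int) -> float:
        seq = self.eit_pct_floor
        return float(seq[min(change_index, len(seq) - 1)])

    def noise(self, key: str) -> float:
        return float(self.noise_sd.get(key, DEFAULT_NOISE_SD[key]))

    def with_zero_effects(self) -> "EffectConfig":
        """Null configuration: all injected effects zero, noise retained.

        The impedance-effect floor/median machinery is bypassed with zeros so
        downstream discrimination is chance-level by construction.
        """
        return replace(
            self,
            eit_thx_median_pct_step=(0.0,) * len(self.eit_thx_median_pct_step),
            eit_pct_floor=(0.0,) * len(self.eit_pct_floor),
            effect_sigma=0.0,
            hr_effect_by_level={k: 0.0 for k in self.hr_effect_by_level},
            pleth_a_effect_by_level={k: 0.0 for k in self.pleth_a_effect_by_level},
            map_effect_by_level={k: 0.0 for k in self.map_effect_by_level},
        )

    def with_zero_noise(self) -> "EffectConfig":
        """Deterministic configuration: all noise and dispersion removed."""
        return replace(
            self,
            noise_sd={k: 0.0 for k in DEFAULT_NOISE_SD},
            effect_sigma=0.0,
            subject_scale_sd=0.0,
        )

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eis_site_scale"] = dict(self.eis_site_scale)
        d["hr_effect_by_level"] = {int(k): float(v) for k, v in self.hr_effect_by_level.items()}
        d["pleth_a_effect_by_level"] = {
            int(k): float(v) for k, v in self.pleth_a_effect_by_level.items()
        }
        d["map_effect_by_level"] = {int(k): float(v) for k, v in self.map_effect_by_level.items()}
        d["noise_sd"] = dict(self.noise_sd)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("eit_thx_median_pct_step", "eit_pct_floor", "tolerance_range",
                    "eis_effect_band"):
            if key in kw and isinstance(kw[key], Sequence):
                kw[key] = tuple(kw[key])
        for key in ("hr_effect_by_level", "pleth_a_effect_by_level", "map_effect_by_level"):
            if key in kw:
                kw[key] = {int(k): float(v) for k, v in kw[key].items()}
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EffectConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
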