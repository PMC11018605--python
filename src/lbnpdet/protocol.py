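"""Stepped LBNP protocol timeline.

The protocol applies lower-body negative pressure in 5-minute steps:
baseline (0 mmHg), then 15 mmHg increments up to 60 mmHg, then 10 mmHg
increments up to 100 mmHg.  The pump needs a transition period at the start
of each step (~48 s on average), so the usable "stable period" of a 300 s
step is about 252 s (4.2 min).  A subject's run stops at their tolerance
level, somewhere between 60 and 100 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidConfigError

#: Full ladder of nominal LBNP levels (positive suction magnitude, mmHg).
LBNP_LEVELS: tuple[int, ...] = (0, 15, 30, 45, 60, 70, 80, 90, 100)

#: Levels retained by the diagnostic analyses (clinically occult range).
ANALYSIS_LEVELS: tuple[int, ...] = (0, 15, 30, 45, 60)

#: Levels at which a run may stop (subject tolerance).
STOP_LEVELS: tuple[int, ...] = (60, 70, 80, 90, 100)

STEP_DURATION_S: float = 300.0
DEFAULT_TRANSITION_S: float = 48.0


@dataclass(frozen=True)
class ProtocolStep:
    level: int          # mmHg, positive suction magnitude
    start_time: float   # s
    end_time: float     # s

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class ProtocolTimeline:
    """Contiguous sequence of LBNP steps for one subject."""

    steps: tuple[ProtocolStep, ...]
    transition_duration: float = DEFAULT_TRANSITION_S
    baseline_duration: float = STEP_DURATION_S

    def __post_init__(self) -> None:
        levels = [s.level for s in self.steps]
        if not levels or levels[0] != 0:
            raise InvalidConfigError("protocol must start with a 0 mmHg baseline step")
        expected = list(LBNP_LEVELS[: len(levels)])
        if levels != expected:
            raise InvalidConfigError(
                f"protocol levels {levels} do not follow the ladder {expected}"
            )
        for prev, cur in zip(self.steps, self.steps[1:]):
            if abs(prev.end_time - cur.start_time) > 1e-9:
                raise InvalidConfigError("protocol steps must be contiguous")
        if self.stop_level not in STOP_LEVELS:
            raise InvalidConfigError(
                f"stop level {self.stop_level} mmHg outside {STOP_LEVELS}"
            )

    @property
    def stop_level(self) -> int:
        return self.steps[-1].level

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(s.level for s in self.steps)

    @property
    def total_duration(self) -> float:
        return self.steps[-1].end_time

    def step_for_level(self, level: int) -> ProtocolStep:
        for s in self.steps:
            if s.level == level:
                return s
        raise KeyError(f"level {level} mmHg not in protocol {self.levels}")

    def stable_window(self, level: int, transition_skip: float | None = None) -> tuple[float, float]:
        """Window of a step after the pressure transition has settled.

        The skip is applied uniformly to every level, including baseline, so
        that the averaging window has the same duration at every level.
        """
        skip = self.transition_duration if transition_skip is None else transition_skip
        s = self.step_for_level(level)
        lo = s.start_time + skip
        if lo >= s.end_time:
            raise InvalidConfigError(
                f"transition skip {skip} s leaves no stable window in a {s.duration} s step"
            )
        return (lo, s.end_time)

    def level_at(self, t: float) -> int:
        """Nominal level of the step containing time ``t`` (end-exclusive)."""
        for s in self.steps:
            if s.start_time <= t < s.end_time:
                return s.level
        if t == self.total_duration:
            return self.steps[-1].level
        raise ValueError(f"time {t} s outside protocol [0, {self.total_duration}]")


def generate_protocol(
    subject_tolerance: int,
    transition_duration: float = DEFAULT_TRANSITION_S,
    step_duration: float = STEP_DURATION_S,
) -> ProtocolTimeline:
    """Build the step timeline for a subject stopping at ``subject_tolerance``.

    A 300 s baseline at 0 mmHg is followed by 300 s steps up the ladder
    until the tolerance level.  With the default 48 s transition, each
    step's stable period is 252 s = 4.2 min.
    """
    if subject_tolerance not in STOP_LEVELS:
        raise InvalidConfigError(
            f"tolerance {subject_tolerance} mmHg is not a valid stop level {STOP_LEVELS}"
        )
    if not 0 < transition_duration < step_duration:
        raise InvalidConfigError("transition must be positive and shorter than a step")
    levels = [lv for lv in LBNP_LEVELS if lv <= subject_tolerance]
    steps = tuple(
        ProtocolStep(level=lv, start_time=i * step_duration, end_time=(i + 1) * step_duration)
        for i, lv in enumerate(levels)
    )
    return ProtocolTimeline(
        steps=steps,
        transition_duration=transition_duration,
        baseline_duration=step_duration,
    )


@dataclass(frozen=True)
class BloodLossMap:
    """Cumulative blood-volume-loss equivalents of LBNP levels.

    The stepped LBNP model sequesters blood in the lower body; published
    calibration equates levels 15/30/45/60 mmHg with cumulative central
    volume losses of 93/193/313/451 ml.
    """

    pairs: tuple[tuple[int, int], ...] = ((0, 0), (15, 93), (30, 193), (45, 313), (60, 451))

    def __post_init__(self) -> None:
        lv = [p[0] for p in self.pairs]
        ml = [p[1] for p in self.pairs]
        if sorted(lv) != lv or sorted(ml) != ml or len(set(lv)) != len(lv):
            raise InvalidConfigError("blood-loss map must be strictly increasing")

    def cumulative(self, level: int) -> int:
        for lv, ml in self.pairs:
            if lv == level:
                return ml
        raise KeyError(f"level {level} mmHg not in blood-loss map (no interpolation)")

    def incremental(self, from_level: int, to_level: int) -> int:
        return self.cumulative(to_level) - self.cumulative(from_level)


def blood_loss(level_or_pair, loss_map: BloodLossMap | None = None) -> int:
    """Cumulative loss (ml) at a level, or incremental loss across a level pair."""
    m = loss_map or BloodLossMap()
    if isinstance(level_or_pair, (tuple, list)):
        a, b = level_or_pair
        return m.incremental(a, b)
    return m.cumulative(level_or_pair)
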