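"""Orbital-shaker stimulation parameterization.

Embryos are stimulated on an orbital shaker whose plateau describes a circle
of radius ``radius_cm`` at ``rpm`` rotations per minute, with the rotation
direction reversed every ``reversal_period_s`` seconds.  The tangential speed
of the dish rim gives the scale of the flow the embryos experience:

    peak speed = 2*pi * (rpm / 60) * radius_cm          [cm/s]

With the direction reversing periodically, the velocity is modelled as a
sinusoid of that amplitude, so the time-averaged absolute speed is
``(2/pi) * peak`` (a square-wave model, where the speed is always at the
peak, is also available).

Stochastic stimulation schedules are sequences of (rpm, duration, reversal
period) segments drawn uniformly within instrument limits; ``generate_schedule``
produces them reproducibly and ``validate_schedule`` checks any schedule
(including a hand-written one) against the limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Iterable

import numpy as np

__all__ = [
    "ShakerSettings",
    "ScheduleSegment",
    "StimulationSchedule",
    "InstrumentLimits",
    "PRINTED_STOCHASTIC_SCHEDULE",
    "flow_speed",
    "generate_schedule",
    "validate_schedule",
]


@dataclass(frozen=True)
class ShakerSettings:
    rpm: float
    radius_cm: float
    reversal_period_s: float

    def __post_init__(self) -> None:
        for name in ("rpm", "radius_cm", "reversal_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ScheduleSegment:
    rpm: float
    duration_min: float
    period_s: float


@dataclass(frozen=True)
class StimulationSchedule:
    segments: tuple[ScheduleSegment, ...]

    @property
    def total_duration_min(self) -> float:
        return float(sum(s.duration_min for s in self.segments))


@dataclass(frozen=True)
class InstrumentLimits:
    """Caller-supplied instrument envelope; defaults are the ranges used for
    the 2 h stochastic runs (68-99 rpm, reversal every 2-9 s, segment
    durations of 5-29 min)."""

    rpm_min: float = 68.0
    rpm_max: float = 99.0
    period_min_s: float = 2.0
    period_max_s: float = 9.0
    seg_min_min: float = 5.0
    seg_max_min: float = 29.0

    def __post_init__(self) -> None:
        if not (
            0 < self.rpm_min <= self.rpm_max
            and 0 < self.period_min_s <= self.period_max_s
            and 0 < self.seg_min_min <= self.seg_max_min
        ):
            raise ValueError("inconsistent instrument limits")


#: The six-segment stochastic sequence used for the 2 h stochastic runs,
#: as printed (rpm, duration in minutes, reversal period in seconds).  Note
#: that segments 1 and 6 fall below the 68 rpm lower limit quoted for the
#: instrument envelope; ``validate_schedule`` reports them as violations.
PRINTED_STOCHASTIC_SCHEDULE = StimulationSchedule(
    segments=(
        ScheduleSegment(58, 5, 5),
        ScheduleSegment(81, 27, 2),
        ScheduleSegment(76, 16, 9),
        ScheduleSegment(98, 22, 6),
        ScheduleSegment(76, 29, 5),
        ScheduleSegment(55, 28, 2),
    )
)


def flow_speed(settings: ShakerSettings, model: str = "sinusoidal") -> tuple[float, float]:
    """Peak and mean absolute tangential flow speed, in cm/s.

    peak = 2*pi*(rpm/60)*radius; mean |v| = (2/pi)*peak for the sinusoidal
    reversal model, = peak for the square model.
    """
    peak = 2.0 * pi * (settings.rpm / 60.0) * settings.radius_cm
    if model == "sinusoidal":
        mean_abs = (2.0 / pi) * peak
    elif model == "square":
        mean_abs = peak
    else:
        raise ValueError(f"unknown flow model: {model!r}")
    return peak, mean_abs


def generate_schedule(
    limits: InstrumentLimits,
    total_min: float,
    seed: int | None = 0,
) -> StimulationSchedule:
    """Draw segments uniformly within the instrument limits until the total
    duration reaches ``total_min``, truncating the last segment.
    """
    if total_min <= 0:
        raise ValueError("total_min must be > 0")
    rng = np.random.default_rng(seed)
    segments: list[ScheduleSegment] = []
    elapsed = 0.0
    while elapsed < total_min:
        rpm = float(rng.uniform(limits.rpm_min, limits.rpm_max))
        dur = float(rng.uniform(limits.seg_min_min, limits.seg_max_min))
        per = float(rng.uniform(limits.period_min_s, limits.period_max_s))
        dur = min(dur, total_min - elapsed)
        segments.append(ScheduleSegment(rpm, dur, per))
        elapsed += dur
    return StimulationSchedule(segments=tuple(segments))


def validate_schedule(
    schedule: StimulationSchedule,
    limits: InstrumentLimits,
) -> list[tuple[int, str, float]]:
    """Return (segment index, field, value) for every value outside the
    instrument limits; an empty list means the schedule is valid.

    A truncated final segment shorter than the minimum duration is tolerated.
    """
    violations: list[tuple[int, str, float]] = []
    n = len(schedule.segments)
    for i, seg in enumerate(schedule.segments):
        if not (limits.rpm_min <= seg.rpm <= limits.rpm_max):
            violations.append((i, "rpm", seg.rpm))
        low_ok = seg.duration_min >= limits.seg_min_min or i == n - 1
        if not (low_ok and seg.duration_min <= limits.seg_max_min):
            violations.append((i, "duration_min", seg.duration_min))
        if not (limits.period_min_s <= seg.period_s <= limits.period_max_s):
            violations.append((i, "period_s", seg.period_s))
    return violations
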