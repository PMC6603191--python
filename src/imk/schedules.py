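"""Temporal dose-delivery schedules.

A schedule describes *when* dose arrives: an ordered list of beam-on
segments, each with a constant dose rate.  Everything downstream — the
fractionated lethal-lesion sum, split-dose recovery, pulsed dose-rate
regimens — consumes this one representation.  "Acute" exposures are
segments with a very short but finite duration (``ACUTE_EPSILON_H``), so
there is no separate impulse code path.

Times are hours, doses gray (Gy), dose rates Gy/h throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Duration assigned to nominally instantaneous exposures (hours).
ACUTE_EPSILON_H = 1e-6

#: Beam-on dose rate of the X-ray source while delivering (Gy/min).
BEAM_ON_RATE_GY_PER_MIN = 0.59


@dataclass(frozen=True)
class DeliverySegment:
    """One beam-on (or explicitly beam-off) interval at constant dose rate."""

    start_time: float  # h
    duration: float    # h, > 0
    dose_rate: float   # Gy/h, >= 0

    def __post_init__(self) -> None:
        if not (self.start_time >= 0.0 and math.isfinite(self.start_time)):
            raise ValidationError(f"segment start_time must be >= 0, got {self.start_time}")
        if not (self.duration > 0.0 and math.isfinite(self.duration)):
            raise ValidationError(f"segment duration must be > 0, got {self.duration}")
        if not (self.dose_rate >= 0.0 and math.isfinite(self.dose_rate)):
            raise ValidationError(f"segment dose_rate must be >= 0, got {self.dose_rate}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def dose(self) -> float:
        return self.duration * self.dose_rate


@dataclass(frozen=True)
class DeliverySchedule:
    """Time-ordered, non-overlapping delivery segments."""

    segments: tuple[DeliverySegment, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError("schedule must contain at least one segment")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_time < prev.end_time - 1e-12:
                raise ValidationError(
                    f"segments overlap or are out of order at t={cur.start_time} h"
                )

    @property
    def start_time(self) -> float:
        return self.segments[0].start_time

    @property
    def end_time(self) -> float:
        return self.segments[-1].end_time

    @property
    def total_time(self) -> float:
        """Elapsed time T from first beam-on to last beam-off (h)."""
        return self.end_time - self.start_time

    @property
    def total_dose(self) -> float:
        return float(sum(s.dose for s in self.segments))

    def _cumulative_breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        times = [self.start_time]
        cum = [0.0]
        for seg in self.segments:
            if seg.start_time > times[-1]:          # beam-off gap
                times.append(seg.start_time)
                cum.append(cum[-1])
            times.append(seg.end_time)
            cum.append(cum[-1] + seg.dose)
        return np.asarray(times), np.asarray(cum)

    def cumulative_dose(self, t) -> np.ndarray:
        """Dose delivered up to time ``t`` (piecewise-linear in time)."""
        times, cum = self._cumulative_breakpoints()
        return np.interp(np.asarray(t, dtype=float), times, cum)

    def scaled(self, factor: float, label: str | None = None) -> "DeliverySchedule":
        """Same timing, all dose rates multiplied by ``factor`` (e.g. scatter)."""
        if factor < 0:
            raise ValidationError("scale factor must be >= 0")
        segs = tuple(
            DeliverySegment(s.start_time, s.duration, s.dose_rate * factor)
            for s in self.segments
        )
        return DeliverySchedule(segs, label if label is not None else self.label)


@dataclass(frozen=True)
class DiscretizedSchedule:
    """A schedule chopped into N equal sub-sections of width delta_t.

    ``segment_doses[n]`` is the dose landing in sub-section n, i.e. the
    average dose rate over that sub-section times delta_t.
    """

    delta_t: float
    segment_doses: np.ndarray
    n_steps: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "segment_doses", np.asarray(self.segment_doses, dtype=float)
        )
        if self.n_steps != len(self.segment_doses):
            raise ValidationError("n_steps must equal len(segment_doses)")

    @property
    def total_dose(self) -> float:
        return float(self.segment_doses.sum())

    @property
    def total_time(self) -> float:
        return self.delta_t * self.n_steps


def make_acute(dose: float, *, start_time: float = 0.0,
               epsilon: float = ACUTE_EPSILON_H, label: str = "acute") -> DeliverySchedule:
    """A nominally instantaneous exposure of ``dose`` Gy.

    The exposure is represented as a single segment of duration ``epsilon``
    hours so acute and protracted deliveries share one code path.
    """
    if dose < 0:
        raise ValidationError(f"dose must be >= 0, got {dose}")
    return DeliverySchedule(
        (DeliverySegment(start_time, epsilon, dose / epsilon),), label=label
    )


def make_split(d1: float, d2: float, tau: float,
               fraction_rate="acute", *,
               epsilon: float = ACUTE_EPSILON_H, label: str = "") -> DeliverySchedule:
    """Two fractions of ``d1`` and ``d2`` Gy separated by a gap of ``tau`` h.

    ``tau`` is measured from the end of the first fraction to the start of
    the second.  ``fraction_rate`` is either ``"acute"`` or a dose rate in
    Gy/h applied to both fractions.
    """
    if d1 < 0 or d2 < 0:
        raise ValidationError("fraction doses must be >= 0")
    if tau < 0:
        raise ValidationError(f"inter-fraction time must be >= 0, got {tau}")
    if fraction_rate == "acute":
        dur1, dur2 = epsilon, epsilon
        r1, r2 = d1 / dur1, d2 / dur2
    else:
        rate = float(fraction_rate)
        if rate <= 0:
            raise ValidationError("fraction_rate must be positive or 'acute'")
        dur1 = d1 / rate if d1 > 0 else epsilon
        dur2 = d2 / rate if d2 > 0 else epsilon
        r1 = d1 / dur1
        r2 = d2 / dur2
    segs = (
        DeliverySegment(0.0, dur1, r1),
        DeliverySegment(dur1 + tau, dur2, r2),
    )
    return DeliverySchedule(segs, label or f"split {d1}+{d2} Gy, tau={tau} h")


def make_constant_rate(dose: float, rate: float, *,
                       label: str = "") -> DeliverySchedule:
    """Continuous delivery of ``dose`` Gy at constant ``rate`` Gy/h."""
    if rate <= 0:
        raise ValidationError(f"dose rate must be > 0, got {rate}")
    if dose < 0:
        raise ValidationError(f"dose must be >= 0, got {dose}")
    if dose == 0:
        return DeliverySchedule(
            (DeliverySegment(0.0, ACUTE_EPSILON_H, 0.0),), label or "zero dose"
        )
    return DeliverySchedule(
        (DeliverySegment(0.0, dose / rate, rate),),
        label or f"{dose} Gy at {rate} Gy/h",
    )


def discretize(schedule: DeliverySchedule, n_steps: int) -> DiscretizedSchedule:
    """Chop ``schedule`` into ``n_steps`` equal sub-sections (T = N dT).

    Sub-section doses are exact integrals of the dose-rate profile, so the
    total dose is conserved regardless of how segment boundaries align with
    the grid.
    """
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
    edges = np.linspace(schedule.start_time, schedule.end_time, n_steps + 1)
    cum = schedule.cumulative_dose(edges)
    return DiscretizedSchedule(
        delta_t=schedule.total_time / n_steps,
        segment_doses=np.diff(cum),
        n_steps=n_steps,
    )


# --- pulsed dose-rate regimen presets --------------------------------------
#
# The four time-averaged dose-rate regimens (0.59, 0.2, 0.1 and 0.05 Gy/min
# for a total of 4 Gy) are delivered by a source that is always on at
# 0.59 Gy/min; the lower averages are produced by interleaving beam-off
# gaps.  The exact pulse pattern of the experimental rig is not published,
# so these presets are approximations: equal pulses with equal gaps sized
# to hit the stated average rate.  They are data, not code — pass your own
# mapping to :func:`pulsed_regimen` to override.

DEFAULT_REGIMENS: dict[str, dict] = {
    "0.59": {"average_rate_gy_per_min": 0.59},
    "0.2": {"average_rate_gy_per_min": 0.2},
    "0.1": {"average_rate_gy_per_min": 0.1},
    "0.05": {"average_rate_gy_per_min": 0.05},
}


def pulsed_regimen(average_rate_gy_per_min: float, *,
                   total_dose: float = 4.0,
                   beam_rate_gy_per_min: float = BEAM_ON_RATE_GY_PER_MIN,
                   n_pulses: int = 8,
                   label: str = "") -> DeliverySchedule:
    """Equal-pulse schedule reaching a given time-averaged dose rate.

    If the requested average equals the beam-on rate the schedule is a
    single continuous segment.
    """
    if average_rate_gy_per_min <= 0 or total_dose < 0:
        raise ValidationError("average rate must be > 0 and total dose >= 0")
    if average_rate_gy_per_min > beam_rate_gy_per_min * (1 + 1e-12):
        raise ValidationError("average rate cannot exceed the beam-on rate")
    avg_h = average_rate_gy_per_min * 60.0
    beam_h = beam_rate_gy_per_min * 60.0
    label = label or f"{average_rate_gy_per_min} Gy/min avg, {total_dose} Gy"
    if abs(average_rate_gy_per_min - beam_rate_gy_per_min) < 1e-12:
        return make_constant_rate(total_dose, beam_h, label=label)
    if n_pulses < 2:
        raise ValidationError("pulsed regimens need n_pulses >= 2")
    pulse_dose = total_dose / n_pulses
    on = pulse_dose / beam_h
    total_time = total_dose / avg_h
    gap = (total_time - n_pulses * on) / (n_pulses - 1)
    segs = tuple(
        DeliverySegment(i * (on + gap), on, beam_h) for i in range(n_pulses)
    )
    return DeliverySchedule(segs, label)


def regimen_schedule(name: str, *, total_dose: float = 4.0,
                     regimens: dict[str, dict] | None = None) -> DeliverySchedule:
    """Build one of the named dose-rate regimen presets."""
    table = DEFAULT_REGIMENS if regimens is None else regimens
    if name not in table:
        raise ValidationError(
            f"unknown regimen {name!r}; available: {sorted(table)}"
        )
    spec = dict(table[name])
    spec.setdefault("label", f"regimen {name} Gy/min")
    return pulsed_regimen(total_dose=total_dose, **spec)
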