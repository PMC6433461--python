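"""Reagent switching schedules for laminar-flow buffer exchange.

In a two-inlet laminar flow cell, alternating the syringe flow rates shifts
the boundary between the two reagent streams across the tethered DNA.  The
switch is not instantaneous: the boundary sweeps past the molecule over a
finite *exchange time* (measured with a fluorescein tracer to be ~6.5 s).
A :class:`SwitchingSchedule` describes the resulting piecewise
concentration protocol c(t) seen by the molecule, with each switch smoothed
by a linear (default) or logistic ramp of that duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScheduleError", "SwitchingSchedule", "concentration_profile"]

DEFAULT_EXCHANGE_TIME = 6.5  # s, complete boundary shift at the working flow rates


class ScheduleError(ValueError):
    """Invalid switching-schedule configuration."""


@dataclass(frozen=True)
class SwitchingSchedule:
    """Piecewise reagent-concentration protocol with boundary-exchange smoothing.

    Parameters
    ----------
    segments
        Ordered ``(start_time_s, concentration_M)`` pairs describing one
        cycle.  The first segment's concentration also applies before its
        start time.  Times must be strictly increasing, concentrations
        non-negative.
    period
        Cycle length in seconds.  If set, the segment pattern repeats every
        ``period`` seconds (the return to ``segments[0]`` at each cycle
        boundary is itself a smoothed switch).  ``None`` means the schedule
        does not repeat.
    exchange_time
        Duration of the boundary shift: each switch starts at its segment
        time and completes exactly ``exchange_time`` later.
    profile_shape
        ``"linear"`` ramp (default) or ``"logistic"`` (smooth sigmoid,
        normalised to hit both endpoints exactly).
    """

    segments: tuple[tuple[float, float], ...]
    period: float | None = None
    exchange_time: float = DEFAULT_EXCHANGE_TIME
    profile_shape: str = "linear"

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(c)) for t, c in self.segments)
        object.__setattr__(self, "segments", segs)
        if len(segs) == 0:
            raise ScheduleError("schedule must contain at least one segment")
        times = [t for t, _ in segs]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError("segment start times must be strictly increasing")
        if any(c < 0 for _, c in segs):
            raise ScheduleError("concentrations must be non-negative")
        if self.exchange_time <= 0:
            raise ScheduleError("exchange_time must be positive")
        if self.profile_shape not in ("linear", "logistic"):
            raise ScheduleError(f"unknown profile_shape {self.profile_shape!r}")
        if self.period is not None and self.period <= times[-1] - times[0]:
            raise ScheduleError("period must exceed the span of one cycle's segments")

    @classmethod
    def square_wave(cls, concentration: float, period: float = 60.0,
                    duty: float = 0.5, exchange_time: float = DEFAULT_EXCHANGE_TIME,
                    profile_shape: str = "linear") -> "SwitchingSchedule":
        """Protein-on / buffer-off square wave (protein first), repeating."""
        if not 0 < duty < 1:
            raise ScheduleError("duty must be in (0, 1)")
        return cls(segments=((0.0, concentration), (duty * period, 0.0)),
                   period=period, exchange_time=exchange_time,
                   profile_shape=profile_shape)

    @classmethod
    def constant(cls, concentration: float,
                 exchange_time: float = DEFAULT_EXCHANGE_TIME) -> "SwitchingSchedule":
        """A schedule with a single, never-switched concentration."""
        return cls(segments=((0.0, concentration),), exchange_time=exchange_time)

    # ------------------------------------------------------------------

    def switch_events(self, duration: float) -> list[tuple[float, float]]:
        """All ``(switch_time, new_concentration)`` events in ``[t0, duration]``.

        The first segment is not a switch (its concentration is the initial
        condition); cycle-boundary returns to the first segment are.
        """
        t0 = self.segments[0][0]
        events: list[tuple[float, float]] = []
        if self.period is None:
            events = [(t, c) for t, c in self.segments[1:] if t <= duration]
        else:
            k = 0
            while t0 + k * self.period <= duration:
                offset = k * self.period
                for i, (t, c) in enumerate(self.segments):
                    if i == 0 and k == 0:
                        continue  # initial condition, not a switch
                    te = t + offset
                    if te <= duration:
                        events.append((te, c))
                k += 1
            events.sort()
        return events

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return concentration_profile(self, t)


def _ramp_fraction(u: np.ndarray, shape: str) -> np.ndarray:
    """Completed fraction of a switch at normalised time u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    if shape == "linear":
        return u
    # logistic, rescaled so f(0)=0 and f(1)=1 exactly
    a = 10.0
    s = 1.0 / (1.0 + np.exp(-a * (u - 0.5)))
    s0 = 1.0 / (1.0 + math.exp(a * 0.5))
    s1 = 1.0 / (1.0 + math.exp(-a * 0.5))
    return (s - s0) / (s1 - s0)


def concentration_profile(schedule: SwitchingSchedule,
                          t: float | np.ndarray) -> float | np.ndarray:
    """Reagent concentration (molar) at time(s) ``t``.

    Constant within each segment; each switch ramps from the value at the
    switch instant to the new target over ``schedule.exchange_time`` with
    the schedule's profile shape.  Before the first segment the initial
    concentration applies.  Switches closer together than the exchange time
    restart the ramp from the mid-ramp value.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ScheduleError("t must be non-negative")
    tau = schedule.exchange_time
    events = schedule.switch_events(float(t_arr.max()) if t_arr.size else 0.0)

    # value reached at each event start (ramps may be interrupted)
    start_values = [schedule.segments[0][1]]
    for i, (te, target) in enumerate(events):
        if i + 1 < len(events):
            dt_next = events[i + 1][0] - te
        else:
            dt_next = math.inf
        frac = float(_ramp_fraction(np.asarray(min(dt_next, tau) / tau), schedule.profile_shape))
        start_values.append(start_values[-1] + (target - start_values[-1]) * frac)

    out = np.full_like(t_arr, schedule.segments[0][1])
    for i, (te, target) in enumerate(events):
        mask = t_arr >= te
        if not mask.any():
            break
        v0 = start_values[i + 1 - 1]  # value when this ramp starts
        frac = _ramp_fraction((t_arr[mask] - te) / tau, schedule.profile_shape)
        out[mask] = v0 + (target - v0) * frac
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out
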