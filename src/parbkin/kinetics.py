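"""Exponential kinetic fits for binding/unbinding traces.

The fluorescence of a protein-coated DNA under pseudo-first-order exchange
follows single exponentials:

* association (protein at concentration c flowed in):
  ``F(t) = Fmax * (1 - exp(-kobs * t))`` with ``kobs = kon*c + koff``;
* dissociation (buffer flowed in, c = 0):
  ``F(t) = F0 * exp(-koff * t)``.

Each molecule's trace is segmented into association/dissociation phases
aligned to the buffer-switch times (excluding a dead time equal to the
boundary-exchange interval), each phase is fitted independently by
unweighted least squares, and per-condition statistics are taken across
molecules (mean ± SD), not from a global fit.  ``kon`` is estimated from
the slope of kobs versus concentration restricted to the lowest
concentrations, where fluid exchange does not yet limit the observed rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .schedule import SwitchingSchedule
from .trace import IntensityTrace

__all__ = [
    "PhaseWindow",
    "KineticFit",
    "ConditionSummary",
    "KonEstimate",
    "BleachFit",
    "FrapFit",
    "segment_cycles",
    "fit_dissociation",
    "fit_association",
    "fit_phase",
    "estimate_kon",
    "half_life",
    "fit_bleach_halflife",
    "fit_frap_recovery",
    "aggregate_condition",
]

_FIT_XTOL = 1e-10  # parameter tolerance for the nonlinear fits
MIN_POINTS = 3


@dataclass(frozen=True)
class PhaseWindow:
    """One association or dissociation phase of a switching experiment.

    ``start``/``end`` are absolute trace times in seconds; ``start``
    already excludes the dead time after the switch.  ``concentration`` is
    the reagent concentration during the phase (0 for dissociation).
    """

    kind: str  # "association" | "dissociation"
    start: float
    end: float
    concentration: float
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("association", "dissociation"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("phase window must have start < end")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class KineticFit:
    """Result of a single-phase exponential fit.

    ``rate`` is koff (dissociation) or kobs (association) in s^-1;
    ``amplitude`` is F0 or Fmax in counts.  ``ok`` is False for
    non-converged fits, which aggregation excludes.
    """

    rate: float
    amplitude: float
    stderr: float
    rss: float
    n_points: int
    kind: str
    window: PhaseWindow | None = None
    molecule_id: str = ""
    ok: bool = True
    flag: str = ""


@dataclass
class ConditionSummary:
    """Across-molecule statistics of one rate under one condition."""

    label: str
    concentration: float | None
    mean_rate: float
    sd_rate: float
    n_molecules: int

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.sd_rate < 0:
            raise ValueError("SD must be non-negative")


@dataclass
class KonEstimate:
    """Linear kobs-vs-concentration fit: slope = kon, intercept = koff."""

    kon: float
    koff_intercept: float
    kon_stderr: float
    n_points: int


@dataclass
class BleachFit:
    """Photobleach rate and half-life from a crosslinked-control trace."""

    k_bleach: float
    half_life_s: float
    fit: KineticFit
    ok: bool = True
    flag: str = ""


@dataclass
class FrapFit:
    """Post-pulse fluorescence recovery fit."""

    rate: float
    plateau: float
    recovery_fraction: float
    stderr: float
    n_points: int
    ok: bool = True


# ----------------------------------------------------------------------
# segmentation


def segment_cycles(trace: IntensityTrace, schedule: SwitchingSchedule,
                   dead_time: float = 6.5) -> list[PhaseWindow]:
    """Split a trace into association/dissociation windows at the switch times.

    Each window runs from its (cycle or switch) start plus ``dead_time`` —
    absorbing the boundary-shift interval — to the next switch (or trace
    end).  Windows left with fewer than 3 frames are dropped with a
    warning.  The phase kind follows the schedule concentration:
    association where c > 0, dissociation where c = 0.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    t_end = float(trace.times[-1])
    events = schedule.switch_events(t_end)
    boundaries = [(float(trace.times[0]), schedule.segments[0][1])]
    boundaries += [(t, c) for t, c in events]

    windows: list[PhaseWindow] = []
    for i, (t_switch, conc) in enumerate(boundaries):
        stop = boundaries[i + 1][0] if i + 1 < len(boundaries) else t_end + 0.5 / trace.frame_rate
        start = t_switch + dead_time
        kind = "association" if conc > 0 else "dissociation"
        n_frames = np.count_nonzero((trace.times >= start) & (trace.times < stop))
        if start >= stop or n_frames < MIN_POINTS:
            warnings.warn(f"dropping {kind} window at t={t_switch:.1f}s: "
                          f"fewer than {MIN_POINTS} frames after dead time",
                          stacklevel=2)
            continue
        windows.append(PhaseWindow(kind=kind, start=start, end=stop,
                                   concentration=conc, dead_time=dead_time))
    return windows


def _window_data(trace: IntensityTrace,
                 window: PhaseWindow | None) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        t, y = trace.times, trace.values
    else:
        sub = trace.crop(window.start, window.end)
        t, y = sub.times, sub.values
    if t.size < MIN_POINTS:
        raise ValueError(f"phase has fewer than {MIN_POINTS} points")
    return t - t[0], y


# ----------------------------------------------------------------------
# single-phase fits


def _curve_fit(model, t, y, p0, bounds) -> tuple[np.ndarray, np.ndarray] | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                            xtol=_FIT_XTOL, ftol=1e-12,
                                            maxfev=10000)
        return popt, pcov
    except (RuntimeError, optimize.OptimizeWarning):
        return None


def fit_dissociation(trace: IntensityTrace,
                     window: PhaseWindow | None = None) -> KineticFit:
    """Fit ``F(t) = F0 * exp(-koff * t)`` to a dissociation phase.

    Initialised from a log-linear regression on the positive values;
    standard error of koff comes from the fit covariance.  A non-converged
    fit is returned with ``ok=False`` and is excluded from aggregation.
    """
    t, y = _window_data(trace, window)

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 0.0)
        f0 = math.exp(intercept)
    else:
        k0, f0 = 0.1, max(float(y[0]), 1.0)

    def model(tt, f, k):
        return f * np.exp(-k * tt)

    res = _curve_fit(model, t, y, p0=[f0, k0],
                     bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    if res is None:
        return KineticFit(rate=math.nan, amplitude=math.nan, stderr=math.nan,
                          rss=math.nan, n_points=t.size, kind="dissociation",
                          window=window, molecule_id=trace.molecule_id,
                          ok=False, flag="no_convergence")
    (f_fit, k_fit), pcov = res
    resid = y - model(t, f_fit, k_fit)
    return KineticFit(rate=float(k_fit), amplitude=float(f_fit),
                      stderr=float(np.sqrt(pcov[1, 1])), rss=float(resid @ resid),
                      n_points=t.size, kind="dissociation", window=window,
                      molecule_id=trace.molecule_id)


def fit_association(trace: IntensityTrace,
                    window: PhaseWindow | None = None) -> KineticFit:
    """Fit ``F(t) = Fmax * (1 - exp(-kobs * t))`` to an association phase.

    kobs is initialised from the time to half-plateau
    (``kobs0 = ln 2 / t_half``), Fmax from the mean of the final decile.
    """
    t, y = _window_data(trace, window)

    fmax0 = float(np.mean(y[-max(1, t.size // 10):]))
    if fmax0 <= 0:
        fmax0 = max(float(y.max()), 1.0)
    above = np.nonzero(y >= 0.5 * fmax0)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2) / t_half

    def model(tt, f, k):
        return f * (1.0 - np.exp(-k * tt))

    res = _curve_fit(model, t, y, p0=[fmax0, k0],
                     bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    if res is None:
        return KineticFit(rate=math.nan, amplitude=math.nan, stderr=math.nan,
                          rss=math.nan, n_points=t.size, kind="association",
                          window=window, molecule_id=trace.molecule_id,
                          ok=False, flag="no_convergence")
    (f_fit, k_fit), pcov = res
    resid = y - model(t, f_fit, k_fit)
    return KineticFit(rate=float(k_fit), amplitude=float(f_fit),
                      stderr=float(np.sqrt(pcov[1, 1])), rss=float(resid @ resid),
                      n_points=t.size, kind="association", window=window,
                      molecule_id=trace.molecule_id)


def fit_phase(trace: IntensityTrace, window: PhaseWindow) -> KineticFit:
    """Dispatch to the association or dissociation fit for ``window``."""
    if window.kind == "association":
        return fit_association(trace, window)
    return fit_dissociation(trace, window)


# ----------------------------------------------------------------------
# derived quantities


def estimate_kon(points: list[tuple[float, float]], n_low: int = 2) -> KonEstimate:
    """Estimate kon from the low-concentration linear regime of kobs(c).

    Fits ``kobs = kon*c + koff`` by ordinary least squares to the ``n_low``
    lowest-concentration points; the slope is kon (M^-1 s^-1) and the
    intercept an independent estimate of koff.
    """
    if n_low < 2:
        raise ValueError("n_low must be >= 2")
    if n_low > len(points):
        raise ValueError(f"n_low={n_low} exceeds the {len(points)} available points")
    pts = sorted(points, key=lambda p: p[0])[:n_low]
    c = np.array([p[0] for p in pts], dtype=float)
    k = np.array([p[1] for p in pts], dtype=float)
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    if n_low == 2:
        kon = (k[1] - k[0]) / (c[1] - c[0])
        return KonEstimate(kon=float(kon), koff_intercept=float(k[0] - kon * c[0]),
                           kon_stderr=math.nan, n_points=2)
    reg = stats.linregress(c, k)
    return KonEstimate(kon=float(reg.slope), koff_intercept=float(reg.intercept),
                       kon_stderr=float(reg.stderr), n_points=n_low)


def half_life(rate: float) -> float:
    """Half-life ``ln 2 / rate`` in seconds (rate in s^-1, must be positive)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return math.log(2) / rate


def fit_bleach_halflife(trace: IntensityTrace,
                        window: PhaseWindow | None = None) -> BleachFit:
    """Photobleach rate and half-life from a crosslinked-control trace.

    With koff pinned to zero by crosslinking and no free labelled protein,
    the intensity decay is photobleaching alone; a single-exponential fit
    gives ``k_bleach`` and ``half-life = ln 2 / k_bleach``.  A trace with
    no measurable decay is flagged and reported with infinite half-life.
    """
    fit = fit_dissociation(trace, window)
    if not fit.ok:
        return BleachFit(k_bleach=math.nan, half_life_s=math.nan, fit=fit,
                         ok=False, flag=fit.flag)
    if fit.rate < 1e-10:
        return BleachFit(k_bleach=fit.rate, half_life_s=math.inf, fit=fit,
                         ok=True, flag="no_decay")
    return BleachFit(k_bleach=fit.rate, half_life_s=half_life(fit.rate), fit=fit)


def fit_frap_recovery(trace: IntensityTrace, pre_pulse_plateau: float,
                      window: PhaseWindow | None = None) -> FrapFit:
    """Fit the post-pulse recovery ``F(t) = Fplateau * (1 - exp(-k_rec * t))``.

    ``trace`` (or ``window``) should cover the recovery only, with t = 0 at
    the end of the bleach pulse.  The recovery fraction is the fitted
    plateau relative to the pre-pulse plateau.

    Note on the expected rate: because bleached molecules still occupy
    their sites and leave at koff, the exact recovery of the fluorescent
    occupancy after a full-field bleach at steady state is
    ``b* (1 - exp(-koff t))`` — the recovery is rate-limited by koff, with
    amplitude equal to the pre-pulse steady state.
    """
    if pre_pulse_plateau <= 0:
        raise ValueError("pre_pulse_plateau must be positive")
    fit = fit_association(trace, window)
    if not fit.ok:
        return FrapFit(rate=math.nan, plateau=math.nan, recovery_fraction=math.nan,
                       stderr=math.nan, n_points=fit.n_points, ok=False)
    return FrapFit(rate=fit.rate, plateau=fit.amplitude,
                   recovery_fraction=fit.amplitude / pre_pulse_plateau,
                   stderr=fit.stderr, n_points=fit.n_points)


def aggregate_condition(fits: list[KineticFit], label: str,
                        concentration: float | None = None) -> ConditionSummary:
    """Across-molecule mean ± SD of the fitted rates (per-molecule-first).

    Flagged (non-converged) fits are excluded; aggregating an empty or
    all-flagged list is an error.  SD is the sample standard deviation
    (0 for a single fit).
    """
    rates = np.array([f.rate for f in fits if f.ok], dtype=float)
    if rates.size == 0:
        raise ValueError("no unflagged fits to aggregate")
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return ConditionSummary(label=label, concentration=concentration,
                            mean_rate=float(rates.mean()), sd_rate=sd,
                            n_molecules=int(rates.size))
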