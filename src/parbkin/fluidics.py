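"""Flow-cell physics: hydrodynamic radius, Reynolds number, force budget,
and boundary-exchange-time estimation from a tracer trace.

All computations are in coherent SI units (metres, seconds, pascal-seconds,
kg/m^3, newtons); the CLI converts from the bench units (µm, mm, µl/min,
pN).  Note that evaluating the Reynolds number with the cell's stated
geometry and flow in SI gives Re on the order of 0.4 — either way orders of
magnitude below the ~2000 turbulence threshold, so the operative laminar
bound holds for any defensible unit reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .trace import IntensityTrace

__all__ = [
    "FlowCellGeometry",
    "FluidState",
    "ForceBudget",
    "ReynoldsResult",
    "hydrodynamic_radius",
    "reynolds_number",
    "total_force",
    "drag_force_from_flow_rate",
    "exchange_time",
]

LAMINAR_THRESHOLD = 2000.0


@dataclass(frozen=True)
class FlowCellGeometry:
    """Rectangular duct cross-section: height ``d`` and width ``w`` in metres."""

    d: float = 200e-6
    w: float = 3e-3

    def __post_init__(self) -> None:
        if self.d <= 0 or self.w <= 0:
            raise ValueError("flow-cell dimensions must be positive")


@dataclass(frozen=True)
class FluidState:
    """Bulk fluid properties and mean linear velocity (SI units)."""

    v_mean: float = 1e-3       # m/s at the maximum working flow rate
    viscosity: float = 1e-3    # Pa s (water)
    density: float = 1000.0    # kg/m^3 (water)

    def __post_init__(self) -> None:
        if min(self.v_mean, self.viscosity, self.density) <= 0:
            raise ValueError("fluid parameters must be positive")


@dataclass(frozen=True)
class ForceBudget:
    """Magnetic, drag and total force on the DNA, in piconewtons.

    The magnetic pull and the flow drag act along orthogonal axes, so the
    total is the Euclidean sum and satisfies
    ``max(Fm, Fd) <= F_total <= Fm + Fd``.
    """

    F_magnetic: float
    F_drag: float
    F_total: float


class ReynoldsResult(NamedTuple):
    value: float
    laminar: bool


def hydrodynamic_radius(geometry: FlowCellGeometry) -> float:
    """Equivalent hydrodynamic radius of a rectangular duct, ``r = d*w/(d+w)``."""
    return geometry.d * geometry.w / (geometry.d + geometry.w)


def reynolds_number(r: float, fluid: FluidState) -> ReynoldsResult:
    """``Re = 2 r rho v_mean / eta`` and whether the flow is laminar (Re < 2000)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    re = 2.0 * r * fluid.density * fluid.v_mean / fluid.viscosity
    return ReynoldsResult(value=re, laminar=re < LAMINAR_THRESHOLD)


def total_force(F_magnetic: float, F_drag: float) -> ForceBudget:
    """Total force on the DNA: orthogonal sum ``sqrt(Fm^2 + Fd^2)`` (pN in, pN out)."""
    if F_magnetic < 0 or F_drag < 0:
        raise ValueError("forces must be non-negative")
    return ForceBudget(F_magnetic=F_magnetic, F_drag=F_drag,
                       F_total=math.hypot(F_magnetic, F_drag))


def drag_force_from_flow_rate(flow_rate_ul_min: float,
                              calibration: Sequence[tuple[float, float]]) -> float:
    """Drag force (pN) at a flow rate (µl/min) from a measured calibration table.

    ``calibration`` is a sequence of ``(flow_rate_ul_min, force_pN)`` points
    from a flow-stretch measurement; linear interpolation between points,
    no extrapolation beyond the calibrated range.
    """
    if len(calibration) < 2:
        raise ValueError("calibration table needs at least 2 points")
    cal = sorted(calibration)
    q = np.array([p[0] for p in cal], dtype=float)
    f = np.array([p[1] for p in cal], dtype=float)
    if not (q[0] <= flow_rate_ul_min <= q[-1]):
        raise ValueError("flow rate outside the calibrated range")
    return float(np.interp(flow_rate_ul_min, q, f))


def exchange_time(trace: IntensityTrace, low_q: float = 0.05, high_q: float = 0.95,
                  plateau_frac: float = 0.2,
                  smooth_window: int | None = None) -> float:
    """Boundary-exchange duration from a tracer (e.g. fluorescein) trace.

    The trace must contain a single monotone-in-mean transition between two
    plateaus.  The plateaus are estimated as medians of the first and last
    ``plateau_frac`` of the trace; the exchange time is the interval between
    the first samples at or beyond the ``low_q`` and ``high_q`` fractional
    levels of the plateau-to-plateau swing (defaults 5% and 95%).  An ideal
    step therefore yields 0; an ideal linear ramp of duration T yields
    ``(high_q - low_q) * T`` up to one frame of discretisation.

    ``smooth_window`` (frames) applies a centred moving average before the
    crossing search, for noisy traces.  Indistinguishable plateaus (swing
    below 3x the plateau noise SD) raise an error.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    v = trace.values.astype(float)
    n = v.size
    k = max(3, int(plateau_frac * n))
    if n < 2 * k:
        raise ValueError("trace too short to estimate plateaus")
    p0 = float(np.median(v[:k]))
    p1 = float(np.median(v[-k:]))
    noise = max(float(np.std(v[:k])), float(np.std(v[-k:])))
    if abs(p1 - p0) < 3.0 * noise:
        raise ValueError("plateaus indistinguishable from noise")

    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kernel, mode="same")
    u = (v - p0) / (p1 - p0)  # 0 at the initial plateau, 1 at the final one

    lo_idx = np.nonzero(u >= low_q)[0]
    hi_idx = np.nonzero(u >= high_q)[0]
    if lo_idx.size == 0 or hi_idx.size == 0:
        raise ValueError("trace never crosses the requested levels")
    return float(trace.times[hi_idx[0]] - trace.times[lo_idx[0]])
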