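"""Stochastic simulation of fluorescent protein binding to a DNA lattice.

The imaged DNA segment is modelled as ``n_sites`` independent, identical
non-specific binding sites.  Each empty site binds protein from solution at
rate ``kon * c(t)`` (pseudo-first order in the free concentration, which the
flow cell holds constant within a phase) and each bound protein unbinds at
``koff``.  A bound dimer carries ``dyes_per_dimer`` fluorophores that bleach
independently at ``k_bleach`` under imaging illumination (or at
``k_bleach_pulse`` during a FRAP pulse).  Bleaching affects emission only:
a fully bleached dimer still occupies its site and still unbinds at
``koff``.  Newly arriving dimers come from the (unbleached) solution pool
and carry a full dye complement.

This is the two-state scheme

    DNA + P  <->(kon, koff)  DNA:P

with mean occupancy relaxing as ``1 - exp(-(kon*c + koff)*t)`` toward the
Langmuir level ``kon*c / (kon*c + koff)``; the model deliberately excludes
cooperativity and nucleation intermediates.

Time stepping is per-frame Bernoulli with automatic sub-stepping so that no
per-step transition probability exceeds 0.1; probabilities within a substep
use the exact exponential form ``1 - exp(-r*dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .schedule import SwitchingSchedule, concentration_profile
from .trace import IntensityTrace

__all__ = [
    "KineticModel",
    "SimulationTruth",
    "OccupancyTrajectory",
    "simulate_binding",
    "run_protocol",
    "simulate_condensation_assay",
]

MAX_STEP_PROBABILITY = 0.1  # sub-step until every per-step probability is below this


@dataclass(frozen=True)
class KineticModel:
    """Two-state binding model: association ``kon`` (M^-1 s^-1), dissociation ``koff`` (s^-1)."""

    kon: float
    koff: float

    def __post_init__(self) -> None:
        if self.kon < 0 or self.koff < 0:
            raise ValueError("kon and koff must be non-negative")

    def kobs(self, concentration: float) -> float:
        """Observed association rate ``kon*c + koff`` (s^-1)."""
        return self.kon * concentration + self.koff

    def occupancy(self, concentration: float) -> float:
        """Langmuir steady-state occupancy fraction ``kon*c / (kon*c + koff)``."""
        kc = self.kon * concentration
        denom = kc + self.koff
        return kc / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth kinetic and optical parameters of a synthetic experiment.

    Defaults are the conditions of the emulated measurements: 9.52 Hz
    acquisition, a 28 s fluorophore bleaching half-life at imaging power,
    ~2 dyes per labelled monomer hence 4 per bound dimer, and 200 sites on
    the ~24 kbp DNA.  ``visible_fraction`` models the part of the tilted
    DNA near the bead that falls outside the evanescent TIRF field.
    """

    model: KineticModel
    n_sites: int = 200
    dyes_per_dimer: int = 4
    k_bleach: float = math.log(2) / 28.0
    k_bleach_pulse: float = 20.0
    frame_rate: float = 9.52
    visible_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.dyes_per_dimer < 1:
            raise ValueError("dyes_per_dimer must be >= 1")
        if min(self.k_bleach, self.k_bleach_pulse, self.frame_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 < self.visible_fraction <= 1:
            raise ValueError("visible_fraction must be in (0, 1]")


@dataclass
class OccupancyTrajectory:
    """Per-frame site occupancy and fluorophore state of one simulated molecule.

    ``bound`` and ``dye_counts`` are ``(n_frames, n_sites)`` arrays: which
    sites are occupied, and how many unbleached dyes each occupant carries
    (0 for empty sites).  ``visible`` marks the sites inside the TIRF field.
    """

    times: np.ndarray
    bound: np.ndarray        # (n_frames, n_sites) bool
    dye_counts: np.ndarray   # (n_frames, n_sites) uint8, 0 where not bound
    visible: np.ndarray      # (n_sites,) bool
    frame_rate: float

    @property
    def n_sites(self) -> int:
        return self.bound.shape[1]

    @property
    def bound_total(self) -> np.ndarray:
        """Occupied sites per frame (fluorescent + bleached)."""
        return self.bound.sum(axis=1)

    @property
    def bound_fluorescent(self) -> np.ndarray:
        """Occupied sites per frame that still carry at least one unbleached dye."""
        return (self.bound & (self.dye_counts > 0)).sum(axis=1)

    @property
    def bound_bleached(self) -> np.ndarray:
        """Occupied sites per frame whose dyes are all bleached."""
        return (self.bound & (self.dye_counts == 0)).sum(axis=1)

    @property
    def fluorescent_dyes(self) -> np.ndarray:
        """Total unbleached dyes on the DNA per frame."""
        return self.dye_counts.sum(axis=1, dtype=np.int64)

    @property
    def visible_fluorescent_dyes(self) -> np.ndarray:
        """Unbleached dyes on TIRF-visible sites per frame (what the camera sees)."""
        return self.dye_counts[:, self.visible].sum(axis=1, dtype=np.int64)

    def to_trace(self, brightness: float = 100.0, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 molecule_id: str = "") -> IntensityTrace:
        """Integrated-intensity trace: visible unbleached dyes x counts-per-dye (+ noise)."""
        values = self.visible_fluorescent_dyes.astype(float) * brightness
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        return IntensityTrace(times=self.times.copy(), values=values,
                              frame_rate=self.frame_rate, molecule_id=molecule_id)


def _n_substeps(max_rate: float, dt: float) -> int:
    if max_rate <= 0:
        return 1
    return max(1, math.ceil(max_rate * dt / MAX_STEP_PROBABILITY))


def simulate_binding(truth: SimulationTruth, schedule: SwitchingSchedule,
                     duration: float, *,
                     initial_occupancy: float | str = 0.0,
                     frap_pulse: tuple[float, float] | None = None,
                     koff_override: float | None = None,
                     rng: np.random.Generator | None = None) -> OccupancyTrajectory:
    """Simulate site occupancy under a time-varying concentration.

    Parameters
    ----------
    truth
        Kinetic/optical ground truth.  ``truth.seed`` seeds the simulation
        unless an explicit ``rng`` is given; the same seed and configuration
        reproduce the trajectory bit for bit.
    schedule
        Concentration protocol c(t).
    duration
        Total simulated time (s); frames are recorded at ``truth.frame_rate``
        starting at t = 0.
    initial_occupancy
        Starting bound fraction: a number in [0, 1], or ``"equilibrium"``
        for the Langmuir occupancy at the schedule's initial concentration.
        Initially bound dimers carry a full dye complement.
    frap_pulse
        Optional ``(t_start, t_end)`` window during which dyes bleach at
        ``truth.k_bleach_pulse`` instead of ``truth.k_bleach``.
    koff_override
        Replace the model koff (used by the crosslinked control, koff = 0).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frap_pulse is not None:
        t0, t1 = frap_pulse
        if not (0 <= t0 < t1 <= duration):
            raise ValueError("frap_pulse window must lie within [0, duration]")
    if rng is None:
        rng = np.random.default_rng(truth.seed)

    kon = truth.model.kon
    koff = truth.model.koff if koff_override is None else koff_override
    n = truth.n_sites
    dt = 1.0 / truth.frame_rate
    n_frames = int(math.floor(duration * truth.frame_rate)) + 1
    times = np.arange(n_frames) / truth.frame_rate

    c0 = concentration_profile(schedule, 0.0)
    if initial_occupancy == "equilibrium":
        p0 = truth.model.occupancy(c0)
    else:
        p0 = float(initial_occupancy)
        if not 0 <= p0 <= 1:
            raise ValueError("initial_occupancy must be in [0, 1]")

    bound = rng.random(n) < p0
    dyes = np.where(bound, truth.dyes_per_dimer, 0).astype(np.int64)

    bound_rec = np.empty((n_frames, n), dtype=bool)
    dyes_rec = np.empty((n_frames, n), dtype=np.uint8)
    bound_rec[0] = bound
    dyes_rec[0] = dyes

    # visible sites: the contiguous run away from the bead end
    n_vis = max(1, int(round(truth.visible_fraction * n)))
    visible = np.zeros(n, dtype=bool)
    visible[:n_vis] = True

    for i in range(1, n_frames):
        t_left = times[i - 1]
        c = concentration_profile(schedule, t_left)
        kb = truth.k_bleach
        if frap_pulse is not None and frap_pulse[0] <= t_left < frap_pulse[1]:
            kb = truth.k_bleach_pulse
        max_rate = max(kon * c, koff, kb)
        m = _n_substeps(max_rate, dt)
        dts = dt / m
        p_on = -np.expm1(-kon * c * dts)
        p_off = -np.expm1(-koff * dts)
        p_bleach = -np.expm1(-kb * dts)
        for _ in range(m):
            u = rng.random(n)
            unbind = bound & (u < p_off)
            bind = ~bound & (u < p_on)
            if p_bleach > 0:
                has_dye = dyes > 0
                if has_dye.any():
                    dyes[has_dye] -= rng.binomial(dyes[has_dye], p_bleach)
            bound ^= unbind | bind
            dyes[unbind] = 0
            dyes[bind] = truth.dyes_per_dimer
        bound_rec[i] = bound
        dyes_rec[i] = dyes

    return OccupancyTrajectory(times=times, bound=bound_rec, dye_counts=dyes_rec,
                               visible=visible, frame_rate=truth.frame_rate)


def run_protocol(truth: SimulationTruth, protocol: str, *,
                 schedule: SwitchingSchedule | None = None,
                 concentration: float | None = None,
                 duration: float | None = None,
                 n_cycles: int = 2,
                 period: float = 60.0,
                 exchange_time: float | None = None,
                 pulse: tuple[float, float] | None = None,
                 brightness: float = 100.0,
                 noise_sd: float = 0.0,
                 molecule_id: str = "",
                 rng: np.random.Generator | None = None,
                 ) -> tuple[OccupancyTrajectory, IntensityTrace]:
    """Run one of the standard measurement protocols and return trajectory + trace.

    Protocols
    ---------
    ``"switching"``
        Square-wave alternation between protein at ``concentration`` and
        buffer, ``n_cycles`` cycles of length ``period`` (needs either
        ``schedule`` or ``concentration``).
    ``"wash"``
        Start at the Langmuir equilibrium for ``concentration``, then flow
        buffer (c = 0) from t = 0; pure dissociation plus bleaching.
    ``"frap"``
        Constant ``concentration`` starting at equilibrium; a high-power
        ``pulse = (t0, t1)`` bleaches at ``truth.k_bleach_pulse``.
    ``"crosslinked"``
        Formaldehyde-crosslinked control: koff forced to 0, no free protein,
        all sites initially bound — intensity decay is photobleaching only.

    The trace is ``visible unbleached dyes x brightness`` with optional
    Gaussian camera noise of standard deviation ``noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    tau = exchange_time if exchange_time is not None else 6.5

    if protocol == "switching":
        if schedule is None:
            if concentration is None:
                raise ValueError("switching protocol needs a schedule or a concentration")
            schedule = SwitchingSchedule.square_wave(concentration, period=period,
                                                     exchange_time=tau)
        if duration is None:
            if schedule.period is None:
                raise ValueError("switching protocol needs a repeating schedule or a duration")
            duration = n_cycles * schedule.period
        traj = simulate_binding(truth, schedule, duration, rng=rng)
    elif protocol == "wash":
        if concentration is None:
            raise ValueError("wash protocol needs the pre-wash concentration")
        if duration is None:
            duration = 40.0
        # pre-equilibrated at `concentration`, buffer from t=0
        wash_sched = SwitchingSchedule.constant(0.0, exchange_time=tau)
        traj = simulate_binding(truth, wash_sched, duration,
                                initial_occupancy=truth.model.occupancy(concentration),
                                rng=rng)
    elif protocol == "frap":
        if concentration is None or pulse is None:
            raise ValueError("frap protocol needs a concentration and a pulse window")
        if duration is None:
            duration = pulse[1] + 1200 / truth.frame_rate  # recovery for 1200 frames
        if not (0 <= pulse[0] < pulse[1] <= duration):
            raise ValueError("frap pulse must lie within the recording")
        sched = SwitchingSchedule.constant(concentration, exchange_time=tau)
        traj = simulate_binding(truth, sched, duration,
                                initial_occupancy="equilibrium",
                                frap_pulse=pulse, rng=rng)
    elif protocol == "crosslinked":
        if duration is None:
            duration = 120.0
        sched = SwitchingSchedule.constant(0.0, exchange_time=tau)
        traj = simulate_binding(truth, sched, duration, initial_occupancy=1.0,
                                koff_override=0.0, rng=rng)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    trace = traj.to_trace(brightness=brightness, noise_sd=noise_sd, rng=rng,
                          molecule_id=molecule_id)
    return traj, trace


# ----------------------------------------------------------------------
# condensation / competition assay generator

DEFAULT_REDUCTION_DISTS = {
    # uniform (low, high) ranges of fractional extension reduction per class
    "condensed": (0.92, 1.00),
    "partial": (0.15, 0.85),
    "not_condensed": (0.00, 0.08),
}


def simulate_condensation_assay(n_molecules: int,
                                condensation_probability: float,
                                *,
                                partial_probability: float = 0.0,
                                reduction_dists: dict[str, tuple[float, float]] | None = None,
                                competition_factor: float = 1.0,
                                n_cycles: int = 4,
                                base_intensity_range: tuple[float, float] = (5000.0, 15000.0),
                                noise_cv: float = 0.05,
                                condition: str = "",
                                rng: np.random.Generator | None = None,
                                seed: int | None = None):
    """Generate per-molecule condensation outcomes and paired cycle intensities.

    Each molecule condenses with ``condensation_probability``, is partially
    condensed with ``partial_probability``, and otherwise does not
    condense; its extension reduction is drawn uniformly from the range
    for its class (point masses allowed as ``(x, x)``).  Condensation
    dynamics are not modelled mechanistically — the draw is the outcome
    the downstream classifier consumes.

    For the competition pairing, each molecule gets a baseline integrated
    intensity (uniform in ``base_intensity_range``, emulating the
    molecule-to-molecule spread in the imaged DNA fraction) and ``n_cycles``
    paired intensities: condition A at the baseline, condition B scaled by
    ``competition_factor`` (the fraction of labelled occupancy retained
    with the competitor present), both with multiplicative Gaussian noise
    of coefficient of variation ``noise_cv``.
    """
    from .condense import MoleculeRecord  # local import avoids a module cycle

    if not 0 <= condensation_probability <= 1:
        raise ValueError("condensation_probability must be in [0, 1]")
    if not 0 <= partial_probability <= 1 - condensation_probability:
        raise ValueError("partial_probability must fit in the remaining probability")
    if competition_factor <= 0:
        raise ValueError("competition_factor must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    dists = dict(DEFAULT_REDUCTION_DISTS)
    if reduction_dists:
        dists.update(reduction_dists)

    records = []
    for i in range(n_molecules):
        u = rng.random()
        if u < condensation_probability:
            cls = "condensed"
        elif u < condensation_probability + partial_probability:
            cls = "partial"
        else:
            cls = "not_condensed"
        lo, hi = dists[cls]
        reduction = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        base = rng.uniform(*base_intensity_range)
        noise_a = 1.0 + noise_cv * rng.standard_normal(n_cycles)
        noise_b = 1.0 + noise_cv * rng.standard_normal(n_cycles)
        records.append(MoleculeRecord(
            molecule_id=f"mol{i:03d}",
            extension_reduction=reduction,
            condition=condition,
            intensities_a=base * noise_a,
            intensities_b=base * competition_factor * noise_b,
        ))
    return records
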