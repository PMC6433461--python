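import math
import warnings

import numpy as np
import pytest

from parbkin import (
    IntensityTrace,
    KineticModel,
    SimulationTruth,
    SwitchingSchedule,
    run_protocol,
)
from parbkin.kinetics import (
    KineticFit,
    PhaseWindow,
    aggregate_condition,
    estimate_kon,
    fit_association,
    fit_bleach_halflife,
    fit_dissociation,
    fit_frap_recovery,
    fit_phase,
    half_life,
    segment_cycles,
)

from oracles import frap_recovery_ode

FRAME_RATE = 9.52


def make_trace(values, frame_rate=FRAME_RATE):
    t = np.arange(len(values)) / frame_rate
    return IntensityTrace(t, np.asarray(values, float), frame_rate)


def model_trace(kind, rate, amplitude=1000.0, duration=30.0, frame_rate=FRAME_RATE):
    t = np.arange(0, duration, 1 / frame_rate)
    if kind == "dissociation":
        v = amplitude * np.exp(-rate * t)
    else:
        v = amplitude * (1 - np.exp(-rate * t))
    return IntensityTrace(t, v, frame_rate)


class TestSegmentCycles:
    def test_two_cycles_give_four_windows(self, square_schedule):
        trace = make_trace(np.zeros(int(120 * FRAME_RATE)))
        wins = segment_cycles(trace, square_schedule, dead_time=6.5)
        kinds = [w.kind for w in wins]
        assert kinds == ["association", "dissociation"] * 2

    def test_dead_time_offsets_window_starts(self, square_schedule):
        trace = make_trace(np.zeros(int(120 * FRAME_RATE)))
        wins = segment_cycles(trace, square_schedule, dead_time=6.5)
        starts = [w.start for w in wins]
        assert starts == pytest.approx([6.5, 36.5, 66.5, 96.5])

    def test_excessive_dead_time_drops_all_windows(self, square_schedule):
        trace = make_trace(np.zeros(int(120 * FRAME_RATE)))
        with pytest.warns(UserWarning):
            wins = segment_cycles(trace, square_schedule, dead_time=30.0)
        assert wins == []


class TestExactRecovery:
    """Noiseless model traces must be recovered to at least 6 significant figures."""

    @pytest.mark.parametrize("rate", [0.05, 0.1, 0.3])
    def test_dissociation_rate_recovery(self, rate):
        fit = fit_dissociation(model_trace("dissociation", rate))
        assert fit.rate == pytest.approx(rate, rel=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)

    @pytest.mark.parametrize("rate", [0.1, 0.2, 0.5])
    def test_association_rate_recovery(self, rate):
        fit = fit_association(model_trace("association", rate))
        assert fit.rate == pytest.approx(rate, rel=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)

    def test_constant_trace_gives_zero_koff(self):
        fit = fit_dissociation(make_trace(np.full(100, 800.0)))
        assert fit.rate == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dissociation(make_trace([5.0, 4.0]))


class TestSimulatedRecovery:
    def test_wash_koff_recovery(self):
        """Mean fitted koff over 20 simulated wash molecules within 10% of truth."""
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1), n_sites=200,
                                k_bleach=0.0, seed=31)
        rng = np.random.default_rng(31)
        fits = []
        for i in range(20):
            _, trace = run_protocol(truth, "wash", concentration=250e-9,
                                    duration=40.0, rng=rng, molecule_id=f"m{i}")
            fits.append(fit_dissociation(trace))
        summary = aggregate_condition(fits, "wash")
        assert summary.mean_rate == pytest.approx(0.1, rel=0.10)

    def test_association_kobs_instantaneous_exchange(self):
        """kobs ~= kon*c + koff = 0.15 s^-1 at 125 nM with instantaneous exchange."""
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1), n_sites=200,
                                k_bleach=0.0, seed=32)
        rng = np.random.default_rng(32)
        sched = SwitchingSchedule.square_wave(125e-9, period=60.0, exchange_time=1e-3)
        rates = []
        for i in range(15):
            _, trace = run_protocol(truth, "switching", schedule=sched,
                                    n_cycles=1, rng=rng)
            wins = segment_cycles(trace, sched, dead_time=0.0)
            rates.extend(fit_phase(trace, w).rate for w in wins
                         if w.kind == "association")
        assert np.mean(rates) == pytest.approx(0.15, rel=0.10)

    def test_finite_exchange_biases_kobs_down(self):
        """At high concentration the 6.5 s exchange saturates the observed rate.

        Buffer-first schedule so the association phase follows a real
        boundary shift; fits include the exchange interval (dead time 0).
        """
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1), n_sites=300,
                                k_bleach=0.0, seed=33)
        rng = np.random.default_rng(33)
        sched = SwitchingSchedule(segments=((0.0, 0.0), (30.0, 2e-6)),
                                  period=60.0, exchange_time=6.5)
        rates = []
        for i in range(10):
            _, trace = run_protocol(truth, "switching", schedule=sched,
                                    n_cycles=2, rng=rng)
            wins = segment_cycles(trace, sched, dead_time=0.0)
            rates.extend(fit_phase(trace, w).rate for w in wins
                         if w.kind == "association")
        assert np.mean(rates) < 0.5 * truth.model.kobs(2e-6)


class TestEstimateKon:
    def test_two_point_line(self):
        est = estimate_kon([(125e-9, 0.15), (250e-9, 0.20)], n_low=2)
        assert est.kon == pytest.approx(4.0e5)
        assert est.koff_intercept == pytest.approx(0.10)

    def test_exact_line_any_n_low(self):
        pts = [(c, 3e5 * c + 0.07) for c in (1e-7, 2e-7, 5e-7, 1e-6)]
        for n_low in (2, 3, 4):
            est = estimate_kon(pts, n_low=n_low)
            assert est.kon == pytest.approx(3e5, rel=1e-9)
            assert est.koff_intercept == pytest.approx(0.07, rel=1e-9)

    def test_uses_lowest_concentrations(self):
        # saturation at high c must not affect the low-c fit
        pts = [(125e-9, 0.15), (250e-9, 0.20), (2e-6, 0.35)]
        est = estimate_kon(pts, n_low=2)
        assert est.kon == pytest.approx(4.0e5)

    def test_n_low_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_kon([(1e-7, 0.1)], n_low=2)


class TestHalfLife:
    def test_published_off_rate_maps_to_nine_seconds(self):
        assert half_life(0.08) == pytest.approx(8.66, abs=0.01)
        assert round(half_life(0.08)) == 9

    def test_ln2_rate_gives_one_second(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)

    def test_bleach_rate_maps_to_28_seconds(self):
        assert half_life(0.0248) == pytest.approx(28.0, abs=0.1)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestBleachFit:
    def test_noiseless_recovery(self):
        fit = fit_bleach_halflife(model_trace("dissociation", 0.0248, duration=90.0))
        assert fit.half_life_s == pytest.approx(math.log(2) / 0.0248, rel=1e-6)

    def test_simulated_crosslinked_halflife(self):
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1), n_sites=200,
                                k_bleach=math.log(2) / 28, seed=34)
        rng = np.random.default_rng(34)
        halves = []
        for i in range(20):
            _, trace = run_protocol(truth, "crosslinked", duration=90.0, rng=rng)
            halves.append(fit_bleach_halflife(trace).half_life_s)
        assert np.mean(halves) == pytest.approx(28.0, rel=0.10)

    def test_zero_bleach_flagged_infinite(self):
        fit = fit_bleach_halflife(make_trace(np.full(60, 900.0)))
        assert math.isinf(fit.half_life_s)
        assert fit.flag == "no_decay"


class TestFrap:
    def test_noiseless_recovery_rate(self):
        fit = fit_frap_recovery(model_trace("association", 0.15),
                                pre_pulse_plateau=1000.0)
        assert fit.rate == pytest.approx(0.15, rel=1e-6)
        assert fit.recovery_fraction == pytest.approx(1.0, rel=1e-6)

    def test_simulated_recovery_rate_is_koff_limited(self):
        """Recovery of fluorescent occupancy proceeds at koff: bleached
        molecules still occupy sites and gate rebinding (three-state ODE)."""
        kon, koff, c = 4e5, 0.1, 250e-9
        truth = SimulationTruth(model=KineticModel(kon=kon, koff=koff),
                                n_sites=3000, k_bleach=0.0, k_bleach_pulse=400.0,
                                seed=35)
        pulse = (2.0, 2.5)
        _, trace = run_protocol(truth, "frap", concentration=c, pulse=pulse,
                                duration=60.0)
        pre = float(trace.values[trace.times < pulse[0]].mean())
        recovery = trace.crop(pulse[1], 60.0)
        recovery = IntensityTrace(recovery.times - recovery.times[0],
                                  recovery.values, trace.frame_rate)
        fit = fit_frap_recovery(recovery, pre_pulse_plateau=pre)
        # cross-check the expected rate with the numeric ODE oracle
        t = np.linspace(0, 57, 200)
        f_ode = frap_recovery_ode(kon, koff, c, t)
        ode_fit = fit_association(IntensityTrace(
            np.arange(0, 57, 1 / FRAME_RATE),
            np.interp(np.arange(0, 57, 1 / FRAME_RATE), t, f_ode), FRAME_RATE))
        assert ode_fit.rate == pytest.approx(koff, rel=0.02)
        assert fit.rate == pytest.approx(koff, rel=0.15)
        assert fit.recovery_fraction == pytest.approx(1.0, abs=0.10)

    def test_recovery_fraction_near_one_when_bleach_slow(self):
        """k_bleach << koff: exchange replaces bleached protein, full recovery."""
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.2),
                                n_sites=2000, k_bleach=0.002, k_bleach_pulse=400.0,
                                seed=36)
        pulse = (2.0, 2.5)
        _, trace = run_protocol(truth, "frap", concentration=250e-9, pulse=pulse,
                                duration=45.0)
        pre = float(trace.values[trace.times < pulse[0]].mean())
        post_plateau = float(trace.values[trace.times > 35.0].mean())
        assert post_plateau / pre == pytest.approx(1.0, abs=0.10)


class TestAggregation:
    def test_single_fit(self):
        f = KineticFit(rate=0.1, amplitude=1.0, stderr=0.0, rss=0.0, n_points=10,
                       kind="dissociation")
        s = aggregate_condition([f], "x")
        assert s.mean_rate == 0.1 and s.sd_rate == 0.0 and s.n_molecules == 1

    def test_mean_and_sd(self):
        fits = [KineticFit(rate=r, amplitude=1.0, stderr=0.0, rss=0.0,
                           n_points=10, kind="dissociation")
                for r in (0.08, 0.10, 0.12)]
        s = aggregate_condition(fits, "x")
        assert s.mean_rate == pytest.approx(0.10)
        assert s.sd_rate == pytest.approx(0.02)

    def test_flagged_fits_excluded(self):
        good = KineticFit(rate=0.1, amplitude=1.0, stderr=0.0, rss=0.0,
                          n_points=10, kind="dissociation")
        bad = KineticFit(rate=math.nan, amplitude=math.nan, stderr=math.nan,
                         rss=math.nan, n_points=10, kind="dissociation", ok=False)
        s = aggregate_condition([good, bad], "x")
        assert s.n_molecules == 1

    def test_all_flagged_rejected(self):
        bad = KineticFit(rate=math.nan, amplitude=math.nan, stderr=math.nan,
                         rss=math.nan, n_points=10, kind="dissociation", ok=False)
        with pytest.raises(ValueError):
            aggregate_condition([bad], "x")

    def test_clt_consistency_on_simulated_molecules(self):
        """Mean koff over 30 molecules within 3 SD/sqrt(30) of the truth."""
        truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1), n_sites=200,
                                k_bleach=0.0, seed=37)
        rng = np.random.default_rng(37)
        fits = []
        for i in range(30):
            _, trace = run_protocol(truth, "wash", concentration=250e-9,
                                    duration=40.0, rng=rng, molecule_id=f"m{i}")
            fits.append(fit_dissociation(trace))
        s = aggregate_condition(fits, "koff")
        tol = 3 * s.sd_rate / math.sqrt(s.n_molecules)
        assert abs(s.mean_rate - 0.1) <= tol + 0.002
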