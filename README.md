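# parbkin

Binding and unbinding kinetics of a DNA-binding protein measured by
combined magnetic-tweezers / TIRF microscopy with fast laminar buffer
exchange — as a fully synthetic, testable pipeline.

The package is aimed at single-molecule biophysicists analysing
flow-exchange fluorescence recordings of proteins (here: the bacterial
partition protein ParB) binding non-specifically to a stretched DNA. It
provides:

* **`parbkin.simulate`** — a stochastic generator of such experiments:
  `n` independent binding sites exchanging with solution at rates
  `kon·c(t)` / `koff`, per-dye photobleaching, FRAP pulses, square-wave
  concentration schedules with a finite (~6.5 s) boundary-exchange ramp,
  and a condensation/competition assay generator;
* **`parbkin.render` / `parbkin.imagequant`** — TIRF-like image-stack
  rendering (Gaussian PSF, evanescent-field attenuation, Poisson + read
  noise) and the ROI quantification rules used on the real data (main ROI
  minus the mean of four equal-area background ROIs; kymographs);
* **`parbkin.kinetics`** — exponential fits
  `F(t) = Fmax(1 − e^(−kobs t))` and `F(t) = F0 e^(−koff t)`, with
  `kobs = kon[P] + koff`, phase segmentation with a dead time for the
  exchange interval, `kon` from the low-concentration slope of
  `kobs(c)`, bleach and FRAP fits, per-molecule-first aggregation;
* **`parbkin.fluidics`** — flow-cell physics: duct hydrodynamic radius
  `r = d·w/(d+w)`, Reynolds number `2rρv/η` with a laminar-flow check,
  force budget `F = √(F_mag² + F_drag²)`, boundary-exchange time from a
  tracer trace;
* **`parbkin.condense`** — condensation classification (>90% extension
  reduction = condensed, <10% = not condensed) and the through-origin
  paired-intensity competition slope;
* **`parbkin.report` / CLI** — an end-to-end pipeline with Student's
  t-test condition comparisons, tables, plots and a seeded, reproducible
  run log.

Because no experimental recordings are deposited, every stage is
validated by parameter recovery against the simulator's ground truth (see
`docs/methods.md` for the model, assumptions and caveats).

## Worked example

Simulate twenty molecules under a 60 s protein/buffer square wave at
250 nM, fit both phases of each cycle, and aggregate:

```python
import numpy as np
from parbkin import (KineticModel, SimulationTruth, SwitchingSchedule,
                     run_protocol)
from parbkin.kinetics import (aggregate_condition, fit_phase,
                              segment_cycles)

truth = SimulationTruth(model=KineticModel(kon=4e5, koff=0.1),
                        n_sites=200, k_bleach=0.0)
sched = SwitchingSchedule.square_wave(250e-9, period=60.0,
                                      exchange_time=1e-3)
rng = np.random.default_rng(7)

fits = {"association": [], "dissociation": []}
for i in range(20):
    _, trace = run_protocol(truth, "switching", schedule=sched,
                            n_cycles=1, molecule_id=f"m{i}", rng=rng)
    for w in segment_cycles(trace, sched, dead_time=0.0):
        fits[w.kind].append(fit_phase(trace, w))

for kind, fs in fits.items():
    s = aggregate_condition(fs, kind)
    print(f"{kind:13s} rate = {s.mean_rate:.3f} ± {s.sd_rate:.3f} s^-1 "
          f"(n = {s.n_molecules})")
```

Output:

```
association   rate = 0.211 ± 0.044 s^-1 (n = 20)
dissociation  rate = 0.103 ± 0.013 s^-1 (n = 20)
```

The association rate is the observed rate `kobs = kon·c + koff`
(4×10⁵ × 250×10⁻⁹ + 0.1 = 0.2 s⁻¹) and the dissociation rate recovers
`koff = 0.1 s⁻¹`; the spreads are the molecule-to-molecule SD expected
from fitting stochastic 200-site traces. The same chain works on real
trace CSVs (`time_s,intensity_counts`) via the `fit` CLI command, and on
image stacks via `quantify`.

Flow-cell numbers from the command line:

```bash
$ parbkin flowcalc radius --d 200um --w 3mm
{"radius_m": 0.00018749999999999998, "radius_um": 187.49999999999997}
$ parbkin flowcalc force --fmag 1pN --fdrag 3.36pN
{"F_magnetic_pN": 1.0, "F_drag_pN": 3.36, "F_total_pN": 3.505652578336878}
```

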