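# Methods

## The measurement being modelled

A single ~24 kbp DNA molecule is stretched sideways above a coverslip by a
magnetic bead while a fluorescently labelled DNA-binding protein (a
bacterial partition protein that binds DNA non-specifically and, at low
force, condenses it) is flowed over it. Total-internal-reflection (TIRF)
illumination excites only fluorophores near the surface, so the integrated
fluorescence of the DNA's region of interest is proportional to the number
of bound, unbleached dyes in the visible part of the molecule. A two-inlet
laminar flow cell alternates the solution between protein at concentration
c and plain buffer; each switch sweeps a reagent boundary across the
molecule in a finite exchange time (~6.5 s at the working flow rates).
Association phases give the observed rate k_obs, dissociation phases give
k_off, and the low-concentration slope of k_obs(c) gives k_on.

## Kinetic model

Binding is pseudo-first-order two-state exchange on independent sites:

    DNA + P  <->  DNA:P        (k_on, M^-1 s^-1; k_off, s^-1)

With the free concentration held constant by the flow, the bound fraction
relaxes exponentially toward the Langmuir occupancy
b* = k_on c / (k_on c + k_off) at rate k_obs = k_on c + k_off, so

    association:   F(t) = F_max (1 - exp(-k_obs t))
    dissociation:  F(t) = F_0 exp(-k_off t)

The model deliberately has no cooperativity or nucleation intermediates;
it is the semi-quantitative frame in which rates at different conditions
are compared. Consequences used throughout:

* k_off fitted from dissociation phases must not depend on c;
* k_obs is linear in c only while the binding time 1/k_obs is long
  compared with the boundary-exchange time — at high c the fitted rate is
  limited by fluid exchange and saturates (the package reproduces the
  direction of this bias, not a quantitative model of it);
* a half-life is ln 2 / rate (k_off = 0.08 s^-1 -> ~9 s occupancy
  half-time).

## The simulator

`simulate_binding` evolves `n_sites` independent sites by per-frame
Bernoulli steps with exact per-step probabilities 1 - exp(-r dt) and
automatic sub-stepping so no per-step probability exceeds 0.1. Defaults
are the study conditions: 9.52 Hz frame rate, 200 sites per molecule (the
non-specific footprint is not known; site count is a free parameter and
sites are explicitly independent), 4 dyes per bound dimer (~2 per
monomer), per-dye independent bleaching with a 28 s half-life at imaging
power, and a configurable TIRF-visible fraction modelling the part of the
tilted DNA near the bead that escapes the evanescent field. Bleached
molecules still occupy sites and still unbind — bleaching affects emission
only. Arriving molecules always carry a full dye complement (the solution
pool is unbleached). An event-driven sampler with exact exponential
waiting times is kept in the test suite as an independent oracle; the
discrete-time scheme agrees with it and with the Langmuir isotherm within
binomial sampling error.

Protocols: `switching` (square-wave alternation, default period 60 s with
a linear — optionally logistic — boundary ramp of 6.5 s), `wash`
(equilibrium then buffer), `frap` (a high-power pulse bleaches bound dyes,
recovery under constant c), and `crosslinked` (k_off pinned to 0, no free
protein: the decay is photobleaching alone, which is how the bleach rate
is calibrated).

A consequence of site-blocking bleached occupants worth stating: after a
full-field FRAP pulse at steady state, the *fluorescent* bound fraction
recovers as b*(1 - exp(-k_off t)) — rate-limited by k_off, because a
bleached occupant must leave before an unbleached one can bind — not at
k_on c + k_off, which would hold only if bleached molecules vacated
instantly. The test suite pins this against a numeric integration of the
three-state (empty/fluorescent/bleached) ODE.

`render_stack` turns a trajectory into a 16-bit TIFF-like stack: dyes at
their site positions along a pixel line, excitation attenuated
exponentially with distance along the (tilted) DNA, Gaussian PSF, Poisson
photon noise, multiplicative gain, Gaussian read noise and a constant
offset. The camera model has no EM excess-noise factor and no saturation;
it is sufficient for trace-level statistics, not for photon-counting.

The condensation assay generator draws per-molecule outcomes (condensed /
partial / not condensed) from stated probabilities and extension-reduction
ranges — condensation dynamics are not simulated mechanistically — plus
paired per-cycle intensities in which a competitor scales labelled
occupancy by a factor f. Per-molecule baseline intensities are uniform in
a configurable range, emulating the molecule-to-molecule spread in imaged
DNA fraction; cycle noise is multiplicative Gaussian with CV 0.05.

## Fitting choices

* Unweighted nonlinear least squares (`scipy.optimize.curve_fit`,
  parameter tolerance 1e-10, rate bounded at 0). Dissociation fits are
  initialised from a log-linear regression on the positive samples,
  association fits from the time to half-plateau. Noiseless model traces
  are recovered to better than 6 significant figures.
* Traces are segmented at the schedule's switch times; each window drops a
  dead time (default: the 6.5 s exchange time) at its start. Excluding
  the exchange interval is a choice — it can be set to 0 to include the
  ramp, which reproduces the saturation of k_obs at high c.
* Amplitudes are free; no baseline offset by default (traces are
  background-corrected; an offset can be enabled by correcting traces
  beforehand).
* Aggregation is per-molecule-first: each molecule's phases are fitted
  individually, rates are averaged across molecules, and the spread is the
  sample SD. Non-converged fits are flagged and excluded.
* k_on comes from an ordinary least-squares line through the lowest-
  concentration (c, mean k_obs) points (default: the two lowest), where
  exchange does not yet limit the observed rate.
* No photobleaching correction is applied by default: under fast exchange
  bound dyes are replaced from solution much faster than they bleach. An
  optional exponential correction (`correct_bleaching`) with a fitted
  bleach rate is provided; note a dissociation trace decays at
  k_off + k_bleach, so when k_off is comparable to k_bleach the
  uncorrected fit overestimates k_off (~25% at k_off = 0.1 s^-1 with the
  28 s bleach half-life). Parameter-recovery validations therefore run
  with bleaching disabled so they measure estimator error, not the
  photophysical confound; the bleach path is validated separately through
  the crosslinked control.

## Image quantification

Pixel coordinates are 0-based with half-open rectangles. A main ROI
around the DNA is summed per frame; exactly four background ROIs of
identical area (unequal areas are rejected — the correction subtracts raw
counts) are placed around it, preferring above/below/left/right and
falling back to second tiers above/below for full-width DNA ROIs. The
corrected trace is main minus the mean of the four. Kymographs sum a
transverse band along an axis-aligned DNA line; their full-width column
sums equal the covering-rectangle ROI integral exactly (integer counts).

## Flow-cell physics

SI units internally; the CLI accepts bench units. The hydrodynamic radius
of the rectangular duct is r = d w / (d + w) (187.5 µm for the 200 µm x
3 mm cell), the Reynolds number 2 r rho v / eta evaluates to ~0.4 in SI at
the maximum flow — far below the ~2000 turbulence threshold, which is the
operative claim — and the total force on the DNA is the orthogonal sum
sqrt(F_mag^2 + F_drag^2) (1 pN and 3.36 pN give 3.5 pN). Drag force at a
given flow rate comes from a user-supplied calibration table (linear
interpolation, no extrapolation). The boundary-exchange time of a tracer
trace is operationalised as the interval between the first samples at the
5% and 95% levels of the plateau-to-plateau swing (quantiles
configurable): an ideal step gives 0, an ideal ramp of duration T gives
0.9 T, and plateaus closer than 3x the plateau noise SD are rejected.

## Condensation and competition analysis

Extension-reduction thresholds are strict: > 0.9 condensed, < 0.1 not
condensed, boundaries partial. The competition slope is a through-origin
least-squares regression of condition-A on condition-B per-cycle
intensities pooled over molecules (each per-cycle intensity is the mean
over the final 10 s of its phase window); a no-effect control gives slope
1, a competitor retaining fraction f of labelled occupancy gives 1/f.
Between-condition comparisons use the equal-variance (Student's)
two-sample two-sided t-test with no multiple-testing correction; Welch's
test is available as an option.

## What the synthetic data does and does not show

The generator reproduces exponential exchange kinetics, finite boundary
exchange, photobleaching, FRAP, camera noise and partial visibility — so
green tests demonstrate that the estimators recover known rates under
realistic noise and protocol structure. It does not model cooperativity,
nucleation, local condensates (which the real protein shows at high
concentration and which depress apparent unbinding), surface sticking,
bead-attachment geometry, drift, or mechanistic condensation. Passing
tests therefore validate the analysis chain, not the biology; the
experimental condensation percentages and competition slopes enter the
generator as inputs, and the analysis demonstrates that the chain reports
them faithfully.

## Problem sizes and numerics

Validation runs use 200 sites/molecule and 15–30 molecules per condition
(the study's stated range), 30–60 s phases at 9.52 Hz, and 1000-site
ensembles for distribution-level checks. Per-molecule fitted rates have
~20% SD under these conditions — this is the real uncertainty of fitting
a stochastic 200-site trace, and it is why condition summaries are
means ± SD across molecules. Degenerate inputs (constant traces, windows
shorter than 3 frames, all-flagged fits, indistinguishable plateaus,
non-positive normalisation denominators) raise or flag rather than return
silently wrong numbers.
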