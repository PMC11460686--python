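# Methods

## The model

`cmcal` simulates a single human iPSC-derived cardiomyocyte with the
Kernik-formulation ionic model: 13 membrane currents (I_Na, I_f, I_CaL,
I_CaT, I_to, I_Kr, I_Ks, I_K1, I_NaK, I_NaCa, I_PCa and Na/Ca backgrounds),
a sarcoplasmic reticulum with SERCA uptake, passive leak and a Shannon-type
3-state ryanodine-receptor release channel operating on bulk cytosolic
calcium, and ten Tusscher-style instantaneous Ca buffering.  The state
vector has 22 entries (V, Ca_SR, Cai, Nai, Ki, 14 Hodgkin–Huxley gates, 3
RyR states).  Hodgkin–Huxley gates use the Kernik parameterization: rate
constants `a = a1·exp(V/a2)`, `b = a3·exp(V/a4)` with `a3 = a5·a1` and
`a4 = 1/(1/a2 + 1/a6)`.

Every maximal conductance or flux amplitude carries a dimensionless
multiplier; the all-ones multiplier set is the baseline cell.  Channel
block by fraction *b* multiplies the corresponding conductance by (1−b).
The baseline cell beats spontaneously at ≈0.55 Hz with a maximum diastolic
potential of ≈−75 mV, peak ≈+46 mV, APD90 ≈ 430 ms and a calcium transient
of ≈0.03–0.45 µM, and it follows pacing 1:1 from 1 to 2 Hz — the published
baseline behavior of this model family.  Because the published parameter
files could not be fetched in the build environment, the flux-side
magnitudes that were not known with confidence (RyR rate constants, SERCA
Vmax, cytosolic buffer capacity, G_CaT and G_K1 scale) were fixed once so
that the baseline cell reproduces those published behaviors, and were not
revisited.  The model should therefore be read as a faithful
reconstruction of the Kernik formulation rather than a verbatim parameter
copy; every quantitative claim in the test suite is made against the
behavioral anchors above, not against digit-level published outputs.

## Numerics

The workhorse integrator is a numba-compiled hybrid scheme: exact
exponential (Rush–Larsen) updates for the 14 gates *and* the 3 RyR states
(the RyR subsystem is linear given the concentrations, so a Gauss–Seidel
exponential update is unconditionally stable), forward Euler for V, the
four concentrations, with the step adapted to dV/dt (0.25 mV per step),
relative changes in Cai and Ca_SR (0.5% per step), capped at 1 ms and
floored at 0.5 µs.  Steps never cross a stimulus edge or an output sample;
dense output lands exactly on the requested grid.  A step budget
(average dt ≥ 0.02 ms over the run) converts pathological crawls into
flagged failures.  Integration failures (non-finite state, V outside
[−150, +100] mV) return a trace flagged `failed` — downstream code treats
these as sentinel-fitness candidates or as cessation of organized beating,
never as exceptions.

SciPy's LSODA (rtol 1e-6, per-state atol: 1e-8 concentrations, 1e-4 V,
1e-6 gates) runs the identical right-hand side as `method="lsoda"` and is
the accuracy reference: the two integrators agree on spontaneous rate and
APD90 to <2% in the cross-check test.  The stimulus is an additive inward
current density (default 60 pA/pF, 1 ms) whose first pulse starts at
t = period; its charge is carried on the K+ balance.

## Protocols and the fluorescence surrogate

A protocol is an ordered list of conditions (milieu, pacing, blocks,
duration); conditions run sequentially with full state carry-over, and the
trailing window (default 5 s, 0.1 ms grid) of each condition is recorded.
Min–max normalization of each segment to [0, 1] — per segment and per
signal, each acquisition treated as an independent recording — is the sole
fluorescence surrogate; there is no optical forward model.  The default
in-silico roster has 19 conditions in the families: buffer Ca 1.0/1.8/2.5
mM, pacing 1–2 Hz, I_CaL block 25/50%, mixed combinations, I_Kr/I_K1 block
(validation family), and the unperturbed baseline.  The optimized
calibration protocol is: (1) 1.0 mM Ca_o spontaneous, (2) 1.8 mM Ca_o
spontaneous, (3) 1.8 mM Ca_o with 1.25 Hz pacing and 25% I_CaL block.

## Synthetic populations

Population cells draw an independent log-normal multiplier per parameter
(median 1; spread = SD of log-multipliers, default 0.2 natural-log, log2
available).  Populations are filtered to spontaneous rates in [0.3, 1.0]
Hz (closed interval; non-beating and failed cells excluded) under the
unperturbed baseline, mirroring observed iPSC-CM automaticity.  The
generator's defaults are the study conditions; tests and the acceptance
script do not alter them.  What the synthetic data do *not* emulate: dye
dynamics and photobleaching beyond min-max scaling, optical blur, cell-to-
cell coupling in a tissue, and recording noise (except where tests add it
explicitly), so passing recovery tests demonstrate identifiability under
idealized recordings, not robustness to every experimental artifact.

## Calibration

Individuals are log2-multiplier vectors over the free parameters (default
all 16; search bounds ±3.32 ≈ 0.1–10x).  Fitness is the sum over segments
of the pointwise mean squared error between candidate and target V and Ca
series (equal weight), computed after establishing point correspondence.

Correspondence matters more than any other design choice here.  A single
whole-window shift (first-upstroke or cross-correlation alignment) makes
the error landscape nearly discontinuous in every rate-affecting
parameter: a 3% spontaneous-rate mismatch misaligns the second and third
beats of a 5-s window completely, so the global basin around the true
parameters is a needle that even an 8x-budget search misses.  The default
`per-beat` mode therefore aligns the k-th candidate beat to the k-th
target beat and compares over that beat's span, adding a relative
beat-count penalty; rate errors then degrade the score gradually while
waveform morphology keeps its full weight.  The single-shift modes and
`none` remain available in configuration.

The GA itself: truncation retention (the lowest-error half of the
population survives unchanged — best fitness is therefore non-increasing),
tournament parent selection among the retained, BLX-0.25 blend crossover,
per-gene Gaussian mutation in log2 space annealed geometrically from 0.5
to 0.03 over the run, and a log-normal initial population centred on the
baseline cell (SD 0.5 log2) — the population-of-models prior; log-uniform
initialization over the bounds is available.  Defaults: population 200,
20 generations, 10 independent runs per target.  Failed or non-beating
candidates receive a sentinel fitness of 10^6.  Fitness values are cached
by genome, so retained individuals cost nothing to re-score.

Scaled-down settings used in the test suite and acceptance script
(population 50, 10 generations, 60 s per-condition pre-equilibration, 4
free parameters) keep a full recovery experiment inside a few minutes on
one CPU; the 60 s equilibration leaves the first (hypocalcemic) segment of
the optimized protocol still quiescent after the solution switch, which is
reproduced identically in candidates and target and mainly reduces that
segment's information content.

## Evaluation

Calibration error is |log2(fitted/true)| per parameter; calibration spread
is the sample SD (ddof = 1) of log2(fitted/true) across repeated GA runs.
Prediction scoring reports beat-aligned trace MSE (same definition as the
fitness), the percent error of amplitude-normalized APD90 under a block,
and the percent error of the amplitude-normalized APD90 change between
baseline and block.

The I_Kr block tolerance threshold scans block levels ascending (default
1% steps), each level simulated independently from the cell's baseline
steady state with 5 min of pre-equilibration and classified on the
trailing window (default 30 s); the first level whose label differs from
`none` is the threshold, with a `tolerant` sentinel if none is found up to
100%.  An exhaustive mode evaluates every level as the brute-force check.

Arrhythmia labels (priority: cessation > afterdepolarization > alternans >
tachycardia > irregular > none) use package-chosen thresholds: cessation
(<2 beats or all amplitudes <10% of baseline), afterdepolarization (a
re-depolarization bump ≥5% of beat amplitude that rises and falls again
between a beat's peak and the next upstroke, armed only after 5% of
repolarization so the peak itself cannot trigger), alternans (≥4 beats of
alternating-sign APD90 differences each >5% of mean), tachycardia (rate >
max(2 Hz, 2x baseline)), irregular (inter-beat-interval CV > 0.2).  All
live in the `arrhythmia:` config block.  These rules are package choices,
not literature-fixed constants, and threshold results are reported with
their sensitivity to these settings.

Parameter sensitivity is ordinary least squares of z-scored outputs
(log-transformed when strictly positive) on z-scored log2 multipliers over
a simulated population (default 300 cells), one coefficient per parameter
per output, with top-4/bottom-4 groupings by |coefficient|.  OLS was
chosen over partial least squares because n >> p makes the coefficient
estimates essentially equivalent; the config exposes the choice.

## Recording preprocessing

Plate-imager channels (default 125 Hz) pass a fixed pipeline: (1) baseline
drift estimation by grayscale erosion — a moving minimum whose window
defaults to 1.5x the median beat interval, so it tracks drift but not the
transients — and subtraction; (2) 5-sample median filter; (3) linear
resampling onto the pipeline grid (0.1 ms, or the native rate via
`compare_grid: native`); (4) min–max normalization.  Window sizes are
package choices.  The in-vitro workflow pairs voltage- and calcium-dye
channels per condition, calibrates to all non-held-out conditions and
reports hold-out prediction errors for the ensemble.

## Known limitations

Single cells only (no tissue-level dynamics; "irregular" is the
single-cell surrogate for torsadogenic behavior); no temperature
dependence; no kinetic (time-constant) fitting; the model-parameter
reconstruction caveat above; per-beat correspondence discards absolute
phase information within a window (rate enters through beat counts and
the paced conditions); thresholds and windows in the arrhythmia classifier
are heuristic defaults, and downstream threshold values shift by a few
percent when they are varied (the acceptance script quantifies this).
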