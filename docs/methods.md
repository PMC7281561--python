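# Methods

This note documents the models, numerical choices and synthetic-data
calibrations behind seizurekit, and what the passing test suite does and
does not establish about real recordings.

## Evoked IPSC model and measurement

A synthetic evoked IPSC is rendered as

    I(t) = (1 − e^(−t/τ_rise)) · (A_fast e^(−t/τ_fast) + A_slow e^(−t/τ_slow)),  t ≥ 0

after each stimulus, with additive i.i.d. Gaussian baseline noise.
Choices and rationale:

* **Noise model.** I.i.d. Gaussian is the standard stand-in for
  voltage-clamp baseline noise and is sufficient for parameter-recovery
  testing. Real recordings carry 1/f and line components, stimulus
  artifacts and series-resistance filtering that the generator does not
  emulate; passing recovery tests therefore validates the estimators, not
  their robustness to every instrumental nuisance.
* **Rise phase.** Single-exponential onset with τ_rise = 2 ms. The decay
  analysis fits only the 10–90% decay segment, but with a finite rise the
  early segment is slightly contaminated; on the defaults this biases the
  fast component by ~1 point of percent block, well inside the tested
  tolerances. τ_rise = 0 gives an instantaneous rise and exact closed-form
  recovery.
* **Polarity.** GABAergic currents recorded at depolarized potentials are
  outward (positive) by default; a flag flips the convention for inward
  recordings, and all measurement routines normalize polarity first.
* **Units.** Currents pA, time constants ms, sampling 20 kHz for eIPSC
  sweeps (the acquisition rate of the emulated recordings).

Peak amplitude is read against the mean of the 10 ms preceding the
stimulus (short enough to be drift-safe; the emulated protocol does not
specify a window). Charge transfer integrates 0–750 ms post-stimulus by
the trapezoid rule. The 10–90% decay segment is located on a copy
smoothed with a 1 ms boxcar so that baseline noise cannot trigger the
crossings prematurely (an unsmoothed crossing on a noisy trace truncates
the segment near the 10% level and destabilizes τ_slow); the raw samples
are returned. Segment time is referenced to the stimulus so the fitted
amplitudes extrapolate to stimulus onset and are comparable across a
baseline/treated pair.

## Biexponential fitting

The model is label-symmetric, so after every fit components are relabeled
to the canonical order τ_fast < τ_slow. Initialization scans a log-spaced
grid of (τ_fast, τ_slow) pairs over 1–500 ms (12 values), solving the
amplitudes at each pair by non-negative linear least squares, and refines
the best grid point with bounded nonlinear least squares; this avoids the
local minima that plague free four-parameter exponential fits without
manual starting values. Unconstrained fits enforce A ≥ 0; fits whose time
constants differ by less than 1.5× are flagged ill-separated (a single
exponential describes such data equally well, and the split of mass
between components is arbitrary). Refinement failures fall back to the
grid solution with a converged-flag of False rather than raising.

The paired constrained protocol (unconstrained fits → arithmetic mean of
the pair's τ_fast and τ_slow → amplitude-only refit with τ fixed) uses a
sign-unconstrained linear refit so potentiation of a component is
expressible. Because the constrained refit is nested within the
unconstrained problem, its residual can never be smaller — asserted as an
invariant. Group summaries average per-cell percent blocks (mean ± SEM),
not ratios of group means.

## Drug presets and calibration

The paper-calibrated defaults are the study conditions, chosen once:

| parameter | value | basis |
|---|---|---|
| control decay | 300 pA/11 ms fast, 200 pA/86 ms slow | gives τ_w = 41 ms exactly, the control group mean |
| PTZ | 23% fast block, 63% slow block | the reported per-component blocks; implies 40% amplitude and 55% area block, matching the reported values |
| cefepime | 19% fast, 11.5% slow block | matches the reported 16% amplitude block and +4% τ_w |
| cefepime+PTZ | 35% fast, 55% slow block | matches the reported ~41% amplitude block and −15% τ_w |

Two reported numbers are not exactly co-satisfiable under pure
per-component amplitude scaling: the cefepime preset yields ~13–14% area
block where 16 ± 2% was reported (within its SEM), and a linear
superposition train with 37% of the slow component remaining cannot push
the normalized fifth peak below ~1.14, whereas 0.99 ± 0.06 was reported —
values below 1 require presynaptic depression, which is outside the
generator's scope. The tests assert the qualitative direction (summation
is reduced by slow-component block), which holds.

Trains are five stimuli at 10 Hz with linear superposition and one noise
realization; peaks are read per inter-stimulus window against the
pre-train baseline (the alternative trough-referenced convention is not
used; the emulated protocol does not specify one).

## Epileptiform events

The generator places Poisson-drawn counts of PIDs (positive Gaussian
transients; half-width is the FWHM) and SLEs (a positive Hann-windowed
GABAergic phase overlapping a negative glutamatergic phase over the event
duration) without overlap by rejection sampling, refusing rate
combinations that would occupy more than 80% of the sweep. Long traces
are generated and analyzed at 1 kHz: PID half-widths of tens of ms are
resolved to 1 ms while half-hour sweeps stay tractable.

The detector is deliberately plain — the emulated experiments report no
detection criteria, so every constant is a documented configuration
default rather than biology: 4th-order Butterworth low-pass at 50 Hz
(zero-phase), median baseline, MAD×1.4826 noise scale, threshold 4 robust
SDs, minimum duration 50 ms, merge gap 200 ms, SLE minimum duration 2 s.
A negative phase counts toward SLE classification only when it exceeds
both the threshold and 10% of the event's positive peak; without that
guard, the filter undershoot of a large PID (~1% of its amplitude)
masquerades as a glutamatergic phase. Noise-free traces have MAD = 0 and
require an explicit `noise_floor_pa`. Validation is against generator
ground truth, not against any recorded trace.

## MEST staircase

The ladder (12, 14, 17, 20, 23, 27, 32 mA; 0.07 log10 steps, stored as
the printed integers) steps down after extension, up after no extension;
steps past the ladder ends are clipped and flagged rather than erroring,
since real protocols simply repeat the boundary current. Imputation
propagates extension upward and non-extension downward, making the
probability curve monotone by construction; it is idempotent.

The Boltzmann fit weights each probability point by the number of animals
tested at that current (weighted least squares on the aggregated curve —
the form the emulated analysis used); an unweighted option and a
per-animal binomial likelihood option (`method="mle"`) exist behind
flags. Standard errors come from the fit covariance. At cohort sizes of
~11 the staircase sometimes realizes an all-steep curve whose fitted
slope collapses and whose EC50 SE is optimistic; EC50 point estimates
remain well-behaved (recovery within one ladder step in median at n = 24
over 500 seeds is asserted). Group comparison uses a normal reference on
the combined SE with Bonferroni correction — Welch degrees of freedom are
not defined for fit covariances, and the conclusions tested are robust to
this choice.

## Behavioral scoring

The average score is the mean over 30-s bins of the maximal score of any
episode overlapping each bin ([0,30), [30,60), …; touching a bin for any
positive duration counts, and an episode ending exactly on an edge does
not touch the next bin). Overlapping episodes merge to the maximum score
at construction. Total duration sums merged episodes. Status epilepticus
is a contiguous convulsive run strictly longer than 600 s; whether brief
pauses interrupt a run is unspecified in the emulated protocol, so a
`gap_tolerance` (default 0 s — strict contiguity) makes the choice
explicit and monotone. The behavioral cohorts the pipeline simulates
reproduce the study's group outcome counts (9 animals per group; 3 with
status epilepticus and 5 dead in control, none in either treatment
group), which drive the exact tests; treatment groups are pooled (n = 18)
against control for those tables, the reading under which the printed
p-values reproduce.

## Exact statistics

The two-sided Fisher test uses the point-probability rule (sum of all
tables with the observed margins whose probability does not exceed the
observed table's). For grand totals up to 2000 the hypergeometric weights
are exact rationals (`fractions.Fraction`) compared exactly and converted
to float once, giving bit-identical results across platforms; larger
tables fall back to log-gamma evaluation with a small relative tolerance
against roundoff ties. Percent change is 100·(after − before)/before,
with rounding left to the report layer.

## Problem sizes and limitations

The default test/acceptance runs use 10 cells per drug condition (10
averaged sweeps per condition per cell, 2% baseline noise), 7 train
cells, 5 slices per epiform condition at 1800 s, staircase cohorts of 11
animals (500-seed recovery checks use n = 24), and 9-animal behavioral
groups — the sizes of the emulated study arms. Known limitations: no
stimulus-artifact or series-resistance modeling, no spontaneous miniature
events, no presynaptic plasticity in trains, no EEG or video analysis,
and the detector is validated only against the generator's event shapes.
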