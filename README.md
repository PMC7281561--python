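# seizurekit

Analysis toolkit for seizure-pharmacology experiments built around GABAergic
inhibition: evoked-IPSC decay kinetics and drug-block estimation, temporal
summation of 10 Hz stimulus trains, up-and-down staircase estimation of the
maximal electroshock seizure threshold (MEST), detection of epileptiform
events (preictal discharges and seizure-like events) in long voltage-clamp
sweeps, Racine-scale behavioral scoring of chemoconvulsant (PTZ) tests, and
the exact statistics that tie the endpoints together. Every analysis ships
with a seeded synthetic-data generator carrying known ground truth, so the
whole pipeline is testable end to end without recordings.

It is written for cellular electrophysiologists and pharmacologists who need
a reproducible, scriptable version of the measurements usually done by hand
in acquisition software.

## Models and statistics

**IPSC decay decomposition.** The 10–90% decay phase of an evoked inhibitory
postsynaptic current is fitted with a biexponential

```
I(t) = A_fast · exp(-t/τ_fast) + A_slow · exp(-t/τ_slow)
```

(grid-seeded nonlinear least squares, canonical ordering τ_fast < τ_slow).
The amplitude-weighted decay constant is
τ_w = (τ_fast·A_fast + τ_slow·A_slow)/(A_fast + A_slow). Drug block of any
quantity A is `Block = 100% · (A_baseline − A_treated)/A_baseline`; negative
values mean potentiation. Per-component block uses a paired constrained
protocol: both decays are fitted unconstrained, the pair's time constants
are averaged, and both decays are refitted amplitude-only with τ fixed to
those averages, so amplitudes are compared on a common kinetic basis.

**MEST staircase.** The stimulation current steps one ladder rung down after
tonic hind-limb extension and one rung up after its absence (default ladder
12–32 mA, equal 0.07 steps in log10). Monotonicity imputes each animal's
outcome across the rest of the ladder; the per-current extension probability
is fitted with the Boltzmann sigmoid

```
P(I) = 1 / (1 + exp((EC50 − I)/Slope))
```

by animal-weighted least squares, and group EC50s are compared with a
normal-reference test on the fitted standard errors, Bonferroni corrected.

**Event detection.** A low-pass-filtered sweep is thresholded at k·MAD
(robust noise units) around the median baseline; merged excursions are
classified as seizure-like events when long enough (≥ 2 s) or when they
carry a supra-threshold negative (glutamatergic) phase, and as preictal
discharges otherwise. Frequencies are reported in mHz, PID width as the
half-amplitude width.

**Behavior.** Episodes scored 1–4 on a modified Racine scale yield latency,
total convulsion time, the average of per-30-s-bin maximal scores over a
30-min window, and a status-epilepticus flag for continuous convulsive runs
longer than 10 min. Group outcome tables are compared with a two-sided
Fisher exact test (point-probability rule, exact rational arithmetic).

## Worked example

```python
import seizurekit as sk

# synthetic control cell and a PTZ-like treatment blocking the slow component
spec = sk.SweepSpec(decay=sk.CONTROL_DECAY, baseline_noise_sd=10.0)
baseline = sk.gen_eipsc(spec, seed=1)
treated_decay = sk.apply_drug(sk.CONTROL_DECAY, sk.PTZ_EFFECT)
treated = sk.gen_eipsc(sk.SweepSpec(decay=treated_decay, baseline_noise_sd=10.0), seed=2)

m = sk.measure_eipsc(baseline)
print(round(m.peak_amplitude), round(m.tau_weighted, 1))
# 359 41.6   <- observed peak (finite 2 ms rise), weighted decay ~41 ms

pair = sk.constrained_pair_fit(sk.extract_decay_segment(baseline),
                               sk.extract_decay_segment(treated))
fast, slow = sk.component_block(pair)
print(round(fast, 1), round(slow, 1))
# 21.3 62.6  <- the slow GABAa component is blocked far more than the fast one

print(round(sk.fisher_exact_two_sided(5, 4, 0, 18), 4))
# 0.0016     <- mortality contingency, two-sided exact test
```

The numbers above are what the code prints for those seeds: the constrained
pair fit recovers the generator's 23%/63% per-component block to within the
noise, and the exact test on a 5/9 vs 0/18 mortality table gives p ≈ 0.002.

A full synthetic study (all arms, tidy CSV + JSON artifacts) runs with

```
seizurekit demo --seed 1 --outdir run1
```

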