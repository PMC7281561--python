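"""Seeded generators for every synthetic input the analysis pipeline consumes.

All generators are pure functions of ``(spec, seed)``: the same arguments
always produce bitwise-identical output.  A single seed is expanded into
independent substreams (noise, event counts, event placement, Bernoulli
outcomes) via :class:`numpy.random.SeedSequence` so that adding one draw
does not perturb the others.

The default kinetic and pharmacological parameters are calibrated to the
group means reported for GABAergic eIPSCs in rat entorhinal cortex: the
control decay (300 pA / 11 ms fast, 200 pA / 86 ms slow) has a weighted
time constant of exactly 41 ms, and the drug presets reproduce the
printed per-component block profiles (PTZ 23% fast / 63% slow; cefepime
a weak block sparing the slow component).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DecayComponents,
    DrugEffect,
    EpiformSpec,
    ScoreSeries,
    StaircaseTable,
    Sweep,
    SweepSpec,
)

__all__ = [
    "CONTROL_DECAY",
    "PTZ_EFFECT",
    "CFP_EFFECT",
    "CFP_PTZ_EFFECT",
    "MEST_LADDER_MA",
    "gen_eipsc",
    "gen_train",
    "apply_drug",
    "gen_epiform_trace",
    "gen_staircase_cohort",
    "gen_score_series",
]

#: Control eIPSC decay; weighted tau = (11*300 + 86*200)/500 = 41 ms.
CONTROL_DECAY = DecayComponents(a_fast=300.0, tau_fast=11.0, a_slow=200.0, tau_slow=86.0)

#: PTZ (400 uM): blocks the slow component more than the fast one.
PTZ_EFFECT = DrugEffect(fast_block_frac=0.23, slow_block_frac=0.63)

#: Cefepime (100 uM): weak block sparing the slow component (decay slows slightly).
CFP_EFFECT = DrugEffect(fast_block_frac=0.19, slow_block_frac=0.115)

#: Cefepime + PTZ: PTZ-like total block but a much weaker slow-component block.
CFP_PTZ_EFFECT = DrugEffect(fast_block_frac=0.35, slow_block_frac=0.55)

#: Staircase current ladder in mA, equally spaced by 0.07 in log10.
MEST_LADDER_MA: Tuple[float, ...] = (12.0, 14.0, 17.0, 20.0, 23.0, 27.0, 32.0)


def _substream(seed: int, key: int) -> np.random.Generator:
    """Independent generator substream ``key`` derived from a global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _render_waveform(
    times_s: np.ndarray,
    stimulus_times: Sequence[float],
    decay: DecayComponents,
    rise_tau_ms: float,
) -> np.ndarray:
    """Noise-free superposition of one evoked response per stimulus."""
    y = np.zeros_like(times_s)
    for t0 in stimulus_times:
        t_ms = (times_s - t0) * 1000.0
        # tolerance so a sample nominally coincident with the stimulus is not
        # dropped by float roundoff in t0 + k*isi
        mask = t_ms >= -1e-6
        t = np.clip(t_ms[mask], 0.0, None)
        resp = decay.evaluate(t)
        if rise_tau_ms > 0:
            resp = resp * (1.0 - np.exp(-t / rise_tau_ms))
        y[mask] += resp
    return y


def _finalize_sweep(spec: SweepSpec, y: np.ndarray, noise_rng: np.random.Generator,
                    stimulus_times: Sequence[float], label: str) -> Sweep:
    if spec.polarity == "inward_negative":
        y = -y
    if spec.baseline_noise_sd > 0:
        y = y + noise_rng.normal(0.0, spec.baseline_noise_sd, size=y.size)
    return Sweep(
        values=y,
        sampling_rate=spec.sampling_rate,
        stimulus_times=tuple(stimulus_times),
        holding_potential=spec.holding_potential,
        id=label,
    )


def gen_eipsc(spec: SweepSpec, seed: int) -> Sweep:
    """Generate a synthetic evoked-IPSC sweep.

    With ``baseline_noise_sd = 0`` the trace equals the closed-form waveform
    to machine precision; the same ``(spec, seed)`` always yields an
    identical trace.
    """
    n = int(round(spec.duration * spec.sampling_rate))
    times = np.arange(n) / spec.sampling_rate
    y = _render_waveform(times, spec.stimulus_times, spec.decay, spec.rise_tau_ms)
    return _finalize_sweep(spec, y, _substream(seed, 0), spec.stimulus_times,
                           f"eipsc-seed{seed}")


def gen_train(spec: SweepSpec, n_stimuli: int, isi_ms: float, seed: int) -> Sweep:
    """Generate a train of ``n_stimuli`` evoked responses with linear superposition.

    Stimuli start at ``spec.stimulus_times[0]`` and repeat every ``isi_ms``;
    the responses superpose linearly and share one noise realization.
    ``n_stimuli = 1`` reproduces :func:`gen_eipsc` sample for sample.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli: must be >= 1")
    if not isi_ms > 0:
        raise ValueError("isi_ms: must be > 0")
    if len(spec.stimulus_times) != 1:
        raise ValueError("stimulus_times: gen_train expects exactly one train-onset time")
    t0 = spec.stimulus_times[0]
    stim = tuple(t0 + k * isi_ms / 1000.0 for k in range(n_stimuli))
    if stim[-1] >= spec.duration:
        raise ValueError(
            f"duration: last stimulus at {stim[-1]:.3f} s falls outside the {spec.duration} s sweep"
        )
    n = int(round(spec.duration * spec.sampling_rate))
    times = np.arange(n) / spec.sampling_rate
    y = _render_waveform(times, stim, spec.decay, spec.rise_tau_ms)
    return _finalize_sweep(spec, y, _substream(seed, 0), stim,
                           f"train{n_stimuli}-seed{seed}")


def apply_drug(decay: DecayComponents, effect: DrugEffect) -> DecayComponents:
    """Scale decay components by a drug effect (zero effect is the identity)."""
    return effect.apply(decay)


def _pid_waveform(t_s: np.ndarray, center_s: float, amplitude: float, fwhm_ms: float) -> np.ndarray:
    sigma_s = fwhm_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((t_s - center_s) / sigma_s) ** 2)


def _sle_waveform(t_s: np.ndarray, onset_s: float, duration_s: float,
                  pos_amplitude: float, neg_amplitude: float) -> np.ndarray:
    """Positive (GABAergic) Hann phase overlapping a negative (glutamatergic) one."""
    u = (t_s - onset_s) / duration_s
    y = np.zeros_like(t_s)
    # positive phase over [0, 0.6], negative over [0.45, 1.0]; the overlap
    # keeps the compound waveform from dwelling near zero mid-event
    pos = (u >= 0.0) & (u <= 0.6)
    y[pos] += pos_amplitude * np.sin(np.pi * u[pos] / 0.6) ** 2
    neg = (u >= 0.45) & (u <= 1.0)
    y[neg] -= neg_amplitude * np.sin(np.pi * (u[neg] - 0.45) / 0.55) ** 2
    return y


def gen_epiform_trace(spec: EpiformSpec, seed: int) -> Tuple[Sweep, pd.DataFrame]:
    """Generate a long sweep with injected PIDs and SLEs plus a ground-truth table.

    Event counts are Poisson draws at the requested rates; onsets are placed
    uniformly with rejection sampling so events never overlap.  Returns the
    sweep and a DataFrame with the exact type, onset, offset, peak time and
    amplitude of every injected event.

    Raises ``ValueError`` when the requested rates cannot be placed without
    overlap.
    """
    rng_counts = _substream(seed, 1)
    rng_place = _substream(seed, 2)
    rng_noise = _substream(seed, 0)

    n_pid = int(rng_counts.poisson(spec.pid_rate / 1000.0 * spec.duration))
    n_sle = int(rng_counts.poisson(spec.sle_rate / 1000.0 * spec.duration))

    sigma_s = spec.pid_half_width / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pid_span = 8.0 * sigma_s  # +-4 sigma support
    guard = 1.0  # s of clearance between events

    spans = [("SLE", spec.sle_duration)] * n_sle + [("PID", pid_span)] * n_pid
    occupancy = sum(s for _, s in spans) + guard * len(spans)
    if occupancy > 0.8 * spec.duration:
        raise ValueError(
            f"pid_rate/sle_rate: rates too high — {len(spans)} events need "
            f"{occupancy:.0f} s of a {spec.duration:.0f} s sweep"
        )

    placed: list[tuple[str, float, float]] = []  # (type, onset, offset)
    for etype, span in spans:  # longest (SLEs) first eases placement
        for _ in range(10_000):
            onset = float(rng_place.uniform(guard, spec.duration - span - guard))
            if all(onset + span + guard <= s or onset >= e + guard for _, s, e in placed):
                placed.append((etype, onset, onset + span))
                break
        else:
            raise ValueError("pid_rate/sle_rate: rates too high for non-overlapping placement")

    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    y = np.zeros(n)
    rows = []
    for etype, onset, offset in sorted(placed, key=lambda r: r[1]):
        if etype == "PID":
            center = onset + (offset - onset) / 2.0
            lo, hi = np.searchsorted(t, [onset, offset])
            y[lo:hi] += _pid_waveform(t[lo:hi], center, spec.pid_amplitude, spec.pid_half_width)
            rows.append(("PID", onset, offset, center, spec.pid_amplitude,
                         spec.pid_half_width, 0.0))
        else:
            lo, hi = np.searchsorted(t, [onset, offset])
            y[lo:hi] += _sle_waveform(t[lo:hi], onset, spec.sle_duration,
                                      spec.pid_amplitude, spec.sle_neg_amplitude)
            peak_time = onset + 0.3 * spec.sle_duration
            rows.append(("SLE", onset, offset, peak_time, spec.pid_amplitude,
                         np.nan, spec.sle_neg_amplitude))

    if spec.baseline_noise_sd > 0:
        y = y + rng_noise.normal(0.0, spec.baseline_noise_sd, size=n)

    truth = pd.DataFrame(
        rows,
        columns=["type", "onset_s", "offset_s", "peak_time_s", "peak_amplitude_pa",
                 "half_width_ms", "neg_amplitude_pa"],
    )
    sweep = Sweep(values=y, sampling_rate=spec.sampling_rate, stimulus_times=(),
                  holding_potential=-27.0, id=f"epiform-seed{seed}")
    return sweep, truth


def boltzmann_probability(current: np.ndarray, ec50: float, slope: float) -> np.ndarray:
    """Sigmoid extension probability P(I) = 1 / (1 + exp((EC50 - I)/Slope))."""
    from scipy.special import expit  # overflow-safe logistic

    current = np.asarray(current, dtype=float)
    return expit((current - ec50) / slope)


def gen_staircase_cohort(
    ec50: float,
    slope: float,
    ladder: Sequence[float] = MEST_LADDER_MA,
    n_animals: int = 11,
    start_index: int = 5,
    seed: int = 0,
) -> StaircaseTable:
    """Simulate an up-and-down staircase cohort with Boltzmann-distributed outcomes.

    Animal ``k+1`` receives one ladder step below/above animal ``k``'s
    current after extension/no-extension; steps beyond the ladder ends are
    clipped and flagged.  The first animal receives ``ladder[start_index]``
    (27 mA on the default ladder).
    """
    from .mest import next_current  # staircase rule lives with the analysis

    ladder = tuple(float(x) for x in ladder)
    if n_animals < 1:
        raise ValueError("n_animals: must be >= 1")
    if not 0 <= start_index < len(ladder):
        raise ValueError("start_index: outside the ladder")
    rng = _substream(seed, 3)

    rows = []
    idx = start_index
    clipped = False
    for k in range(n_animals):
        current = ladder[idx]
        p = float(boltzmann_probability(np.array([current]), ec50, slope)[0])
        extended = bool(rng.random() < p)
        rows.append((f"animal{k:02d}", current,
                     "extension" if extended else "no_extension", clipped))
        idx, clipped = next_current(ladder, "extension" if extended else "no_extension", idx)
    records = pd.DataFrame(rows, columns=["animal_id", "current_ma", "outcome", "clipped"])
    return StaircaseTable(records=records, ladder=ladder, true_ec50=ec50, true_slope=slope)


def gen_score_series(
    episodes: Sequence[Tuple[float, float, int]],
    latency: Optional[float] = None,
    window: float = 1800.0,
    died: bool = False,
    seed: int = 0,
    id: str = "",
) -> ScoreSeries:
    """Build a well-formed Racine score series from episode triples.

    If ``latency`` is given, episodes are shifted so the first one starts at
    that time.  Overlapping episodes merge to the maximum score (a warning
    is emitted).  ``seed`` is accepted for API symmetry with the other
    generators; the construction is deterministic.
    """
    eps = [(float(s), float(e), int(sc)) for s, e, sc in episodes]
    if latency is not None and eps:
        shift = latency - min(s for s, _, _ in eps)
        eps = [(s + shift, e + shift, sc) for s, e, sc in eps]
    return ScoreSeries(episodes=tuple(eps), window=window, died=died, id=id)
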