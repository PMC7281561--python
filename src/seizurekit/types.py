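"""Shared domain containers for voltage-clamp sweeps, decay kinetics and behavior.

Conventions
-----------
* Currents are in pA, time constants in ms, wall-clock times in s,
  stimulation currents in mA, holding potentials in mV.
* GABAergic currents recorded at depolarized holding potentials are
  outward (positive); a polarity flag flips the sign for inward recordings.
* Decay components are kept in canonical order ``tau_fast < tau_slow``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Sweep",
    "DecayComponents",
    "DrugEffect",
    "SweepSpec",
    "EpiformSpec",
    "EventRecord",
    "ScoreSeries",
    "BehavioralSummary",
    "StaircaseTable",
    "Table2x2",
]


@dataclass(frozen=True)
class Sweep:
    """A uniformly sampled current-clamp/voltage-clamp trace.

    Parameters
    ----------
    values : ndarray
        Membrane current in pA at uniform sampling.
    sampling_rate : float
        Samples per second (Hz).
    stimulus_times : tuple of float
        Extracellular stimulation times in seconds from sweep start.
    holding_potential : float
        Command potential in mV (metadata only).
    id : str
        Free-form label (cell/slice identifier).
    """

    values: np.ndarray
    sampling_rate: float
    stimulus_times: Tuple[float, ...] = ()
    holding_potential: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stimulus_times", tuple(float(t) for t in self.stimulus_times))
        if values.ndim != 1 or values.size < 2:
            raise ValueError("values: a sweep needs a 1-D trace with at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate: must be > 0")
        for t in self.stimulus_times:
            if not (0.0 <= t < self.duration):
                raise ValueError(f"stimulus_times: {t} s outside [0, {self.duration}) s")

    @property
    def duration(self) -> float:
        """Sweep length in seconds."""
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.values.size) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t`` (seconds)."""
        return int(np.ceil(t * self.sampling_rate - 1e-9))


@dataclass(frozen=True)
class DecayComponents:
    """Biexponential decay parameters: I(t) = A_fast e^(-t/tau_fast) + A_slow e^(-t/tau_slow)."""

    a_fast: float  # pA
    tau_fast: float  # ms
    a_slow: float  # pA
    tau_slow: float  # ms

    def __post_init__(self) -> None:
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise ValueError("tau_fast/tau_slow: time constants must be > 0")

    def canonical(self) -> "DecayComponents":
        """Relabel so that tau_fast < tau_slow (the model is label-symmetric)."""
        if self.tau_fast > self.tau_slow:
            return DecayComponents(self.a_slow, self.tau_slow, self.a_fast, self.tau_fast)
        return self

    @property
    def amplitude(self) -> float:
        """Instantaneous (t = 0) amplitude A_fast + A_slow in pA."""
        return self.a_fast + self.a_slow

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the decay at times ``t_ms`` (ms)."""
        t_ms = np.asarray(t_ms, dtype=float)
        return self.a_fast * np.exp(-t_ms / self.tau_fast) + self.a_slow * np.exp(
            -t_ms / self.tau_slow
        )


@dataclass(frozen=True)
class DrugEffect:
    """Per-component multiplicative drug action on a biexponential decay.

    ``*_block_frac`` scales amplitudes by ``(1 - frac)``; a negative
    fraction means potentiation.  ``tau_scale_*`` multiplies the time
    constants (1 = unchanged).
    """

    fast_block_frac: float
    slow_block_frac: float
    tau_scale_fast: float = 1.0
    tau_scale_slow: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fast_block_frac <= 1.0):
            raise ValueError("fast_block_frac: must be in [0, 1]")
        if self.slow_block_frac > 1.0:
            raise ValueError("slow_block_frac: must be <= 1 (negative = potentiation)")
        if not (self.tau_scale_fast > 0 and self.tau_scale_slow > 0):
            raise ValueError("tau_scale_fast/tau_scale_slow: must be > 0")

    def apply(self, decay: DecayComponents) -> DecayComponents:
        return DecayComponents(
            a_fast=decay.a_fast * (1.0 - self.fast_block_frac),
            tau_fast=decay.tau_fast * self.tau_scale_fast,
            a_slow=decay.a_slow * (1.0 - self.slow_block_frac),
            tau_slow=decay.tau_slow * self.tau_scale_slow,
        ).canonical()


@dataclass(frozen=True)
class SweepSpec:
    """Recipe for a synthetic evoked-IPSC sweep.

    The waveform after each stimulus is
    ``(1 - exp(-t/rise_tau)) * (A_fast exp(-t/tau_fast) + A_slow exp(-t/tau_slow))``
    with additive i.i.d. Gaussian baseline noise.  ``rise_tau_ms = 0`` means an
    instantaneous rise.
    """

    decay: DecayComponents
    sampling_rate: float = 20_000.0  # Hz
    duration: float = 1.0  # s
    baseline_noise_sd: float = 0.0  # pA
    rise_tau_ms: float = 2.0
    stimulus_times: Tuple[float, ...] = (0.1,)
    polarity: str = "outward_positive"
    holding_potential: float = 0.0  # mV

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus_times", tuple(float(t) for t in self.stimulus_times))
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate: must be > 0")
        if not self.duration > 0:
            raise ValueError("duration: must be > 0")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd: must be >= 0")
        if self.rise_tau_ms < 0:
            raise ValueError("rise_tau_ms: must be >= 0")
        if self.polarity not in ("outward_positive", "inward_negative"):
            raise ValueError("polarity: must be 'outward_positive' or 'inward_negative'")
        for t in self.stimulus_times:
            if not (0.0 <= t < self.duration):
                raise ValueError(f"stimulus_times: {t} s outside [0, {self.duration}) s")


@dataclass(frozen=True)
class EpiformSpec:
    """Recipe for a long synthetic sweep containing PIDs and SLEs.

    Rates are in mHz (events per 1000 s); event waveforms are placed without
    overlap on top of Gaussian baseline noise.  PIDs are positive Gaussian
    transients; SLEs carry a positive (GABAergic) phase followed by an
    overlapping negative (glutamatergic) phase.
    """

    duration: float = 1800.0  # s
    pid_rate: float = 7.1  # mHz
    sle_rate: float = 2.2  # mHz
    pid_amplitude: float = 716.0  # pA
    pid_half_width: float = 80.0  # ms, FWHM
    sle_duration: float = 10.0  # s
    sle_neg_amplitude: float = 400.0  # pA
    baseline_noise_sd: float = 5.0  # pA
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if self.pid_rate < 0 or self.sle_rate < 0:
            raise ValueError("pid_rate/sle_rate: must be >= 0")
        if not self.sle_duration * 1000.0 > self.pid_half_width:
            raise ValueError("sle_duration: must exceed pid_half_width")
        if not self.duration > 0:
            raise ValueError("duration: must be > 0")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate: must be > 0")


@dataclass(frozen=True)
class EventRecord:
    """A detected or injected epileptiform event."""

    type: str  # "PID" | "SLE"
    onset: float  # s
    offset: float  # s
    peak_amplitude: float  # pA, baseline-subtracted positive peak
    half_width: Optional[float] = None  # ms, PIDs only
    has_negative_phase: bool = False
    peak_time: Optional[float] = None  # s

    def __post_init__(self) -> None:
        if self.type not in ("PID", "SLE"):
            raise ValueError("type: must be 'PID' or 'SLE'")
        if not self.offset > self.onset:
            raise ValueError("offset: must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def merge_episodes(
    episodes: Sequence[Tuple[float, float, int]],
    warn: bool = True,
) -> Tuple[Tuple[float, float, int], ...]:
    """Merge overlapping scored episodes; an overlap takes the maximum score."""
    eps = sorted((float(s), float(e), int(sc)) for s, e, sc in episodes)
    merged: list[tuple[float, float, int]] = []
    overlapped = False
    for s, e, sc in eps:
        if merged and s < merged[-1][1]:
            ps, pe, psc = merged[-1]
            merged[-1] = (ps, max(pe, e), max(psc, sc))
            overlapped = True
        else:
            merged.append((s, e, sc))
    if overlapped and warn:
        warnings.warn("overlapping episodes merged to the maximum score", stacklevel=3)
    return tuple(merged)


@dataclass(frozen=True)
class ScoreSeries:
    """Racine-scored convulsion episodes for one animal over an observation window."""

    episodes: Tuple[Tuple[float, float, int], ...]
    window: float = 1800.0  # s
    injection_time: float = 0.0  # s
    died: bool = False
    id: str = ""

    def __post_init__(self) -> None:
        eps = merge_episodes(self.episodes)
        object.__setattr__(self, "episodes", eps)
        for s, e, sc in eps:
            if not (0.0 <= s < e <= self.window):
                raise ValueError(f"episodes: ({s}, {e}) outside [0, {self.window}] s")
            if sc not in (1, 2, 3, 4):
                raise ValueError(f"episodes: score {sc} outside the modified Racine scale 1-4")


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-animal behavioral endpoints of the chemoconvulsant test."""

    latency: Optional[float]  # s, None when no convulsions
    total_duration: float  # s
    average_score: float
    status_epilepticus: bool
    died: bool = False


# imputation cell states for the staircase table
OBSERVED_EXT = "observed_ext"
OBSERVED_NO = "observed_no"
ASSUMED_EXT = "assumed_ext"
ASSUMED_NO = "assumed_no"
UNTESTED = "untested"


@dataclass(frozen=True)
class StaircaseTable:
    """Up-and-down staircase observations for one treatment group.

    ``records`` is a pandas DataFrame with columns
    ``animal_id, current_ma, outcome ('extension'|'no_extension'), clipped``.
    ``imputed`` (animals x ladder currents) is filled by
    :func:`seizurekit.mest.impute_outcomes`.
    """

    records: "object"  # pandas.DataFrame
    ladder: Tuple[float, ...]
    imputed: Optional["object"] = None  # pandas.DataFrame, animal x current
    true_ec50: Optional[float] = None
    true_slope: Optional[float] = None

    def __post_init__(self) -> None:
        ladder = tuple(float(x) for x in self.ladder)
        object.__setattr__(self, "ladder", ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ladder: currents must be strictly increasing")


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table; rows are groups, columns are outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name}: counts must be non-negative integers")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d
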