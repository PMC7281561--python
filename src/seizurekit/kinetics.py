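"""Evoked-IPSC measurement and biexponential decay decomposition.

The decay phase (10-90% of peak) of a GABAergic postsynaptic current is
modeled as

    I(t) = A_fast * exp(-t / tau_fast) + A_slow * exp(-t / tau_slow)

with time referenced to the response peak, so fitted amplitudes
extrapolate back to the peak.  Drug block is quantified per quantity as

    Block = 100% * (A_baseline - A_treated) / A_baseline

and per kinetic component via the paired constrained protocol: both
decays are first fitted unconstrained, the pair's fast and slow time
constants are averaged, and both decays are refitted amplitude-only with
the time constants fixed to those averages, so amplitude changes are
compared on a common kinetic basis.

The weighted decay time constant is the amplitude-weighted mean

    tau_w = (tau_fast * A_fast + tau_slow * A_slow) / (A_fast + A_slow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .types import DecayComponents, Sweep

__all__ = [
    "average_sweeps",
    "BiexponentialDecay",
    "DecayFitResult",
    "PairFitResult",
    "EIPSCMeasure",
    "measure_peak",
    "measure_area",
    "percent_block",
    "extract_decay_segment",
    "fit_biexponential",
    "constrained_pair_fit",
    "component_block",
    "weighted_tau",
    "train_profile",
    "average_block_over_cells",
    "measure_eipsc",
]


# ---------------------------------------------------------------------------
# scalar utilities


def percent_block(baseline: float, treated: float) -> float:
    """Percent block, 100*(baseline - treated)/baseline; negative = potentiation."""
    if baseline == 0:
        raise ValueError("baseline: percent block is undefined for a zero baseline")
    return 100.0 * (baseline - treated) / baseline


def weighted_tau(decay: DecayComponents) -> float:
    """Amplitude-weighted mean of the fast and slow time constants (ms)."""
    total = decay.a_fast + decay.a_slow
    if total <= 0:
        raise ValueError("a_fast + a_slow: weighted tau needs a positive total amplitude")
    return (decay.tau_fast * decay.a_fast + decay.tau_slow * decay.a_slow) / total


def average_block_over_cells(per_cell_percents: Sequence[float]) -> Tuple[float, float]:
    """Group mean and SEM of per-cell percent blocks (ratios averaged per cell)."""
    x = np.asarray(per_cell_percents, dtype=float)
    if x.size < 2:
        raise ValueError("per_cell_percents: need at least 2 cells for a group mean +- SEM")
    return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size))


def average_sweeps(sweeps: Sequence[Sweep]) -> Sweep:
    """Sample-wise mean of stimulus-aligned sweeps (the 10-15 response average)."""
    if len(sweeps) < 1:
        raise ValueError("sweeps: need at least one sweep")
    ref = sweeps[0]
    for s in sweeps[1:]:
        if s.sampling_rate != ref.sampling_rate or s.values.size != ref.values.size:
            raise ValueError("sweeps: sampling rates and lengths must match")
        if s.stimulus_times != ref.stimulus_times:
            raise ValueError("sweeps: stimulus times must match for alignment")
    mean = np.mean([s.values for s in sweeps], axis=0)
    return Sweep(values=mean, sampling_rate=ref.sampling_rate,
                 stimulus_times=ref.stimulus_times,
                 holding_potential=ref.holding_potential,
                 id=f"avg{len(sweeps)}:{ref.id}")


# ---------------------------------------------------------------------------
# sweep measurements


def _normalized(sweep: Sweep, polarity: str) -> np.ndarray:
    if polarity == "positive":
        return sweep.values
    if polarity == "negative":
        return -sweep.values
    if polarity == "auto":
        v = sweep.values - np.median(sweep.values)
        return sweep.values if abs(v.max()) >= abs(v.min()) else -sweep.values
    raise ValueError("polarity: must be 'positive', 'negative' or 'auto'")


def _baseline(values: np.ndarray, sweep: Sweep, stim_t: float, baseline_window_ms: float) -> float:
    i1 = sweep.index_at(stim_t)
    i0 = max(0, i1 - int(round(baseline_window_ms / 1000.0 * sweep.sampling_rate)))
    if i1 <= i0:
        return 0.0
    return float(np.mean(values[i0:i1]))


def _stimulus_time(sweep: Sweep, stimulus_index: int) -> float:
    try:
        return sweep.stimulus_times[stimulus_index]
    except IndexError:
        raise ValueError(
            f"stimulus_index: sweep has {len(sweep.stimulus_times)} stimuli, "
            f"index {stimulus_index} is out of range"
        ) from None


def measure_peak(
    sweep: Sweep,
    stimulus_index: int = 0,
    search_window_ms: float = 50.0,
    baseline_window_ms: float = 10.0,
    polarity: str = "positive",
) -> float:
    """Baseline-subtracted peak amplitude (pA) in a window after the stimulus.

    The baseline is the mean over the ``baseline_window_ms`` preceding the
    stimulus; the peak is the maximum of the polarity-normalized current in
    ``[t_stim, t_stim + search_window_ms)``.
    """
    t0 = _stimulus_time(sweep, stimulus_index)
    values = _normalized(sweep, polarity)
    base = _baseline(values, sweep, t0, baseline_window_ms)
    i0 = sweep.index_at(t0)
    i1 = min(values.size, sweep.index_at(t0 + search_window_ms / 1000.0))
    if i1 <= i0:
        raise ValueError("search_window_ms: window contains no samples")
    return float(np.max(values[i0:i1]) - base)


def measure_area(
    sweep: Sweep,
    stimulus_index: int = 0,
    span_ms: float = 750.0,
    baseline_window_ms: float = 10.0,
    polarity: str = "positive",
) -> float:
    """Charge transfer (pA*ms): trapezoidal integral over 0-``span_ms`` post-stimulus."""
    t0 = _stimulus_time(sweep, stimulus_index)
    available_ms = (sweep.duration - t0) * 1000.0
    if available_ms < span_ms:
        raise ValueError(
            f"span_ms: only {available_ms:.1f} ms available after the stimulus, "
            f"{span_ms:.1f} ms required"
        )
    values = _normalized(sweep, polarity)
    base = _baseline(values, sweep, t0, baseline_window_ms)
    i0 = sweep.index_at(t0)
    i1 = min(values.size, sweep.index_at(t0 + span_ms / 1000.0) + 1)
    seg = values[i0:i1] - base
    dt_ms = 1000.0 / sweep.sampling_rate
    return float(np.trapezoid(seg, dx=dt_ms))


def extract_decay_segment(
    sweep: Sweep,
    stimulus_index: int = 0,
    search_window_ms: float = 50.0,
    baseline_window_ms: float = 10.0,
    polarity: str = "positive",
    smooth_ms: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Extract the 10-90% decay phase of an evoked response.

    Returns ``(t_ms, values_pa)`` where time is in ms relative to the
    stimulus and values are baseline-subtracted and polarity-normalized:
    the segment runs from the first post-peak crossing of 90% of peak down
    to the first crossing of 10% of peak.  With the stimulus as the time
    origin, fitted amplitudes extrapolate back to stimulus onset and so
    recover the generating component amplitudes on synthetic input.

    Peak and crossing locations are read from a copy smoothed with a
    ``smooth_ms`` boxcar so baseline noise cannot trigger the 90%/10%
    criteria prematurely; the returned samples are the raw trace.
    """
    t0 = _stimulus_time(sweep, stimulus_index)
    values = _normalized(sweep, polarity)
    base = _baseline(values, sweep, t0, baseline_window_ms)
    y = values - base
    w = max(1, int(round(smooth_ms / 1000.0 * sweep.sampling_rate)))
    ys = np.convolve(y, np.ones(w) / w, mode="same") if w > 1 else y
    i0 = sweep.index_at(t0)
    i1 = min(y.size, sweep.index_at(t0 + search_window_ms / 1000.0))
    if i1 <= i0:
        raise ValueError("search_window_ms: window contains no samples")
    peak_idx = i0 + int(np.argmax(ys[i0:i1]))
    peak = ys[peak_idx]
    if peak <= 0:
        raise ValueError("peak: no positive response found after the stimulus")

    post = ys[peak_idx:]
    below90 = np.nonzero(post <= 0.9 * peak)[0]
    if below90.size == 0:
        raise ValueError("decay: trace never falls below 90% of peak within the sweep")
    start = below90[0]
    below10 = np.nonzero(post[start:] <= 0.1 * peak)[0]
    if below10.size == 0:
        raise ValueError(
            "decay: trace never reaches 10% of peak — sweep too short for the 10-90% fit"
        )
    end = start + below10[0]
    idx = peak_idx + np.arange(start, end + 1)
    t_ms = (idx - i0) * 1000.0 / sweep.sampling_rate
    return t_ms, y[idx]


# ---------------------------------------------------------------------------
# biexponential fitting


def _biexp(t: np.ndarray, a_fast: float, tau_fast: float, a_slow: float, tau_slow: float):
    return a_fast * np.exp(-t / tau_fast) + a_slow * np.exp(-t / tau_slow)


class BiexponentialDecay(BaseEstimator, RegressorMixin):
    """Least-squares biexponential decay model with grid-seeded refinement.

    The fit first scans a log-spaced grid of (tau_fast, tau_slow) pairs,
    solving amplitudes by non-negative linear least squares at each pair,
    then refines the best grid point with bounded nonlinear least squares.
    Time constants are relabeled after fitting so ``tau_fast_ < tau_slow_``.

    Parameters
    ----------
    tau_min_ms, tau_max_ms : float
        Grid span for the time-constant search.
    n_grid : int
        Number of log-spaced grid values per time constant.
    non_negative : bool
        Constrain amplitudes to be >= 0 (the unconstrained-protocol default).

    Attributes
    ----------
    a_fast_, tau_fast_, a_slow_, tau_slow_ : float
        Fitted parameters (pA, ms).
    components_ : DecayComponents
    sse_ : float
        Residual sum of squares.
    converged_ : bool
        False when the nonlinear refinement failed (the grid solution is kept).
    ill_separated_ : bool
        True when the fitted time constants differ by less than 1.5x, i.e.
        the two components are not meaningfully distinct.
    """

    def __init__(self, tau_min_ms: float = 1.0, tau_max_ms: float = 500.0,
                 n_grid: int = 12, non_negative: bool = True):
        self.tau_min_ms = tau_min_ms
        self.tau_max_ms = tau_max_ms
        self.n_grid = n_grid
        self.non_negative = non_negative

    def fit(self, t_ms: np.ndarray, y: np.ndarray) -> "BiexponentialDecay":
        t = np.asarray(t_ms, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t_ms/y: lengths differ")
        if t.size < 20:
            raise ValueError("segment: need at least 20 samples for a biexponential fit")

        grid = np.geomspace(self.tau_min_ms, self.tau_max_ms, self.n_grid)
        best: Optional[tuple] = None
        for i in range(self.n_grid):
            for j in range(i + 1, self.n_grid):
                tf, ts = grid[i], grid[j]
                X = np.column_stack([np.exp(-t / tf), np.exp(-t / ts)])
                if self.non_negative:
                    amps, _ = optimize.nnls(X, y)
                else:
                    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = float(np.sum((X @ amps - y) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, amps[0], tf, amps[1], ts)

        assert best is not None
        sse0, af, tf, asl, ts = best
        p0 = [max(af, 1e-6), tf, max(asl, 1e-6), ts]
        lo = [0.0 if self.non_negative else -np.inf, self.tau_min_ms * 0.02,
              0.0 if self.non_negative else -np.inf, self.tau_min_ms * 0.02]
        hi = [np.inf, self.tau_max_ms * 10.0, np.inf, self.tau_max_ms * 10.0]
        converged = True
        try:
            popt, _ = optimize.curve_fit(_biexp, t, y, p0=p0, bounds=(lo, hi), maxfev=20_000)
            if np.sum((_biexp(t, *popt) - y) ** 2) <= sse0 + 1e-12:
                af, tf, asl, ts = popt
                sse0 = float(np.sum((_biexp(t, *popt) - y) ** 2))
            else:
                converged = False
        except RuntimeError:
            converged = False

        comp = DecayComponents(float(af), float(tf), float(asl), float(ts)).canonical()
        self.a_fast_, self.tau_fast_ = comp.a_fast, comp.tau_fast
        self.a_slow_, self.tau_slow_ = comp.a_slow, comp.tau_slow
        self.components_ = comp
        self.sse_ = float(sse0)
        self.converged_ = converged
        self.ill_separated_ = bool(comp.tau_slow < 1.5 * comp.tau_fast)
        self.n_samples_ = t.size
        return self

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        return self.components_.evaluate(np.asarray(t_ms, dtype=float))


@dataclass(frozen=True)
class DecayFitResult:
    """A fitted biexponential decay plus diagnostics."""

    components: DecayComponents
    sse: float
    converged: bool
    ill_separated: bool

    @property
    def tau_weighted(self) -> float:
        return weighted_tau(self.components)


def fit_biexponential(t_ms: np.ndarray, y: np.ndarray, **params) -> DecayFitResult:
    """Fit Eq-style biexponential decay to a 10-90% segment; see BiexponentialDecay."""
    est = BiexponentialDecay(**params).fit(t_ms, y)
    if not est.converged_:
        warnings.warn("biexponential refinement did not converge; grid solution returned",
                      stacklevel=2)
    if est.ill_separated_:
        warnings.warn("fitted time constants are ill-separated (ratio < 1.5)", stacklevel=2)
    return DecayFitResult(est.components_, est.sse_, est.converged_, est.ill_separated_)


def _amplitude_refit(t: np.ndarray, y: np.ndarray, tau_fast: float, tau_slow: float
                     ) -> Tuple[DecayComponents, float]:
    """Amplitude-only linear refit with fixed time constants (sign-unconstrained)."""
    X = np.column_stack([np.exp(-t / tau_fast), np.exp(-t / tau_slow)])
    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((X @ amps - y) ** 2))
    return DecayComponents(float(amps[0]), tau_fast, float(amps[1]), tau_slow), sse


@dataclass(frozen=True)
class PairFitResult:
    """Result of the paired unconstrained -> averaged-tau -> constrained protocol."""

    baseline: DecayComponents
    treated: DecayComponents
    unconstrained_baseline: DecayFitResult
    unconstrained_treated: DecayFitResult
    tau_fast_mean: float
    tau_slow_mean: float
    sse_baseline: float
    sse_treated: float


def constrained_pair_fit(
    baseline_segment: Tuple[np.ndarray, np.ndarray],
    treated_segment: Tuple[np.ndarray, np.ndarray],
    **params,
) -> PairFitResult:
    """Decompose a baseline/treated decay pair on a shared kinetic basis.

    Step 1 fits each decay unconstrained; step 2 averages the pair's fast
    and slow time constants; step 3 refits both decays amplitude-only with
    the time constants fixed to those averages.  The constrained amplitude
    refit is sign-unconstrained so potentiation is expressible.
    """
    tb, yb = baseline_segment
    tt, yt = treated_segment
    try:
        fit_b = fit_biexponential(tb, yb, **params)
    except ValueError as exc:
        raise ValueError(f"baseline unconstrained fit: {exc}") from exc
    try:
        fit_t = fit_biexponential(tt, yt, **params)
    except ValueError as exc:
        raise ValueError(f"treated unconstrained fit: {exc}") from exc

    tau_fast_mean = 0.5 * (fit_b.components.tau_fast + fit_t.components.tau_fast)
    tau_slow_mean = 0.5 * (fit_b.components.tau_slow + fit_t.components.tau_slow)

    con_b, sse_b = _amplitude_refit(np.asarray(tb, float), np.asarray(yb, float),
                                    tau_fast_mean, tau_slow_mean)
    con_t, sse_t = _amplitude_refit(np.asarray(tt, float), np.asarray(yt, float),
                                    tau_fast_mean, tau_slow_mean)
    return PairFitResult(
        baseline=con_b, treated=con_t,
        unconstrained_baseline=fit_b, unconstrained_treated=fit_t,
        tau_fast_mean=tau_fast_mean, tau_slow_mean=tau_slow_mean,
        sse_baseline=sse_b, sse_treated=sse_t,
    )


def component_block(pair: PairFitResult) -> Tuple[float, float]:
    """Percent block of the fast and slow amplitudes across a constrained pair.

    A zero baseline component leaves that entry NaN (undefined) with a warning.
    """
    out = []
    for name, base, treat in (
        ("fast", pair.baseline.a_fast, pair.treated.a_fast),
        ("slow", pair.baseline.a_slow, pair.treated.a_slow),
    ):
        if base == 0:
            warnings.warn(f"{name} component block undefined: zero baseline amplitude",
                          stacklevel=2)
            out.append(float("nan"))
        else:
            out.append(percent_block(base, treat))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# composite measures


@dataclass(frozen=True)
class EIPSCMeasure:
    """Standard per-response measurements of one evoked IPSC."""

    peak_amplitude: float  # pA
    area: float  # pA*ms over 0-750 ms
    decay: DecayComponents
    tau_weighted: float  # ms


def measure_eipsc(sweep: Sweep, stimulus_index: int = 0, polarity: str = "positive",
                  **fit_params) -> EIPSCMeasure:
    """Peak, 0-750 ms area, decay decomposition and weighted tau of one response."""
    peak = measure_peak(sweep, stimulus_index, polarity=polarity)
    area = measure_area(sweep, stimulus_index, polarity=polarity)
    t_ms, y = extract_decay_segment(sweep, stimulus_index, polarity=polarity)
    fit = fit_biexponential(t_ms, y, **fit_params)
    return EIPSCMeasure(peak_amplitude=peak, area=area, decay=fit.components,
                        tau_weighted=fit.tau_weighted)


def train_profile(
    sweep: Sweep,
    n_stimuli: int = 5,
    isi_ms: float = 100.0,
    baseline_window_ms: float = 10.0,
    polarity: str = "positive",
) -> np.ndarray:
    """Normalized peak amplitudes across a stimulus train.

    Peaks of the compound trace are read in each inter-stimulus window
    relative to the pre-train baseline and divided by the first peak, so the
    first element is 1 by construction and temporal summation shows up as
    later elements exceeding 1.
    """
    if len(sweep.stimulus_times) < n_stimuli:
        raise ValueError(
            f"n_stimuli: sweep has {len(sweep.stimulus_times)} stimuli, {n_stimuli} required"
        )
    values = _normalized(sweep, polarity)
    t_first = sweep.stimulus_times[0]
    base = _baseline(values, sweep, t_first, baseline_window_ms)
    peaks = []
    for k in range(n_stimuli):
        t_k = sweep.stimulus_times[k]
        i0 = sweep.index_at(t_k)
        i1 = min(values.size, sweep.index_at(t_k + isi_ms / 1000.0))
        if i1 <= i0:
            raise ValueError(f"isi_ms: stimulus window {k} contains no samples")
        peaks.append(np.max(values[i0:i1]) - base)
    peaks = np.asarray(peaks)
    if peaks[0] <= 0:
        raise ValueError("train: first response peak is non-positive, cannot normalize")
    return peaks / peaks[0]
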