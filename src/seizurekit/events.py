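"""Detection and quantification of epileptiform events in long sweeps.

In the 4-aminopyridine slice model recorded near -27 mV, preictal
discharges (PIDs) are brief positive (GABAergic) transients while
seizure-like events (SLEs) are long discharges carrying both positive
and negative (glutamatergic) phases.  The detector thresholds a
low-pass-filtered trace at ``k`` robust noise units (MAD) around a
median baseline, merges nearby excursions, and classifies an event as an
SLE when it is long enough or shows a supra-threshold negative phase.

All detector constants are configuration, not biology: thresholds and
windows are explicit parameters with documented defaults.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .types import EventRecord, Sweep

__all__ = [
    "EpiformEventDetector",
    "detect_events",
    "event_frequency",
    "pid_half_width",
    "averaged_pid_waveform",
    "drug_window_filter",
]

_MAD_TO_SD = 1.4826


class EpiformEventDetector(BaseEstimator):
    """Threshold detector for PIDs and SLEs.

    Parameters
    ----------
    threshold_k : float
        Detection threshold in robust noise SD units (MAD * 1.4826).
    lowpass_hz : float or None
        Low-pass corner for the detection copy of the trace (None disables).
    min_duration_s : float
        Minimum above-threshold duration for a candidate event.
    merge_gap_s : float
        Candidate excursions closer than this merge into one event.
    sle_min_duration_s : float
        Events at least this long are SLEs regardless of polarity.
    neg_phase_frac : float
        A negative phase only counts (for SLE classification) when it
        exceeds both the detection threshold and this fraction of the
        event's positive peak; keeps filter undershoot of large PIDs from
        masquerading as a glutamatergic phase.
    noise_floor_pa : float or None
        Absolute lower bound on the detection threshold; required when the
        trace is noise-free (MAD = 0), otherwise optional.

    Attributes
    ----------
    baseline_ : float
        Median of the filtered trace (pA).
    noise_sd_ : float
        Robust noise SD estimate (pA).
    threshold_ : float
        Effective detection threshold (pA).
    events_ : list of EventRecord
    """

    def __init__(self, threshold_k: float = 4.0, lowpass_hz: Optional[float] = 50.0,
                 min_duration_s: float = 0.05, merge_gap_s: float = 0.2,
                 sle_min_duration_s: float = 2.0, neg_phase_frac: float = 0.1,
                 noise_floor_pa: Optional[float] = None):
        self.threshold_k = threshold_k
        self.lowpass_hz = lowpass_hz
        self.min_duration_s = min_duration_s
        self.merge_gap_s = merge_gap_s
        self.sle_min_duration_s = sle_min_duration_s
        self.neg_phase_frac = neg_phase_frac
        self.noise_floor_pa = noise_floor_pa

    def fit(self, sweep: Sweep) -> "EpiformEventDetector":
        """Estimate baseline/noise and detect all events in the sweep."""
        if sweep.duration < 60.0:
            raise ValueError("sweep: event detection needs at least 60 s of recording")
        x = sweep.values
        if self.lowpass_hz is not None and self.lowpass_hz < sweep.sampling_rate / 2.0:
            sos = signal.butter(4, self.lowpass_hz, btype="low",
                                fs=sweep.sampling_rate, output="sos")
            xf = signal.sosfiltfilt(sos, x)
        else:
            xf = x

        baseline = float(np.median(xf))
        mad = float(np.median(np.abs(xf - baseline)))
        noise_sd = _MAD_TO_SD * mad
        threshold = self.threshold_k * noise_sd
        if self.noise_floor_pa is not None:
            threshold = max(threshold, self.noise_floor_pa)
        if threshold <= 0:
            raise ValueError(
                "threshold: zero baseline noise estimate — set noise_floor_pa for "
                "noise-free traces"
            )

        y = xf - baseline
        fs = sweep.sampling_rate
        mask = np.abs(y) > threshold
        events: List[EventRecord] = []
        runs = _runs(mask)
        runs = _merge_runs(runs, int(round(self.merge_gap_s * fs)))
        min_len = int(round(self.min_duration_s * fs))
        for i0, i1 in runs:
            if i1 - i0 < min_len:
                continue
            seg = y[i0:i1]
            onset, offset = i0 / fs, i1 / fs
            duration = offset - onset
            pos_peak = float(seg.max())
            neg_peak = float(seg.min())
            has_neg = neg_peak < -max(threshold, self.neg_phase_frac * pos_peak)
            etype = "SLE" if (duration >= self.sle_min_duration_s or has_neg) else "PID"
            peak_time = onset + int(np.argmax(seg)) / fs
            rec = EventRecord(type=etype, onset=onset, offset=offset,
                              peak_amplitude=pos_peak, has_negative_phase=has_neg,
                              peak_time=peak_time)
            if etype == "PID":
                rec = EventRecord(type="PID", onset=onset, offset=offset,
                                  peak_amplitude=pos_peak, has_negative_phase=has_neg,
                                  peak_time=peak_time,
                                  half_width=_half_width_ms(sweep, rec, baseline))
            events.append(rec)

        self.baseline_ = baseline
        self.noise_sd_ = noise_sd
        self.threshold_ = threshold
        self.events_ = events
        return self

    def detect(self, sweep: Sweep) -> List[EventRecord]:
        """Fit on the sweep and return the detected events."""
        return self.fit(sweep).events_


def _runs(mask: np.ndarray) -> list:
    """(start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_runs(runs: list, gap: int) -> list:
    merged = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return merged


def detect_events(sweep: Sweep, **params) -> List[EventRecord]:
    """Functional wrapper over :class:`EpiformEventDetector`."""
    return EpiformEventDetector(**params).detect(sweep)


def event_frequency(events: Sequence[EventRecord], analyzed_duration: float,
                    type: Optional[str] = None) -> float:
    """Event rate in mHz over the analyzed duration (s), optionally by type."""
    if not analyzed_duration > 0:
        raise ValueError("analyzed_duration: must be > 0")
    n = sum(1 for e in events if type is None or e.type == type)
    return 1000.0 * n / analyzed_duration


def _half_width_ms(sweep: Sweep, event: EventRecord, baseline: float) -> Optional[float]:
    """Width at 50% of the baseline-subtracted peak, linearly interpolated."""
    fs = sweep.sampling_rate
    i0 = max(0, sweep.index_at(event.onset) - 1)
    i1 = min(sweep.values.size, sweep.index_at(event.offset) + 2)
    seg = sweep.values[i0:i1] - baseline
    pk = int(np.argmax(seg))
    half = seg[pk] / 2.0
    left = np.nonzero(seg[:pk + 1] <= half)[0]
    right_rel = np.nonzero(seg[pk:] <= half)[0]
    if left.size == 0 or right_rel.size == 0:
        return None  # clipped at a segment edge; half-width undefined
    li = left[-1]
    t_left = li + (half - seg[li]) / (seg[li + 1] - seg[li])
    ri = pk + right_rel[0]
    t_right = ri - 1 + (half - seg[ri - 1]) / (seg[ri] - seg[ri - 1])
    return float((t_right - t_left) / fs * 1000.0)


def pid_half_width(event: EventRecord, sweep: Sweep, baseline: Optional[float] = None
                   ) -> float:
    """Half-width (ms) of a PID: time between the two 50%-of-peak crossings."""
    if event.type != "PID":
        raise ValueError("event: half-width is defined for PIDs only")
    if baseline is None:
        baseline = float(np.median(sweep.values))
    hw = _half_width_ms(sweep, event, baseline)
    if hw is None:
        raise ValueError("event: trace does not cross 50% of peak on both sides (clipped)")
    return hw


def averaged_pid_waveform(events: Sequence[EventRecord], sweep: Sweep,
                          window_ms: float = 500.0,
                          baseline: Optional[float] = None) -> np.ndarray:
    """Peak-aligned, peak-normalized mean PID waveform over ±window/2.

    Each PID is cut around its peak, divided by its own peak amplitude and
    averaged, so the output waveform peaks at 1 regardless of the amplitude
    distribution across events.
    """
    pids = [e for e in events if e.type == "PID"]
    if len(pids) < 2:
        raise ValueError("events: need at least 2 PIDs to average")
    if baseline is None:
        baseline = float(np.median(sweep.values))
    half = int(round(window_ms / 2000.0 * sweep.sampling_rate))
    out = np.zeros(2 * half + 1)
    n_used = 0
    for e in pids:
        i0 = max(0, sweep.index_at(e.onset))
        i1 = min(sweep.values.size, sweep.index_at(e.offset) + 1)
        pk = i0 + int(np.argmax(sweep.values[i0:i1]))
        if pk - half < 0 or pk + half + 1 > sweep.values.size:
            continue
        seg = sweep.values[pk - half: pk + half + 1] - baseline
        out += seg / seg[half]
        n_used += 1
    if n_used == 0:
        raise ValueError("events: no PID fits inside the sweep with the requested window")
    return out / n_used


def drug_window_filter(events: Sequence[EventRecord], drug_onset: float,
                       washin: float = 420.0) -> List[EventRecord]:
    """Drop events during drug wash-in.

    Events with onset in ``[drug_onset, drug_onset + washin)`` are excluded;
    baseline events (before drug onset) and fully washed-in events are kept.
    The 420 s default corresponds to excluding the first 7 min of perfusion.
    """
    if washin < 0:
        raise ValueError("washin: must be >= 0")
    return [e for e in events if not (drug_onset <= e.onset < drug_onset + washin)]
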