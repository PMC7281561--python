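"""Behavioral endpoints of the chemoconvulsant (PTZ) test.

Convulsions are scored on a modified Racine scale (1 = myoclonic jerks,
2 = partial clonic seizure sitting, 3 = generalized clonic/tonic-clonic
on the belly, 4 = tonic or tonic-clonic on the side).  Per animal the
test reports the latency to the first convulsion, the total convulsion
duration, the average score — the mean over 30-s bins of the maximal
score in each bin across a 30-min observation window — and a
status-epilepticus flag for continuous convulsive runs longer than
10 min.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .types import BehavioralSummary, ScoreSeries, Table2x2, merge_episodes

__all__ = [
    "average_score",
    "latency_and_duration",
    "status_epilepticus",
    "summarize",
    "group_summary",
    "contingency_table",
]


def average_score(series: ScoreSeries, bin_s: float = 30.0) -> float:
    """Mean over fixed bins of the maximal episode score in each bin.

    Bins are ``[0, 30), [30, 60), ...``; an episode touching a bin for any
    positive duration sets that bin's maximum; empty bins score 0.
    """
    n_bins = series.window / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_s: window {series.window} s is not divisible into {bin_s}-s bins")
    n_bins = int(round(n_bins))
    for s, e, _ in series.episodes:
        if not (0.0 <= s < e <= series.window):
            raise ValueError(f"episodes: ({s}, {e}) outside the observation window")
    scores = np.zeros(n_bins)
    for s, e, sc in series.episodes:
        first = int(np.floor(s / bin_s))
        # an episode ending exactly on a bin edge does not touch the next bin
        last = int(np.ceil(e / bin_s)) - 1
        scores[first:last + 1] = np.maximum(scores[first:last + 1], sc)
    return float(scores.mean())


def latency_and_duration(series: ScoreSeries) -> Tuple[Optional[float], float]:
    """Latency to the first convulsion and total merged convulsion time (s).

    Empty series give ``(None, 0.0)``.
    """
    if not series.episodes:
        return None, 0.0
    latency = min(s for s, _, _ in series.episodes)
    merged = merge_episodes(series.episodes, warn=False)
    duration = sum(e - s for s, e, _ in merged)
    return latency, duration


def status_epilepticus(series: ScoreSeries, gap_tolerance: float = 0.0,
                       threshold_s: float = 600.0) -> bool:
    """True iff some convulsive run longer than 10 min (600 s) occurred.

    Episodes separated by gaps of at most ``gap_tolerance`` seconds count as
    one run; the default 0 requires a strictly contiguous run.
    """
    merged = merge_episodes(series.episodes, warn=False)
    run_start = run_end = None
    longest = 0.0
    for s, e, _ in merged:
        if run_end is not None and s - run_end <= gap_tolerance:
            run_end = max(run_end, e)
        else:
            run_start, run_end = s, e
        longest = max(longest, run_end - run_start)
    return longest > threshold_s


def summarize(series: ScoreSeries, gap_tolerance: float = 0.0) -> BehavioralSummary:
    """All per-animal endpoints for one score series."""
    latency, duration = latency_and_duration(series)
    return BehavioralSummary(
        latency=latency,
        total_duration=duration,
        average_score=average_score(series),
        status_epilepticus=status_epilepticus(series, gap_tolerance=gap_tolerance),
        died=series.died,
    )


def group_summary(animals: Sequence[BehavioralSummary]) -> Dict[str, float]:
    """Group-level endpoint statistics for one treatment group.

    Returns means/medians of the continuous endpoints (latency over animals
    that convulsed), the status-epilepticus and mortality proportions, and
    the raw counts needed to build 2x2 tables for exact tests.
    """
    if len(animals) < 1:
        raise ValueError("animals: need at least one animal")
    lat = [a.latency for a in animals if a.latency is not None]
    dur = [a.total_duration for a in animals]
    avg = [a.average_score for a in animals]
    n = len(animals)
    n_se = sum(a.status_epilepticus for a in animals)
    n_died = sum(a.died for a in animals)
    return {
        "n": n,
        "latency_mean_s": float(np.mean(lat)) if lat else float("nan"),
        "latency_median_s": float(np.median(lat)) if lat else float("nan"),
        "duration_mean_s": float(np.mean(dur)),
        "duration_median_s": float(np.median(dur)),
        "average_score_mean": float(np.mean(avg)),
        "average_score_median": float(np.median(avg)),
        "n_status_epilepticus": int(n_se),
        "status_epilepticus_proportion": n_se / n,
        "n_died": int(n_died),
        "mortality_proportion": n_died / n,
    }


def contingency_table(group_a: Dict[str, float], group_b: Dict[str, float],
                      endpoint: str) -> Table2x2:
    """2x2 outcome table (rows = groups, columns = yes/no) for an exact test.

    ``endpoint`` is ``"status_epilepticus"`` or ``"mortality"``.
    """
    key = {"status_epilepticus": "n_status_epilepticus", "mortality": "n_died"}.get(endpoint)
    if key is None:
        raise ValueError("endpoint: must be 'status_epilepticus' or 'mortality'")
    a, na = int(group_a[key]), int(group_a["n"])
    b, nb = int(group_b[key]), int(group_b["n"])
    return Table2x2(a, na - a, b, nb - b)
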