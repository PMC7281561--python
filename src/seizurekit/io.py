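"""Readers and writers for sweeps and result tables.

Sweeps travel as HDF5 (dataset ``current_pa`` with attrs ``sampling_rate``,
``stimulus_times``, ``holding_potential``, ``id``) or as two-column CSV
(``time_s, current_pa``) with the metadata in ``#``-prefixed header lines.
Event, staircase and score tables are plain CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .types import EventRecord, ScoreSeries, StaircaseTable, Sweep

__all__ = [
    "write_sweep_hdf5", "read_sweep_hdf5",
    "write_sweep_csv", "read_sweep_csv",
    "events_to_frame", "write_events_csv", "read_events_csv",
    "write_staircase_csv", "read_staircase_csv",
    "write_score_series_csv", "read_score_series_csv",
]

PathLike = Union[str, Path]


def write_sweep_hdf5(sweep: Sweep, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("current_pa", data=sweep.values)
        ds.attrs["sampling_rate"] = sweep.sampling_rate
        ds.attrs["stimulus_times"] = np.asarray(sweep.stimulus_times, dtype=float)
        ds.attrs["holding_potential"] = sweep.holding_potential
        ds.attrs["id"] = sweep.id


def read_sweep_hdf5(path: PathLike) -> Sweep:
    if not Path(path).exists():
        raise FileNotFoundError(f"sweep file not found: {path}")
    with h5py.File(path, "r") as f:
        ds = f["current_pa"]
        return Sweep(
            values=ds[()],
            sampling_rate=float(ds.attrs["sampling_rate"]),
            stimulus_times=tuple(np.atleast_1d(ds.attrs.get("stimulus_times", []))),
            holding_potential=float(ds.attrs.get("holding_potential", 0.0)),
            id=str(ds.attrs.get("id", "")),
        )


def write_sweep_csv(sweep: Sweep, path: PathLike) -> None:
    stim = ",".join(repr(t) for t in sweep.stimulus_times)
    header = (
        f"# sampling_rate={sweep.sampling_rate!r}\n"
        f"# stimulus_times={stim}\n"
        f"# holding_potential={sweep.holding_potential!r}\n"
        f"# id={sweep.id}\n"
        "time_s,current_pa\n"
    )
    t = sweep.times
    with open(path, "w") as f:
        f.write(header)
        np.savetxt(f, np.column_stack([t, sweep.values]), fmt="%.9g", delimiter=",")


def read_sweep_csv(path: PathLike) -> Sweep:
    if not Path(path).exists():
        raise FileNotFoundError(f"sweep file not found: {path}")
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    df = pd.read_csv(path, comment="#")
    stim = tuple(float(x) for x in meta.get("stimulus_times", "").split(",") if x)
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    rate = float(meta.get("sampling_rate", 1.0 / dt))
    return Sweep(values=df["current_pa"].to_numpy(), sampling_rate=rate,
                 stimulus_times=stim,
                 holding_potential=float(meta.get("holding_potential", 0.0)),
                 id=meta.get("id", ""))


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset, e.offset, e.type, e.peak_amplitude,
          e.half_width if e.half_width is not None else np.nan,
          e.has_negative_phase) for e in events],
        columns=["onset_s", "offset_s", "type", "peak_pa", "half_width_ms",
                 "has_negative_phase"],
    )


def write_events_csv(events: Sequence[EventRecord], path: PathLike) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: PathLike) -> List[EventRecord]:
    if not Path(path).exists():
        raise FileNotFoundError(f"event table not found: {path}")
    df = pd.read_csv(path)
    return [
        EventRecord(type=r.type, onset=r.onset_s, offset=r.offset_s,
                    peak_amplitude=r.peak_pa,
                    half_width=None if pd.isna(r.half_width_ms) else float(r.half_width_ms),
                    has_negative_phase=bool(r.has_negative_phase))
        for r in df.itertuples()
    ]


def write_staircase_csv(table: StaircaseTable, path: PathLike) -> None:
    df = table.records.copy()
    df.attrs = {}
    with open(path, "w") as f:
        f.write("# ladder_ma=" + ",".join(repr(x) for x in table.ladder) + "\n")
        df.to_csv(f, index=False)


def read_staircase_csv(path: PathLike) -> StaircaseTable:
    if not Path(path).exists():
        raise FileNotFoundError(f"staircase table not found: {path}")
    with open(path) as f:
        first = f.readline()
    if first.startswith("# ladder_ma="):
        ladder = tuple(float(x) for x in first.split("=", 1)[1].split(","))
    else:
        ladder = None
    df = pd.read_csv(path, comment="#")
    if ladder is None:
        ladder = tuple(sorted(df["current_ma"].unique()))
    if "clipped" not in df:
        df["clipped"] = False
    return StaircaseTable(records=df, ladder=ladder)


def write_score_series_csv(series_list: Sequence[ScoreSeries], path: PathLike) -> None:
    rows = []
    for s in series_list:
        if s.episodes:
            for start, end, score in s.episodes:
                rows.append((s.id, start, end, score, s.died, s.window))
        else:
            rows.append((s.id, np.nan, np.nan, np.nan, s.died, s.window))
    pd.DataFrame(rows, columns=["animal_id", "start_s", "end_s", "score", "died",
                                "window_s"]).to_csv(path, index=False)


def read_score_series_csv(path: PathLike) -> List[ScoreSeries]:
    if not Path(path).exists():
        raise FileNotFoundError(f"score table not found: {path}")
    df = pd.read_csv(path)
    out = []
    for animal, grp in df.groupby("animal_id", sort=False):
        eps = [(r.start_s, r.end_s, int(r.score)) for r in grp.itertuples()
               if not pd.isna(r.start_s)]
        out.append(ScoreSeries(episodes=tuple(eps), window=float(grp["window_s"].iloc[0]),
                               died=bool(grp["died"].iloc[0]), id=str(animal)))
    return out
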