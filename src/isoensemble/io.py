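"""Plain-text and HDF5 persistence for pipeline artifacts.

CSV schemas
-----------
tournament:   day, mouse_a, mouse_b, winner
lick stream:  mouse, condition, spout, time_s
bout table:   start_s, end_s, n_licks, spout
event series: start_s, end_s, label           (BED-like interval table)
identity map: global_id, session, local_id

Calcium traces, frame times and event times live in one HDF5 container:

    /traces                float (neurons x frames)
    /frame_times_s         float (frames,)
    /events/<class>        float event times (s)

Datasets are written with ``track_times=False`` so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import LickStream, TournamentRecord
from .pose import EventSeries

__all__ = [
    "write_tournament", "read_tournament",
    "write_lick_streams", "read_lick_streams",
    "write_event_series", "read_event_series",
    "write_identity_map", "read_identity_map",
    "write_population_h5", "read_population_h5",
    "write_json",
]


def write_tournament(record: TournamentRecord, path) -> None:
    record.trials.to_csv(path, index=False)


def read_tournament(path) -> TournamentRecord:
    return TournamentRecord(pd.read_csv(path))


def write_lick_streams(streams: list[LickStream], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "mouse": s.mouse,
                "condition": s.condition,
                "spout": s.spout,
                "time_s": s.lick_times_s,
            }
        )
        for s in streams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_lick_streams(path) -> list[LickStream]:
    df = pd.read_csv(path)
    out = []
    for (mouse, condition, spout), sub in df.groupby(
        ["mouse", "condition", "spout"], sort=True
    ):
        out.append(
            LickStream(
                np.sort(sub["time_s"].to_numpy()),
                spout,
                mouse=mouse,
                condition=condition,
            )
        )
    return out


def write_event_series(series: EventSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_event_series(path) -> EventSeries:
    df = pd.read_csv(path)
    label = df["label"].iloc[0] if len(df) else "interaction"
    return EventSeries(df[["start_s", "end_s"]].to_numpy(), label=label)


def write_identity_map(idmap: pd.DataFrame, path) -> None:
    idmap.to_csv(path, index=False)


def read_identity_map(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_population_h5(
    path,
    traces: np.ndarray,
    frame_times_s: np.ndarray,
    events: dict[str, np.ndarray] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=np.asarray(traces, float), track_times=False)
        f.create_dataset(
            "frame_times_s", data=np.asarray(frame_times_s, float), track_times=False
        )
        g = f.create_group("events")
        for cls, times in (events or {}).items():
            g.create_dataset(cls, data=np.asarray(times, float), track_times=False)


def read_population_h5(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    with h5py.File(path, "r") as f:
        traces = f["traces"][()]
        ft = f["frame_times_s"][()]
        events = {k: f["events"][k][()] for k in f["events"]}
    return traces, ft, events


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict("records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
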