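"""Plain-text readers and writers for every table format in the pipeline.

Formats: POR matrix as CSV with an odor-id header row and locust-id index;
spike data as a long CSV (pn_id, odor_id, trial, spike_time_s) with a JSON
sidecar carrying the window spec, panel metadata and the full key
enumeration (so spike-free trials survive round trips); POR traces as a
long CSV (locust_id, odor_id, frame, separation) plus a JSON sidecar.
Malformed rows are reported with their line number, never dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PORMatrix, PORTrace, SpikeDataset, WindowSpec

__all__ = [
    "write_por_matrix",
    "read_por_matrix",
    "write_spike_dataset",
    "read_spike_dataset",
    "write_traces",
    "read_traces",
    "write_json",
    "read_json",
]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_por_matrix(matrix: PORMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="locust_id")


def read_por_matrix(path) -> PORMatrix:
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: header-only or empty POR matrix")
    arr = frame.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {i + 2}: entry {arr[i, j]!r} in column "
            f"{frame.columns[j]!r} is not 0/1"
        )
    return PORMatrix.from_frame(frame)


def write_spike_dataset(dataset: SpikeDataset, table_path, sidecar_path) -> None:
    dataset.to_frame().to_csv(table_path, index=False)
    sidecar = {
        "window": {
            "baseline": dataset.window.baseline,
            "on": dataset.window.on,
            "off": dataset.window.off,
        },
        "panel": {k: list(v) for k, v in dataset.panel.items()},
        "pn_ids": dataset.pn_ids,
        "odor_ids": dataset.odor_ids,
        "n_trials": dataset.n_trials,
    }
    write_json(sidecar, sidecar_path)


def read_spike_dataset(table_path, sidecar_path) -> SpikeDataset:
    sidecar = read_json(sidecar_path)
    frame = pd.read_csv(table_path)
    required = ["pn_id", "odor_id", "trial", "spike_time_s"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{table_path}: missing columns {missing}")
    trials = pd.to_numeric(frame["trial"], errors="coerce")
    bad = trials.isna() | (trials < 0) | (trials != trials.astype("Int64").astype(float))
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{table_path}: line {row + 2}: invalid trial index {frame.trial[row]!r}")
    times = pd.to_numeric(frame["spike_time_s"], errors="coerce")
    if (~np.isfinite(times)).any():
        row = int((~np.isfinite(times)).idxmax())
        raise ValueError(
            f"{table_path}: line {row + 2}: non-finite spike time {frame.spike_time_s[row]!r}"
        )
    frame["trial"] = trials.astype(int)
    keys = pd.DataFrame(
        [
            (pn, odor, t)
            for pn in sidecar["pn_ids"]
            for odor in sidecar["odor_ids"]
            for t in range(sidecar["n_trials"])
        ],
        columns=["pn_id", "odor_id", "trial"],
    )
    window = WindowSpec(**sidecar["window"])
    panel = {k: tuple(v) for k, v in sidecar.get("panel", {}).items()}
    return SpikeDataset.from_frame(frame, window, panel, keys=keys)


def write_traces(traces: list[PORTrace], table_path, sidecar_path) -> None:
    parts = []
    meta = {}
    for t in traces:
        key = f"{t.locust_id}|{t.odor_id}"
        meta[key] = {"onset": t.onset, "offset": t.offset, "fps": t.fps}
        parts.append(
            pd.DataFrame(
                {
                    "locust_id": t.locust_id,
                    "odor_id": t.odor_id,
                    "frame": np.arange(t.n_frames),
                    "separation": t.separation,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(table_path, index=False)
    write_json(meta, sidecar_path)


def read_traces(table_path, sidecar_path) -> list[PORTrace]:
    meta = read_json(sidecar_path)
    frame = pd.read_csv(table_path)
    sep = pd.to_numeric(frame["separation"], errors="coerce")
    if sep.isna().any() or (sep < 0).any():
        row = int((sep.isna() | (sep < 0)).idxmax())
        raise ValueError(
            f"{table_path}: line {row + 2}: invalid separation {frame.separation[row]!r}"
        )
    traces = []
    for (locust, odor), grp in frame.groupby(["locust_id", "odor_id"], sort=False):
        m = meta[f"{locust}|{odor}"]
        grp = grp.sort_values("frame")
        traces.append(
            PORTrace(
                grp["separation"].to_numpy(),
                int(m["onset"]),
                int(m["offset"]),
                str(locust),
                str(odor),
                float(m["fps"]),
            )
        )
    return traces
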