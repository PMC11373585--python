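"""Plain-text readers/writers: CSV series with JSON sidecars.

Traces travel as two-column CSV (time_s, voltage_V) plus a JSON sidecar
holding sampling rate, cue times and (for synthetic traces) ground-truth
event spans; resistance series as (time_s, resistance_ohm) CSV with the
cycle timing in the sidecar.  External recordings in the same layout can
enter the pipeline at either point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import Detection
from .device import ResistanceSeries
from .synthetic import LfpTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_resistance_series",
    "read_resistance_series",
    "write_detections",
    "read_detections",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: LfpTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "voltage_V": trace.samples}).to_csv(
        path, index=False
    )
    meta = {
        "sampling_rate": trace.sampling_rate,
        "t0": trace.t0,
        "cue_times": None if trace.cue_times is None else trace.cue_times.tolist(),
        "event_spans": trace.ground_truth_event_spans,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> LfpTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    spans = meta.get("event_spans")
    return LfpTrace(
        samples=df["voltage_V"].to_numpy(),
        sampling_rate=meta["sampling_rate"],
        t0=meta.get("t0", 0.0),
        cue_times=None if meta.get("cue_times") is None else np.array(meta["cue_times"]),
        ground_truth_event_spans=None if spans is None else [tuple(s) for s in spans],
    )


def write_resistance_series(series: ResistanceSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": series.times, "resistance_ohm": series.readouts}).to_csv(
        path, index=False
    )
    meta = {
        "cycle_period": series.cycle_period,
        "cycles_per_readout": series.cycles_per_readout,
        "initial_resistance": series.initial_resistance,
        "t0": series.t0,
        "cue_times": None if series.cue_times is None else series.cue_times.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_resistance_series(path: str | Path) -> ResistanceSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return ResistanceSeries(
        times=df["time_s"].to_numpy(),
        readouts=df["resistance_ohm"].to_numpy(),
        cycle_period=meta["cycle_period"],
        cycles_per_readout=meta["cycles_per_readout"],
        initial_resistance=meta["initial_resistance"],
        cue_times=None if meta.get("cue_times") is None else np.array(meta["cue_times"]),
        t0=meta.get("t0", 0.0),
    )


def write_detections(detections: list[Detection], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "t_flag_s": [d.t_flag for d in detections],
            "batch_index": [d.batch_index for d in detections],
            "strategy": [d.strategy for d in detections],
            "biomarker_ohm": [d.value for d in detections],
            "r_init_ohm": [d.r_init for d in detections],
        }
    ).to_csv(path, index=False)
    return path


def read_detections(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            t_flag=row.t_flag_s,
            batch_index=int(row.batch_index),
            strategy=row.strategy,
            value=row.biomarker_ohm,
            r_init=row.r_init_ohm,
        )
        for row in df.itertuples()
    ]
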