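"""End-to-end experiment runner: synthesis -> front end -> device ->
detection -> evaluation -> energy, with seeding and plain-text artifacts.

A run is fully determined by ``(RunConfig, seed)``: one root seed feeds
independent child streams for the cue schedule, the trace generator and
the device noise, so artifacts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import io as mio
from .config import RunConfig
from .detection import Detection, batch_end_times, run_detector
from .device import ResistanceSeries, simulate_mis
from .energy import budget
from .frontend import condition
from .synthetic import LfpTrace, generate_cue_schedule, generate_lfp

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "derive_seeds", "run_experiment", "sweep"]

_MAX_SEED = 2**31


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (each below 2**31) from one root seed."""
    return [int(s) % _MAX_SEED for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class RunResult:
    config: RunConfig
    trace: LfpTrace
    amplified: LfpTrace
    series: ResistanceSeries
    windows: list[ev.EventWindow]
    detections: list[Detection]
    counts: ev.ConfusionCounts
    metrics: ev.Metrics
    latencies: np.ndarray
    report: dict


def _simulate_session(config: RunConfig, seed: int):
    """Schedule + trace + front end + device for one seeded session."""
    s_sched, s_synth, s_dev = derive_seeds(seed, 3)
    schedule = generate_cue_schedule(
        config.duration, config.mean_cue_interval, config.cue_jitter_sd, seed=s_sched
    )
    params = replace(config.synthetic, seed=s_synth)
    trace = generate_lfp(schedule, params)
    amplified, device_trace = condition(trace, config.frontend)
    rng = np.random.default_rng(s_dev)
    series = simulate_mis(device_trace, config.device, config.timing, rng=rng)
    windows = ev.extract_event_windows(
        amplified,
        search_horizon=config.evaluation.search_horizon,
        prominence_factor=config.evaluation.prominence_factor,
    )
    return trace, amplified, series, windows


def _evaluate(config: RunConfig, series, windows):
    detections = run_detector(series, config.detection)
    bt = batch_end_times(series, config.detection.batch_size)
    counts = ev.score_detections(detections, windows, bt.size, bt)
    m = ev.metrics(counts)
    latencies = ev.detection_latency(detections, windows)
    return detections, counts, m, latencies


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Run the full chain; optionally write all artifacts to ``out_dir``."""
    trace, amplified, series, windows = _simulate_session(config, config.seed)
    detections, counts, m, latencies = _evaluate(config, series, windows)
    energy_report = budget(config.energy)
    report = {
        "config": config.to_dict(),
        "n_cues": int(trace.cue_times.size),
        "n_windows": len(windows),
        "n_batches": int(batch_end_times(series, config.detection.batch_size).size),
        "n_detections": len(detections),
        "counts": dataclasses.asdict(counts),
        "metrics": dataclasses.asdict(m),
        "median_latency_s": (
            float(np.median(latencies)) if latencies.size else None
        ),
        "latencies_s": latencies.tolist(),
        "classification_rate_hz": 1.0 / (series.cycle_period * config.detection.batch_size),
        "energy": dataclasses.asdict(energy_report),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_trace(trace, out / "trace.csv")
        mio.write_resistance_series(series, out / "resistance.csv")
        mio.write_detections(detections, out / "detections.csv")
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return RunResult(
        config=config,
        trace=trace,
        amplified=amplified,
        series=series,
        windows=windows,
        detections=detections,
        counts=counts,
        metrics=m,
        latencies=latencies,
        report=report,
    )


def sweep(config: RunConfig, axis: str, values) -> pd.DataFrame:
    """One run per value of a dotted config parameter, aggregated.

    The axis is validated before any run.  Axes under ``detection`` or
    ``evaluation`` reuse a single simulated session (shared trace and
    readout series — the common-seed policy); any other axis reruns the
    full chain per value.
    """
    getattr_default(config, axis)  # validates the axis before any run
    values = list(values)
    rows = []
    detection_only = axis.split(".")[0] in ("detection", "evaluation")
    shared = _simulate_session(config, config.seed) if detection_only and values else None
    for v in values:
        cfg = config.with_value(axis, v)
        if detection_only:
            trace, amplified, series, windows = shared
        else:
            trace, amplified, series, windows = _simulate_session(cfg, cfg.seed)
        detections, counts, m, latencies = _evaluate(cfg, series, windows)
        rows.append(
            {
                axis: v,
                "n_detections": len(detections),
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "median_latency_s": float(np.median(latencies)) if latencies.size else None,
            }
        )
    return pd.DataFrame(rows)


def getattr_default(config: RunConfig, axis: str):
    """Current value of a dotted config parameter (validates the axis)."""
    if "." in axis:
        root, leaf = axis.split(".", 1)
        section = getattr(config, root, None)
        if section is None or not dataclasses.is_dataclass(section):
            raise ValueError(f"unknown config section {root!r}")
        if leaf not in {f.name for f in dataclasses.fields(type(section))}:
            raise ValueError(f"unknown key {leaf!r} in section {root!r}")
        return getattr(section, leaf)
    if axis not in {f.name for f in dataclasses.fields(type(config))}:
        raise ValueError(f"unknown config key {axis!r}")
    return getattr(config, axis)
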