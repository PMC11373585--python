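"""Batch-wise biomarker extraction and threshold classification.

Resistance readouts are grouped into non-overlapping batches of N cycles
(140 ms at N=70).  Each batch yields one scalar biomarker DeltaR by one
of three strategies:

    maxdiff  largest difference between consecutive readouts in the batch
    maxdrop  R_max - R_min within the batch
    batch    |R_init - R_end|  (only the batch's boundary readouts)

and a detection is flagged when ``biomarker > A * R_init``, with A a
dimensionless threshold coefficient (defaults 0.03 / 0.01 / 0.022 per
strategy).  R_init chains across batches: it is the most recent readout
before the batch (the device's initial resistance before the first one).

maxdiff uses the absolute consecutive difference by default: on a device
whose events register as resistive *drops*, the literal signed maximum
would be negative within an event and could never exceed the positive
threshold A*R_init.  ``signed_maxdiff=True`` restores the literal formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .device import ResistanceSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Strategy",
    "DetectionConfig",
    "BatchFeature",
    "Detection",
    "batch_series",
    "extract_feature",
    "extract_features",
    "classify",
    "run_detector",
    "batch_end_times",
]

Strategy = Literal["maxdiff", "maxdrop", "batch"]

#: calibrated threshold coefficients per strategy
DEFAULT_THRESHOLDS: dict[str, float] = {"maxdiff": 0.03, "maxdrop": 0.01, "batch": 0.022}


@dataclass(frozen=True)
class DetectionConfig:
    strategy: Strategy = "batch"
    batch_size: int = 70
    threshold_coefficient: float | None = None
    signed_maxdiff: bool = False

    def __post_init__(self):
        if self.strategy not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.threshold_coefficient is None:
            object.__setattr__(
                self, "threshold_coefficient", DEFAULT_THRESHOLDS[self.strategy]
            )
        if self.threshold_coefficient <= 0:
            raise ValueError("threshold_coefficient must be positive")

    @property
    def classification_rate_hz(self) -> float:
        """Detector output rate for a 500 Hz device cycle (device_rate/N)."""
        return 500.0 / self.batch_size


@dataclass(frozen=True)
class BatchFeature:
    """One batch's biomarker with its constituent readouts."""

    strategy: str
    batch_index: int
    t_end: float
    value: float
    r_init: float
    r_end: float
    r_max: float
    r_min: float


@dataclass(frozen=True)
class Detection:
    t_flag: float
    batch_index: int
    strategy: str
    value: float
    r_init: float


def batch_series(readouts: np.ndarray, n: int) -> list[np.ndarray]:
    """Split readouts into consecutive non-overlapping groups of ``n``.

    A trailing partial batch is dropped (logged); a series shorter than
    one batch yields an empty list with a warning.
    """
    if n < 2:
        raise ValueError("batch size must be >= 2")
    readouts = np.asarray(readouts, dtype=float)
    n_batches = readouts.size // n
    if n_batches == 0:
        logger.warning("series of %d readouts shorter than one batch (N=%d)", readouts.size, n)
        return []
    dropped = readouts.size - n_batches * n
    if dropped:
        logger.info("dropping trailing partial batch of %d readouts", dropped)
    return [readouts[i * n : (i + 1) * n] for i in range(n_batches)]


def extract_feature(
    batch: np.ndarray,
    strategy: Strategy,
    r_init: float,
    signed_maxdiff: bool = False,
) -> float:
    """Biomarker value for one batch of readouts, given its R_init."""
    batch = np.asarray(batch, dtype=float)
    if batch.size == 0:
        raise ValueError("empty batch")
    if strategy == "maxdiff":
        if batch.size < 2:
            raise ValueError("maxdiff requires >= 2 readouts per batch")
        d = np.diff(batch)
        return float(d.max()) if signed_maxdiff else float(np.abs(d).max())
    if strategy == "maxdrop":
        if batch.size < 2:
            raise ValueError("maxdrop requires >= 2 readouts per batch")
        return float(batch.max() - batch.min())
    if strategy == "batch":
        return float(abs(r_init - batch[-1]))
    raise ValueError(f"unknown strategy {strategy!r}")


def extract_features(series: ResistanceSeries, config: DetectionConfig) -> list[BatchFeature]:
    """Batch a readout series and compute one biomarker per batch.

    Handles both readout modes: a per-cycle series carries N readouts per
    batch; a per-batch series carries exactly one (its R_end), which only
    the batch strategy can consume.  R_init chains to the last readout of
    the previous batch; the first batch uses the series' initial
    resistance (per-batch mode) or its own first readout (per-cycle mode,
    where that readout is the earliest information available).
    """
    n = config.batch_size
    stride = series.cycles_per_readout
    if n % stride != 0:
        raise ValueError(
            f"batch_size {n} must be a multiple of the series readout stride {stride}"
        )
    per_batch = n // stride
    if per_batch == 1:
        if config.strategy != "batch":
            raise ValueError(
                f"{config.strategy} needs per-cycle readouts; this series reads "
                f"once per {stride} cycles"
            )
        groups = [np.array([r]) for r in series.readouts]
        r_init = series.initial_resistance
    else:
        if stride != 1:
            raise ValueError("mixed readout strides are not supported")
        groups = batch_series(series.readouts, n)
        r_init = groups[0][0] if groups else np.nan
    feats: list[BatchFeature] = []
    for b, grp in enumerate(groups):
        value = extract_feature(grp, config.strategy, r_init, config.signed_maxdiff)
        # same float ops as batch_end_times so timestamps match exactly
        t_end = series.t0 + (n * series.cycle_period) * (b + 1)
        feats.append(
            BatchFeature(
                strategy=config.strategy,
                batch_index=b,
                t_end=t_end,
                value=value,
                r_init=float(r_init),
                r_end=float(grp[-1]),
                r_max=float(grp.max()),
                r_min=float(grp.min()),
            )
        )
        r_init = grp[-1]
    return feats


def classify(value: float, r_init: float, a: float) -> bool:
    """Threshold rule: detection iff ``value > a * r_init`` (strict)."""
    if a <= 0:
        raise ValueError("threshold coefficient must be positive")
    return value > a * r_init


def run_detector(series: ResistanceSeries, config: DetectionConfig) -> list[Detection]:
    """One classification per batch; detections timestamped at batch end."""
    a = config.threshold_coefficient
    return [
        Detection(
            t_flag=f.t_end,
            batch_index=f.batch_index,
            strategy=f.strategy,
            value=f.value,
            r_init=f.r_init,
        )
        for f in extract_features(series, config)
        if classify(f.value, f.r_init, a)
    ]


def batch_end_times(series: ResistanceSeries, batch_size: int) -> np.ndarray:
    """End times of every full batch in the series (the TN grid)."""
    per_batch = batch_size // series.cycles_per_readout
    n_batches = len(series) // per_batch
    return series.t0 + (batch_size * series.cycle_period) * (1 + np.arange(n_batches))
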