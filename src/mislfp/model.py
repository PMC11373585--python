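"""Threshold-calibration model with a statsmodels-flavored fit/results API.

The only data-fitted quantity in the MIS pipeline is the threshold
coefficient A of the classifier ``DeltaR > A * R_init``.
:class:`MisThresholdModel` holds a labelled session (a resistance-readout
series plus its ground-truth event windows); ``fit()`` sweeps A over a
grid, traces the ROC curve, picks the minimal-secant operating point and
returns a :class:`MisThresholdResults` carrying the calibrated A*, the
confusion counts and metrics at that point, the detection latencies and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation as ev
from .detection import DetectionConfig, batch_end_times, run_detector
from .device import DeviceParams, MisTiming, ResistanceSeries, simulate_mis
from .frontend import FrontendParams, condition
from .synthetic import LfpTrace

__all__ = ["MisThresholdModel", "MisThresholdResults"]


class MisThresholdModel:
    """Calibrate the detection threshold on one labelled session.

    Parameters
    ----------
    series : ResistanceSeries
        Memristor readouts for the session.
    windows : list of EventWindow
        Ground-truth event windows on the matching filtered trace.
    strategy, batch_size :
        Biomarker strategy and batch length (cycles).
    a_grid, secant_angle :
        Threshold grid and secant angle for the operating-point search.
    """

    def __init__(
        self,
        series: ResistanceSeries,
        windows: list[ev.EventWindow],
        strategy: str = "batch",
        batch_size: int = 70,
        a_grid: np.ndarray | None = None,
        secant_angle: float = 45.0,
    ):
        self.series = series
        self.windows = windows
        self.config = DetectionConfig(strategy=strategy, batch_size=batch_size)
        kw = {} if a_grid is None else {"a_grid": np.asarray(a_grid, dtype=float)}
        self.search = ev.ThresholdSearchConfig(secant_angle=secant_angle, **kw)

    @classmethod
    def from_trace(
        cls,
        trace: LfpTrace,
        frontend: FrontendParams | None = None,
        device: DeviceParams | None = None,
        timing: MisTiming | None = None,
        search_horizon: float = 2.5,
        prominence_factor: float = 5.0,
        rng: np.random.Generator | None = None,
        **kwargs,
    ) -> "MisThresholdModel":
        """Build the model from a raw voltage trace with cue times.

        Runs the conditioning chain and the MIS simulation, and delimits
        event windows on the filtered amplified trace.
        """
        frontend = frontend or FrontendParams()
        device = device or DeviceParams()
        timing = timing or MisTiming()
        amplified, device_trace = condition(trace, frontend)
        series = simulate_mis(device_trace, device, timing, rng=rng)
        windows = ev.extract_event_windows(
            amplified, search_horizon=search_horizon, prominence_factor=prominence_factor
        )
        return cls(series, windows, **kwargs)

    def fit(self) -> "MisThresholdResults":
        """Sweep the threshold grid and select the minimal-secant optimum."""
        roc = ev.roc_sweep(self.series, self.windows, self.config, self.search)
        a_opt, opt_point = ev.optimal_threshold(roc, self.search.secant_angle)
        fitted = DetectionConfig(
            strategy=self.config.strategy,
            batch_size=self.config.batch_size,
            threshold_coefficient=a_opt,
        )
        detections = run_detector(self.series, fitted)
        bt = batch_end_times(self.series, self.config.batch_size)
        counts = ev.score_detections(detections, self.windows, bt.size, bt)
        return MisThresholdResults(
            model=self,
            a_opt=a_opt,
            opt_point=opt_point,
            roc=roc,
            detections=detections,
            counts=counts,
            metrics=ev.metrics(counts),
            latencies=ev.detection_latency(detections, self.windows),
        )


@dataclass
class MisThresholdResults:
    """Calibrated operating point and its diagnostics."""

    model: MisThresholdModel
    a_opt: float
    opt_point: tuple[float, float]
    roc: ev.RocCurve
    detections: list
    counts: ev.ConfusionCounts
    metrics: ev.Metrics
    latencies: np.ndarray

    @property
    def median_latency(self) -> float:
        return float(np.median(self.latencies)) if self.latencies.size else float("nan")

    @property
    def classification_rate_hz(self) -> float:
        return 1.0 / (self.model.series.cycle_period * self.model.config.batch_size)

    def summary(self) -> str:
        c, m = self.counts, self.metrics
        fmt = lambda x: "   n/a" if x is None else f"{x:6.4f}"
        lines = [
            "          MIS threshold calibration",
            "=" * 45,
            f"strategy: {self.model.config.strategy:<10} batch size N: {self.model.config.batch_size}",
            f"classification rate: {self.classification_rate_hz:.2f} Hz",
            f"secant angle: {self.model.search.secant_angle:.1f} deg   "
            f"grid points: {self.roc.a_values.size}",
            "-" * 45,
            f"optimal threshold A*       {self.a_opt:.4g}",
            f"operating point (FPR,TPR)  ({self.opt_point[0]:.3f}, {self.opt_point[1]:.3f})",
            f"ROC AUC                    {self.roc.auc():.4f}",
            "-" * 45,
            f"TP {c.tp:5d}   FP {c.fp:5d}   FN {c.fn:5d}   TN {c.tn:5d}",
            f"sensitivity  {fmt(m.sensitivity)}",
            f"specificity  {fmt(m.specificity)}",
            f"accuracy     {fmt(m.accuracy)}",
            f"median latency (s)         {self.median_latency:.3f}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve with the calibrated operating point highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, "-", label=f"{self.model.config.strategy}")
        ax.plot(*self.opt_point, "ro", label=f"A* = {self.a_opt:.3g}")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax
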