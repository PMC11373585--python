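"""Windowed detection scoring, ROC sweep, threshold optimization, latency.

Ground truth for scoring is the set of *event windows*: per cue, the
stretch of filtered LFP from the half-height crossing before the first
prominent peak to the half-height crossing after the last one.  Scoring
mixes granularities deliberately — TP/FN count windows, FP counts stray
detections, TN counts quiet batches — and sensitivity, specificity and
accuracy follow from the resulting confusion counts.

The threshold coefficient A is swept over a grid to trace a ROC curve;
the operating point is chosen by the minimal-secant rule: slide a line at
angle alpha (default 45 deg) across the curve and keep the point whose
perpendicular distance to the ideal-classifier corner's secant is
minimal.  At 45 deg this is exactly the maximizer of Youden's
J = TPR - FPR; other angles trade sensitivity against false alarms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .detection import DetectionConfig, Detection, classify, extract_features
from .device import ResistanceSeries
from .synthetic import LfpTrace

logger = logging.getLogger(__name__)

__all__ = [
    "EventWindow",
    "ConfusionCounts",
    "Metrics",
    "RocCurve",
    "ThresholdSearchConfig",
    "extract_event_windows",
    "windows_from_ground_truth",
    "score_detections",
    "metrics",
    "roc_sweep",
    "optimal_threshold",
    "detection_latency",
    "baseline_detect",
]


@dataclass(frozen=True)
class EventWindow:
    start: float
    end: float
    source_cue: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Windowed classification metrics; ``None`` marks an undefined ratio
    (zero denominator) rather than silently reporting 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    tpr: float | None
    fpr: float | None


@dataclass
class RocCurve:
    """(A, FPR, TPR) triples over a threshold grid, sorted by A."""

    a_values: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    strategy: str
    batch_size: int

    def __post_init__(self):
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        for arr, name in ((self.fpr, "FPR"), (self.tpr, "TPR")):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError(f"{name} must lie in [0, 1]")

    def auc(self) -> float:
        """Area under the curve with (0,0) and (1,1) endpoints appended."""
        fpr = np.concatenate([[0.0], self.fpr[::-1], [1.0]])
        tpr = np.concatenate([[0.0], self.tpr[::-1], [1.0]])
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(tpr[order], fpr[order]))


@dataclass(frozen=True)
class ThresholdSearchConfig:
    """Grid of threshold coefficients and the secant angle (degrees)."""

    a_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, -1, 200)
    )
    secant_angle: float = 45.0

    def __post_init__(self):
        grid = np.asarray(self.a_grid, dtype=float)
        object.__setattr__(self, "a_grid", grid)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("a_grid must be positive and strictly increasing")
        if not 0 < self.secant_angle < 90:
            raise ValueError("secant_angle must be in (0, 90) degrees")


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _half_height_crossing(
    t: np.ndarray, y: np.ndarray, peak_idx: int, half: float, direction: int
) -> float:
    """Time where |signal| crosses ``half`` walking from a peak.

    ``direction`` -1 walks backward (window start), +1 forward (window
    end).  Linear interpolation between the bracketing samples; falls back
    to the segment edge if the signal never dips below half.
    """
    i = peak_idx
    n = y.size
    while 0 <= i < n and y[i] >= half:
        i += direction
    if i < 0:
        return t[0]
    if i >= n:
        return t[-1]
    j = i - direction  # last index still >= half
    y0, y1 = y[j], y[i]
    if y0 == y1:
        return t[i]
    frac = (y0 - half) / (y0 - y1)
    return float(t[j] + frac * (t[i] - t[j]))


def extract_event_windows(
    trace: LfpTrace,
    cues: np.ndarray | None = None,
    search_horizon: float = 2.5,
    prominence_factor: float = 5.0,
) -> list[EventWindow]:
    """Delimit one event window per cue on the filtered trace.

    Prominent peaks are peaks of the rectified signal with prominence at
    least ``prominence_factor`` times the trace's median absolute
    deviation, searched in ``[cue, cue + search_horizon]``.  The window
    runs from the half-height crossing before the first such peak to the
    half-height crossing after the last.  Cues with no prominent peak
    yield no window; overlapping windows from adjacent cues are merged
    (keeping the earlier source cue) with a warning.
    """
    if cues is None:
        cues = trace.cue_times
    if cues is None:
        raise ValueError("no cue times available")
    y = np.abs(trace.samples)
    t = trace.times
    prom = max(prominence_factor * _mad(trace.samples), 1e-12)
    peaks, _ = sps.find_peaks(y, prominence=prom)
    windows: list[EventWindow] = []
    for cue in cues:
        lo = np.searchsorted(t, cue)
        hi = np.searchsorted(t, cue + search_horizon)
        in_range = peaks[(peaks >= lo) & (peaks < hi)]
        if in_range.size == 0:
            logger.info("no prominent peak after cue at %.3f s; no window", cue)
            continue
        first, last = in_range[0], in_range[-1]
        start = _half_height_crossing(t, y, first, y[first] / 2.0, -1)
        end = _half_height_crossing(t, y, last, y[last] / 2.0, +1)
        start = max(start, float(cue) + np.finfo(float).eps)
        windows.append(EventWindow(start=start, end=end, source_cue=float(cue)))
    merged: list[EventWindow] = []
    for w in windows:
        if merged and w.start <= merged[-1].end:
            warnings.warn(
                f"event windows from cues {merged[-1].source_cue:.3f} and "
                f"{w.source_cue:.3f} s overlap; merged"
            )
            prev = merged.pop()
            w = EventWindow(
                start=prev.start, end=max(prev.end, w.end), source_cue=prev.source_cue
            )
        merged.append(w)
    return merged


def windows_from_ground_truth(trace: LfpTrace) -> list[EventWindow]:
    """Event windows taken directly from a synthetic trace's recorded
    event spans (paired with its cue times).  Useful when noise is too
    heavy for reliable peak-based window extraction but the generator's
    truth is available."""
    if trace.ground_truth_event_spans is None or trace.cue_times is None:
        raise ValueError("trace carries no ground-truth event spans")
    out = []
    cues = np.asarray(trace.cue_times, dtype=float)
    for start, end in trace.ground_truth_event_spans:
        prior = cues[cues <= start]
        cue = float(prior[-1]) if prior.size else float(start)
        out.append(EventWindow(start=float(start), end=float(end), source_cue=cue))
    return out


def _window_membership(t: np.ndarray, windows: list[EventWindow]) -> np.ndarray:
    """Index of the window containing each time (-1 if none).

    Windows are sorted and non-overlapping by construction.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if not windows:
        return np.full(t.size, -1)
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = (idx >= 0) & (t <= ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


def score_detections(
    detections: list[Detection],
    windows: list[EventWindow],
    n_batches: int,
    batch_times: np.ndarray,
) -> ConfusionCounts:
    """Windowed confusion counts.

    TP: windows holding at least one detection (several in one window are
    grouped into a single behavioral detection).  FN: windows with none.
    FP: every detection flagged outside all windows.  TN: batches whose
    end time lies outside all windows and which produced no detection.
    """
    batch_times = np.asarray(batch_times, dtype=float)
    det_times = np.array([d.t_flag for d in detections], dtype=float)
    if det_times.size:
        lo = np.clip(np.searchsorted(batch_times, det_times) - 1, 0, batch_times.size - 1)
        hi = np.clip(lo + 1, 0, batch_times.size - 1)
        on_grid = np.isclose(batch_times[lo], det_times, atol=1e-9) | np.isclose(
            batch_times[hi], det_times, atol=1e-9
        )
        if not on_grid.all():
            raise ValueError("detection timestamps must lie on the batch grid")
    return _score_times(det_times, windows, batch_times)


def _score_times(
    det_times: np.ndarray, windows: list[EventWindow], batch_times: np.ndarray
) -> ConfusionCounts:
    det_win = _window_membership(det_times, windows)
    tp = int(np.unique(det_win[det_win >= 0]).size)
    fn = len(windows) - tp
    fp = int(np.sum(det_win < 0))
    batch_win = _window_membership(batch_times, windows)
    outside = batch_win < 0
    flagged = np.zeros(batch_times.size, dtype=bool)
    if det_times.size and batch_times.size:
        idx = np.clip(np.searchsorted(batch_times, det_times) - 1, 0, batch_times.size - 1)
        for cand in (idx, np.clip(idx + 1, 0, batch_times.size - 1)):
            hit = np.isclose(batch_times[cand], det_times, atol=1e-9)
            flagged[cand[hit]] = True
    tn = int(np.sum(outside & ~flagged))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total; TPR = sensitivity, FPR = FP/(FP+TN)."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    acc = ratio(counts.tp + counts.tn, counts.tp + counts.tn + counts.fp + counts.fn)
    fpr = ratio(counts.fp, counts.fp + counts.tn)
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc, tpr=sens, fpr=fpr)


def roc_sweep(
    series: ResistanceSeries,
    windows: list[EventWindow],
    config: DetectionConfig,
    search: ThresholdSearchConfig | None = None,
) -> RocCurve:
    """Trace (FPR, TPR) over the threshold grid.

    Biomarkers are extracted once; only the threshold comparison and the
    windowed scoring are repeated per grid point.
    """
    if search is None:
        search = ThresholdSearchConfig()
    feats = extract_features(series, config)
    batch_times = np.array([f.t_end for f in feats])
    values = np.array([f.value for f in feats])
    r_inits = np.array([f.r_init for f in feats])
    fprs, tprs = [], []
    for a in search.a_grid:
        det_times = batch_times[values > a * r_inits]
        m = metrics(_score_times(det_times, windows, batch_times))
        fprs.append(np.nan if m.fpr is None else m.fpr)
        tprs.append(np.nan if m.tpr is None else m.tpr)
    return RocCurve(
        a_values=search.a_grid.copy(),
        fpr=np.array(fprs),
        tpr=np.array(tprs),
        strategy=config.strategy,
        batch_size=config.batch_size,
    )


def optimal_threshold(roc: RocCurve, secant_angle: float = 45.0) -> tuple[float, tuple[float, float]]:
    """Minimal-secant operating point.

    Equivalent to maximizing ``cos(a)*TPR - sin(a)*FPR`` over the curve
    (at 45 deg: Youden's J = TPR - FPR); ties break toward the smaller
    threshold coefficient.  Returns ``(A*, (FPR, TPR))``.
    """
    if roc.a_values.size == 0:
        raise ValueError("empty ROC curve")
    alpha = np.deg2rad(secant_angle)
    score = np.cos(alpha) * roc.tpr - np.sin(alpha) * roc.fpr
    idx = int(np.nanargmax(score))  # first max on the ascending-A grid
    return float(roc.a_values[idx]), (float(roc.fpr[idx]), float(roc.tpr[idx]))


def detection_latency(
    detections: list[Detection], windows: list[EventWindow]
) -> np.ndarray:
    """Cue-to-flag interval for every true-positive window.

    Per window holding at least one detection: first in-window flag time
    minus the source cue.  Summarize with the median.
    """
    det_times = np.sort(np.array([d.t_flag for d in detections], dtype=float))
    out = []
    for w in windows:
        inside = det_times[(det_times >= w.start) & (det_times <= w.end)]
        if inside.size:
            out.append(inside[0] - w.source_cue)
    return np.array(out)


def baseline_detect(
    trace: LfpTrace,
    cues: np.ndarray | None = None,
    sg_window: int = 51,
    sg_order: int = 3,
    prominence: float | None = None,
    search_horizon: float = 2.5,
) -> np.ndarray:
    """Software baseline: Savitzky-Golay smoothing plus peak picking.

    Without cues, returns all prominent peak times.  With cues, returns
    one detection time per cue — the first prominent peak within the
    search horizon (cues with none are skipped).
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    y = sps.savgol_filter(trace.samples, sg_window, sg_order)
    if prominence is None:
        prominence = max(5.0 * _mad(y), 1e-12)
    peaks, _ = sps.find_peaks(y, prominence=prominence)
    peak_times = trace.times[peaks] if peaks.size else np.array([])
    if cues is None:
        return peak_times
    out = []
    for cue in np.asarray(cues, dtype=float):
        after = peak_times[(peak_times >= cue) & (peak_times < cue + search_horizon)]
        if after.size:
            out.append(after[0])
    return np.array(out)
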