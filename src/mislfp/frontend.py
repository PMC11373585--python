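"""Analog conditioning chain: low-pass, gain/offset/clip, device-rate resampling.

Models the front end that turns a raw extracellular voltage into the
stimulus seen by the memristor: a Butterworth low-pass at 130 Hz isolates
the LFP band, a gain of ~1e4 with adjustable offset lifts the tens-of-
microvolt signal into the device's +/-3 V operating range, and the result
is decimated to the 500 Hz bias/read cycle rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import LfpTrace

logger = logging.getLogger(__name__)

__all__ = ["FrontendParams", "lowpass", "amplify_clip", "resample_to_device", "condition"]


@dataclass(frozen=True)
class FrontendParams:
    """Front-end settings.

    ``zero_phase`` selects forward-backward filtering (no group delay;
    detection windows are defined on this filtered trace).  The causal
    single-pass alternative, whose magnitude response is the textbook
    Butterworth ``|H(f)| = 1/sqrt(1+(f/fc)^(2*order))``, is available for
    latency studies.  ``polarity`` flips which LFP deflection maps to
    positive volts at the device.
    """

    filter_order: int = 6
    cutoff_hz: float = 130.0
    gain: float = 1e4
    offset: float = 0.0
    clip_volts: float = 3.0
    device_rate_hz: float = 500.0
    zero_phase: bool = True
    polarity: int = 1

    def __post_init__(self):
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be even and >= 2")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.clip_volts <= 0:
            raise ValueError("clip_volts must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


def lowpass(trace: LfpTrace, params: FrontendParams) -> LfpTrace:
    """Butterworth low-pass (bilinear-transform digital design).

    Zero-phase by default; cue metadata is carried through unchanged.
    """
    nyq = trace.sampling_rate / 2.0
    if params.cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {params.cutoff_hz} Hz must be below Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(params.filter_order, params.cutoff_hz, fs=trace.sampling_rate, output="sos")
    if params.zero_phase:
        y = sps.sosfiltfilt(sos, trace.samples)
    else:
        y = sps.sosfilt(sos, trace.samples)
    return trace.with_samples(y)


def amplify_clip(trace: LfpTrace, params: FrontendParams) -> LfpTrace:
    """Sample-wise ``clamp(polarity*gain*v + offset, -clip, +clip)``."""
    y = params.polarity * params.gain * trace.samples + params.offset
    return trace.with_samples(np.clip(y, -params.clip_volts, params.clip_volts))


def resample_to_device(trace: LfpTrace, device_rate_hz: float) -> LfpTrace:
    """Decimate a band-limited trace to the device stimulation rate.

    The signal is assumed already low-passed below ``device_rate_hz/2``,
    so uniform sample-picking needs no extra anti-alias stage.  A
    non-integer stride falls back to linear interpolation (logged).
    """
    if device_rate_hz <= 0:
        raise ValueError("device_rate_hz must be positive")
    stride = trace.sampling_rate / device_rate_hz
    if abs(stride - round(stride)) < 1e-9:
        y = trace.samples[:: int(round(stride))]
    else:
        logger.info(
            "non-integer resampling stride %.4f (%.1f -> %.1f Hz); interpolating",
            stride, trace.sampling_rate, device_rate_hz,
        )
        new_t = np.arange(0, trace.duration, 1.0 / device_rate_hz)
        y = np.interp(new_t, trace.times - trace.t0, trace.samples)
    out = LfpTrace(
        samples=y,
        sampling_rate=device_rate_hz,
        t0=trace.t0,
        cue_times=None if trace.cue_times is None else trace.cue_times.copy(),
        ground_truth_event_spans=trace.ground_truth_event_spans,
    )
    return out


def condition(trace: LfpTrace, params: FrontendParams) -> tuple[LfpTrace, LfpTrace]:
    """Full chain.  Returns ``(amplified, device_trace)``.

    ``amplified`` is the filtered, amplified trace at the original rate
    (event windows are delimited on it); ``device_trace`` is its
    decimation to the device stimulation rate.
    """
    filtered = lowpass(trace, params)
    amplified = amplify_clip(filtered, params)
    return amplified, resample_to_device(amplified, params.device_rate_hz)
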