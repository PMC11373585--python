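"""Phenomenological memristor model and the MIS bias/read cycle simulator.

The device is a bipolar, thresholded, weighted integrator with
nonvolatile analog state: voltages below the switching thresholds leave
the resistance untouched; suprathreshold voltage of one polarity drives
the resistance down toward the low resistive state (LRS), the opposite
polarity drives it up toward the high resistive state (HRS).  The update
rule is a linear-overdrive rate scaled by a parabolic boundary window,

    dR = -+ k * (|v| - v_th) * dt * w(R),
    w(R) = (R - R_lrs)(R_hrs - R) / ((R_hrs - R_lrs)/2)^2,

which is bounded, monotone per polarity, and saturates smoothly at the
rails — sufficient to reproduce the qualitative event-driven resistive
drops of the physical TiOx devices (LRS ~ 20 kOhm, HRS ~ 40 kOhm).

The memristive-integrating-sensor (MIS) cycle alternates a 10 us
programming pulse at the sampled LFP voltage with a non-disturbing
200 mV readout, at 500 Hz; in per-batch mode the readout runs only once
every N cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .synthetic import LfpTrace

__all__ = [
    "DeviceParams",
    "DeviceState",
    "MisTiming",
    "ResistanceSeries",
    "step",
    "read",
    "reset",
    "simulate_mis",
]


@dataclass(frozen=True)
class DeviceParams:
    """Memristor model constants.

    Rate constants default so that a full-scale 2 V oscillatory event
    (~10 suprathreshold 10 us pulses per half-cycle) moves the state by
    roughly a quarter of the HRS-LRS range; ``k_up < k_down`` reflects the
    usual SET/RESET asymmetry of bipolar oxide devices and is what lets a
    bipolar burst produce a net resistive drop.  ``auto_reset`` enables the
    on-demand emergency reset to HRS when the state saturates within
    ``reset_margin`` of LRS.  ``relax_tau`` (seconds) turns on the volatile
    variant: exponential relaxation toward HRS between cycles; ``None``
    keeps the device nonvolatile.
    """

    r_lrs: float = 20e3
    r_hrs: float = 40e3
    v_th_down: float = 1.0
    v_th_up: float = 1.0
    k_down: float = 5e7
    k_up: float = 1.25e7
    read_voltage: float = 0.2
    noise_sd: float = 0.0
    drift_sd: float = 0.0
    polarity_sign: int = 1
    window_floor: float = 0.25
    auto_reset: bool = False
    reset_margin: float = 2e3
    relax_tau: float | None = None

    def __post_init__(self):
        if not 0 < self.r_lrs < self.r_hrs:
            raise ValueError("require 0 < r_lrs < r_hrs")
        if self.v_th_down <= 0 or self.v_th_up <= 0:
            raise ValueError("switching thresholds must be positive")
        if self.read_voltage >= min(self.v_th_down, self.v_th_up):
            raise ValueError("read_voltage must be below both switching thresholds")
        if self.polarity_sign not in (-1, 1):
            raise ValueError("polarity_sign must be +1 or -1")
        if self.k_down < 0 or self.k_up < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("rate and noise constants must be >= 0")
        if not 0 <= self.window_floor <= 1:
            raise ValueError("window_floor must be in [0, 1]")


@dataclass
class DeviceState:
    """Current resistance of the device, always within [r_lrs, r_hrs]."""

    resistance: float


@dataclass(frozen=True)
class MisTiming:
    """Bias/read cycle timing: 2 ms period (500 Hz), 10 us program pulse,
    600 us readout; per-batch mode reads once every ``batch_size`` cycles."""

    cycle_period: float = 2e-3
    program_pulse_width: float = 10e-6
    read_duration: float = 600e-6
    readout_mode: Literal["per_cycle", "per_batch"] = "per_cycle"
    batch_size: int = 70

    def __post_init__(self):
        if self.program_pulse_width + self.read_duration >= self.cycle_period:
            raise ValueError("program + read must fit inside the cycle period")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.readout_mode not in ("per_cycle", "per_batch"):
            raise ValueError("readout_mode must be 'per_cycle' or 'per_batch'")


@dataclass
class ResistanceSeries:
    """Timestamped resistance readouts from one MIS run.

    ``cycles_per_readout`` is 1 in per-cycle mode and N in per-batch mode;
    ``initial_resistance`` seeds the R_init chain of the batch strategy.
    """

    times: np.ndarray
    readouts: np.ndarray
    cycle_period: float
    cycles_per_readout: int
    initial_resistance: float
    cue_times: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.readouts = np.asarray(self.readouts, dtype=float)
        if self.times.size != self.readouts.size:
            raise ValueError("times and readouts must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.readouts.size


def _boundary_window(r: float, p: DeviceParams) -> float:
    # Parabolic soft-saturation window, 1 at midrange, floored so the
    # state can still be driven off the rails (a pure parabola would pin
    # a device resting exactly at HRS or LRS forever).
    half = (p.r_hrs - p.r_lrs) / 2.0
    return max((r - p.r_lrs) * (p.r_hrs - r) / (half * half), p.window_floor)


def _step_resistance(
    r: float, v: float, dt: float, p: DeviceParams, rng: np.random.Generator | None
) -> float:
    """One programming pulse on a bare resistance value (shared by step and
    simulate_mis so the two paths are bit-identical)."""
    if not math.isfinite(v):
        raise ValueError("applied voltage must be finite")
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = p.polarity_sign * v
    if s > p.v_th_down:
        r = r - p.k_down * (abs(v) - p.v_th_down) * dt * _boundary_window(r, p)
    elif s < -p.v_th_up:
        r = r + p.k_up * (abs(v) - p.v_th_up) * dt * _boundary_window(r, p)
    if p.drift_sd > 0 and rng is not None:
        r += rng.normal(0.0, p.drift_sd)
    return min(max(r, p.r_lrs), p.r_hrs)


def step(
    state: DeviceState,
    v: float,
    dt: float,
    params: DeviceParams,
    rng: np.random.Generator | None = None,
) -> DeviceState:
    """Apply one programming pulse of width ``dt`` at voltage ``v``.

    Subthreshold voltage leaves the state unchanged (aside from optional
    drift noise); suprathreshold voltage moves it by the linear-overdrive
    rule, clamped to [r_lrs, r_hrs].
    """
    return DeviceState(resistance=_step_resistance(state.resistance, v, dt, params, rng))


def read(
    state: DeviceState, params: DeviceParams, rng: np.random.Generator | None = None
) -> float:
    """Non-disturbing readout: resistance plus cycle-to-cycle Gaussian noise.

    The 200 mV read voltage sits below both switching thresholds, so the
    state is never mutated by reading.
    """
    r = state.resistance
    if params.noise_sd > 0 and rng is not None:
        r += rng.normal(0.0, params.noise_sd)
    return r


def reset(state: DeviceState, params: DeviceParams) -> DeviceState:
    """On-demand emergency reset: return the device to HRS."""
    return DeviceState(resistance=params.r_hrs)


def simulate_mis(
    trace: LfpTrace,
    params: DeviceParams,
    timing: MisTiming,
    initial_resistance: float | None = None,
    rng: np.random.Generator | None = None,
) -> ResistanceSeries:
    """Run the full bias/read cycle over a device-rate voltage trace.

    Each input sample drives one programming pulse of width
    ``timing.program_pulse_width``; a readout is emitted every cycle
    (per_cycle) or every ``batch_size`` cycles (per_batch), timestamped at
    the end of its cycle.  With noise off the result equals sequential
    :func:`step` calls exactly.
    """
    rate = 1.0 / timing.cycle_period
    if not math.isclose(trace.sampling_rate, rate, rel_tol=1e-6):
        raise ValueError(
            f"trace sampling rate {trace.sampling_rate} Hz must equal the "
            f"cycle rate {rate} Hz; resample first"
        )
    r = params.r_hrs if initial_resistance is None else float(initial_resistance)
    r0 = r
    stride = 1 if timing.readout_mode == "per_cycle" else timing.batch_size
    reset_floor = params.r_lrs + params.reset_margin
    decay = None if params.relax_tau is None else math.exp(-timing.cycle_period / params.relax_tau)
    dt = timing.program_pulse_width
    samples = trace.samples
    n = samples.size

    noiseless = params.noise_sd == 0 and params.drift_sd == 0 and decay is None
    if noiseless:
        # State only moves on suprathreshold pulses; fill the constant
        # stretches in bulk.  Float-identical to the sequential loop.
        r_after = np.empty(n)
        thr = min(params.v_th_down, params.v_th_up)
        hot = np.flatnonzero(np.abs(samples) > thr)
        prev = 0
        for i in hot:
            r_after[prev:i] = r
            r = _step_resistance(r, float(samples[i]), dt, params, None)
            if params.auto_reset and r < reset_floor:
                r = params.r_hrs
            r_after[i] = r
            prev = i + 1
        r_after[prev:] = r
        reads_arr = r_after[stride - 1 :: stride]
        n_reads = reads_arr.size
        times_arr = trace.t0 + timing.cycle_period * stride * (1 + np.arange(n_reads))
    else:
        times: list[float] = []
        reads: list[float] = []
        for i in range(n):
            r = _step_resistance(r, float(samples[i]), dt, params, rng)
            if decay is not None:
                r = params.r_hrs + (r - params.r_hrs) * decay
            if params.auto_reset and r < reset_floor:
                r = params.r_hrs
            if (i + 1) % stride == 0:
                reads.append(read(DeviceState(resistance=r), params, rng))
                times.append(trace.t0 + (i + 1) * timing.cycle_period)
        reads_arr = np.array(reads)
        times_arr = np.array(times)
    return ResistanceSeries(
        times=times_arr,
        readouts=reads_arr,
        cycle_period=timing.cycle_period,
        cycles_per_readout=stride,
        initial_resistance=r0,
        cue_times=None if trace.cue_times is None else trace.cue_times.copy(),
        t0=trace.t0,
    )
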