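"""Synthetic cue schedules and LFP-like voltage traces.

Emulates the statistical structure of low-frequency extracellular
recordings around repeated auditory cues: a 1/f^beta background at a
target RMS (tens of microvolts, SNR below ~10 dB) and one cue-evoked
oscillatory burst per cue, onset delayed by a neural latency of roughly
450 ms, lasting ~1.7 s, with per-event amplitude variability.  Every
downstream stage of the package is testable against these traces and
their recorded ground-truth event spans without any external data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CueSchedule",
    "SyntheticParams",
    "LfpTrace",
    "generate_cue_schedule",
    "generate_lfp",
    "event_template",
]

#: minimum LFP bandwidth the sampling rate must support (Hz)
_LFP_BAND_HZ = 130.0


@dataclass(frozen=True)
class CueSchedule:
    """Times at which the auditory cue is played, within a session.

    Parameters
    ----------
    cue_times : ndarray
        Cue onsets in seconds, strictly increasing, all in ``[0, duration)``.
    duration : float
        Session length in seconds.
    """

    cue_times: np.ndarray
    duration: float

    def __post_init__(self):
        cues = np.asarray(self.cue_times, dtype=float)
        object.__setattr__(self, "cue_times", cues)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if cues.size:
            if np.any(np.diff(cues) <= 0):
                raise ValueError("cue_times must be strictly increasing")
            if cues[0] < 0 or cues[-1] >= self.duration:
                raise ValueError("cue_times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.cue_times.size


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings for one synthetic session.

    Defaults describe the emulated recordings: ~80 uV cue-evoked events
    over a ~30 uV RMS pink background (SNR < 10 dB), 450 ms mean neural
    latency, 1.68 s event duration (12 x 140 ms), 7 Hz event oscillation
    (inside the <130 Hz LFP band), sampled at 2 kHz.
    """

    sampling_rate: float = 2000.0
    background_rms: float = 30e-6
    background_spectrum_exponent: float = 1.0
    neural_latency_mean: float = 0.45
    neural_latency_sd: float = 0.05
    event_duration: float = 1.68
    event_peak_amplitude_mean: float = 80e-6
    event_peak_amplitude_sd: float = 15e-6
    event_oscillation_freq: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate < 2 * _LFP_BAND_HZ:
            raise ValueError(
                f"sampling_rate must be >= {2 * _LFP_BAND_HZ} Hz to cover the LFP band"
            )
        if self.event_peak_amplitude_mean < 0:
            raise ValueError("event_peak_amplitude_mean must be >= 0")
        if self.neural_latency_mean <= 0:
            raise ValueError("neural_latency_mean must be > 0")
        if self.background_rms < 0 or self.neural_latency_sd < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class LfpTrace:
    """A uniformly sampled voltage series with optional cue annotations.

    ``ground_truth_event_spans`` is populated only by the synthetic
    generator; external recordings carry cue times alone.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    cue_times: np.ndarray | None = None
    ground_truth_event_spans: list[tuple[float, float]] | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.cue_times is not None:
            self.cue_times = np.asarray(self.cue_times, dtype=float)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "LfpTrace":
        """Copy of this trace with new sample values and metadata untouched."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def generate_cue_schedule(
    duration: float, mean_interval: float, jitter_sd: float = 0.0, seed: int = 0
) -> CueSchedule:
    """Place cues on a jittered regular grid across a session.

    Cues sit at ``mean_interval/2 + k*mean_interval`` plus Gaussian jitter;
    jittered times that would break strict ordering or fall outside the
    session are dropped.  Zero jitter therefore yields the exact grid.
    """
    if duration <= 0 or mean_interval <= 0:
        raise ValueError("duration and mean_interval must be positive")
    if duration <= mean_interval:
        raise ValueError("duration must exceed mean_interval")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.arange(mean_interval / 2.0, duration, mean_interval)
    times = base + rng.normal(0.0, jitter_sd, size=base.size)
    times = times[(times >= 0) & (times < duration)]
    # enforce strict monotonicity by dropping any out-of-order stragglers
    keep = np.ones(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t <= last:
            keep[i] = False
        else:
            last = t
    return CueSchedule(cue_times=times[keep], duration=float(duration))


def event_template(
    t: np.ndarray, onset: float, duration: float, amplitude: float, freq: float
) -> np.ndarray:
    """Hann-enveloped sinusoidal burst evaluated at times ``t`` (seconds).

    Zero outside ``[onset, onset + duration]``.  This is the deterministic
    building block of every synthetic event: a bipolar oscillation whose
    positive and negative peaks swell and fade under the raised-cosine
    envelope.
    """
    t = np.asarray(t, dtype=float)
    u = (t - onset) / duration
    env = np.where((u >= 0) & (u <= 1), 0.5 * (1.0 - np.cos(2 * np.pi * u)), 0.0)
    return amplitude * env * np.sin(2 * np.pi * freq * (t - onset))


def _pink_noise(n: int, beta: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^beta, scaled to target RMS."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n)
    achieved = np.sqrt(np.mean(shaped**2))
    return shaped * (rms / achieved) if achieved > 0 else shaped


def generate_lfp(schedule: CueSchedule, params: SyntheticParams) -> LfpTrace:
    """Synthesize one session: shaped background plus one burst per cue.

    Per-event latency and peak amplitude are drawn from independent child
    streams of the root seed, so traces are bit-reproducible and changing
    e.g. the noise level does not perturb event placement.  Events running
    past the end of the trace are truncated (with a logged warning), and
    their recorded span is truncated to match.
    """
    n = int(round(schedule.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate

    root = np.random.SeedSequence(params.seed)
    ss_lat, ss_amp, ss_noise = root.spawn(3)
    rng_lat = np.random.default_rng(ss_lat)
    rng_amp = np.random.default_rng(ss_amp)
    rng_noise = np.random.default_rng(ss_noise)

    x = _pink_noise(n, params.background_spectrum_exponent, params.background_rms, rng_noise)

    spans: list[tuple[float, float]] = []
    prev_end = -np.inf
    for cue in schedule.cue_times:
        latency = max(rng_lat.normal(params.neural_latency_mean, params.neural_latency_sd), 0.0)
        amplitude = max(
            rng_amp.normal(params.event_peak_amplitude_mean, params.event_peak_amplitude_sd), 0.0
        )
        onset = cue + latency
        end = onset + params.event_duration
        if onset >= schedule.duration:
            logger.warning("event for cue at %.3f s falls entirely past trace end; dropped", cue)
            continue
        if end > schedule.duration:
            logger.warning("event for cue at %.3f s truncated at trace end", cue)
            end = schedule.duration
        if onset < prev_end:
            warnings.warn(
                f"event onset {onset:.3f} s overlaps the previous event; "
                "cue schedule violates the minimum inter-cue gap"
            )
        if amplitude > 0:
            x += event_template(
                t, onset, params.event_duration, amplitude, params.event_oscillation_freq
            )
        spans.append((float(onset), float(end)))
        prev_end = end

    return LfpTrace(
        samples=x,
        sampling_rate=params.sampling_rate,
        t0=0.0,
        cue_times=schedule.cue_times.copy(),
        ground_truth_event_spans=spans,
    )
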