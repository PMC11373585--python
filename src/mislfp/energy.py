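"""Analytic per-channel energy and power budget of the MIS signal chain.

Every quantity follows from the single pulse-energy primitive
``E = V^2 * G * t * n`` (voltage across the device, device conductance,
pulse width, pulse count) applied to the programming and readout phases
of one N-pulse batch, plus three fixed digital power contributions (ADC,
feature extraction, threshold classification).  Two stock parameter sets
are provided: the experimental devices (0.5 mS programming conductance,
600 us read) and a projected higher-resistance device (20 uS, 100 ns
read), for which the full budget comes to ~4.14 nW per channel and
~0.58 nJ per 140 ms classification operation.  A published linear power
model for an analog CMOS spike detector, P = 29.4 + 0.077 f nW at firing
rate f, serves as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnergyParams", "EnergyReport", "pulse_energy", "budget", "cmos_baseline_power"]


@dataclass(frozen=True)
class EnergyParams:
    """Inputs to the per-batch energy budget (SI units)."""

    v_prog: float = 2.0
    g_prog: float = 0.5e-3
    t_pulse: float = 100e-9
    pulses_per_batch: int = 70
    v_read: float = 0.2
    g_read: float = 20e-6
    t_read: float = 600e-6
    reads_per_batch: int = 1
    batch_period: float = 0.140
    p_adc: float = 17e-12
    p_feature: float = 0.0627e-9
    p_classifier: float = 0.0582e-9

    def __post_init__(self):
        positive = (
            self.v_prog, self.g_prog, self.t_pulse, self.pulses_per_batch,
            self.v_read, self.g_read, self.t_read, self.reads_per_batch,
            self.batch_period,
        )
        if any(x <= 0 for x in positive):
            raise ValueError("all pulse/read/batch parameters must be positive")
        if min(self.p_adc, self.p_feature, self.p_classifier) < 0:
            raise ValueError("digital power contributions must be >= 0")
        if self.reads_per_batch > self.pulses_per_batch:
            raise ValueError("reads_per_batch cannot exceed pulses_per_batch")

    @classmethod
    def experimental(cls) -> "EnergyParams":
        """As-measured devices: ~kOhm LRS (0.5 mS) programming, 600 us read."""
        return cls()

    @classmethod
    def projected(cls) -> "EnergyParams":
        """Engineered 100 kOhm-class device (20 uS) with a 100 ns read."""
        return cls(g_prog=20e-6, t_read=100e-9)


@dataclass(frozen=True)
class EnergyReport:
    """Per-batch energies and per-channel powers, raw SI values.

    ``e_per_operation`` is the system energy of one classification
    operation: total power times the batch period.
    """

    e_prog: float
    e_read: float
    e_batch_total: float
    p_memristor: float
    p_total: float
    e_per_operation: float

    def summary(self) -> str:
        def si(x: float, unit: str, scale: float) -> str:
            return f"{x / scale:.3g} {unit}"

        lines = [
            "Per-channel energy/power budget",
            "-" * 39,
            f"  programming energy / batch   {si(self.e_prog, 'nJ', 1e-9):>10}",
            f"  readout energy / batch       {si(self.e_read, 'nJ', 1e-9):>10}",
            f"  total memristor energy       {si(self.e_batch_total, 'nJ', 1e-9):>10}",
            f"  memristor power              {si(self.p_memristor, 'nW', 1e-9):>10}",
            f"  system power                 {si(self.p_total, 'nW', 1e-9):>10}",
            f"  energy per operation         {si(self.e_per_operation, 'nJ', 1e-9):>10}",
        ]
        return "\n".join(lines)


def pulse_energy(v: float, g: float, t: float, n: int) -> float:
    """Joule energy of ``n`` square pulses: ``v**2 * g * t * n``."""
    if v < 0 or g < 0 or t < 0 or n < 0:
        raise ValueError("pulse parameters must be non-negative")
    return v * v * g * t * n


def budget(params: EnergyParams) -> EnergyReport:
    """Full per-channel budget from one batch's programming and read pulses."""
    e_prog = pulse_energy(params.v_prog, params.g_prog, params.t_pulse, params.pulses_per_batch)
    e_read = pulse_energy(params.v_read, params.g_read, params.t_read, params.reads_per_batch)
    e_batch = e_prog + e_read
    p_mem = e_batch / params.batch_period
    p_total = p_mem + params.p_adc + params.p_feature + params.p_classifier
    return EnergyReport(
        e_prog=e_prog,
        e_read=e_read,
        e_batch_total=e_batch,
        p_memristor=p_mem,
        p_total=p_total,
        e_per_operation=p_total * params.batch_period,
    )


def cmos_baseline_power(f: float) -> float:
    """Analog CMOS spike-detector power (watts) at event rate ``f`` (Hz):
    ``(29.4 + 0.077 * f)`` nanowatts."""
    if f < 0:
        raise ValueError("event rate must be >= 0")
    return (29.4 + 0.077 * f) * 1e-9
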