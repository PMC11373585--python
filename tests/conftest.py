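import numpy as np
import pytest

import mislfp as m


@pytest.fixture(scope="session")
def noiseless_config():
    """High-SNR operating point: no background, tight event amplitudes,
    2.5e4 gain so 80 uV event peaks reach 2 V (suprathreshold)."""
    syn = m.SyntheticParams(
        background_rms=0.0, neural_latency_sd=0.05, event_peak_amplitude_sd=5e-6
    )
    return m.RunConfig(seed=1, duration=120.0, synthetic=syn)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_config):
    from mislfp.pipeline import _simulate_session

    return _simulate_session(noiseless_config, noiseless_config.seed)


def make_per_cycle_series(readouts, cycle_period=2e-3, initial=40e3):
    readouts = np.asarray(readouts, dtype=float)
    times = cycle_period * (1 + np.arange(readouts.size))
    return m.ResistanceSeries(
        times=times,
        readouts=readouts,
        cycle_period=cycle_period,
        cycles_per_readout=1,
        initial_resistance=initial,
    )
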