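import numpy as np
import pytest

from habpipe import synthetic_data as sd
from habpipe.session_io import EventStream, PositionTrace, Recording, Session, SpikeUnit


@pytest.fixture
def full_session() -> Session:
    """A small session exercising every modality, deterministically."""
    rng = np.random.default_rng(7)
    rec = Recording(1.0 + 0.01 * rng.standard_normal(2000), 500.0, 0.0, "gcamp")
    ev = EventStream([0.5, 1.5, 3.0], ["cue", "us", "cue"], [2.0, 0.5, 2.0])
    unit = SpikeUnit(
        np.sort(rng.uniform(0, 4.0, 50)),
        rng.standard_normal((4, 32)),
        unit_id="u1",
        light_pulses=np.array([3.5, 3.6]),
        pulse_width=0.005,
        t_start=0.0,
        t_stop=4.0,
        waveform_evoked=rng.standard_normal((4, 32)),
    )
    pos = PositionTrace(np.arange(100) / 25.0, np.cumsum(rng.standard_normal((100, 2)), axis=0))
    return Session(recording=rec, events=ev, units=[unit], position=pos)


@pytest.fixture
def noiseless_quinine():
    """Noise-free quinine-preset session: kernel parameters exactly recoverable."""
    preset = sd.preset_with(
        sd.TRANSIENT_PRESETS["quinine"], noise_sd=0.0, amplitude_cv=0.0, drift_tau=np.inf
    )
    rec, ev = sd.gen_photometry_session(preset, 3, sd.LAYOUTS["quinine"], seed=1)
    return preset, rec, ev
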