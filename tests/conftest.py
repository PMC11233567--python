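import numpy as np
import pytest

import sonomyo as sm


@pytest.fixture(scope="session")
def pulse():
    return sm.generate_pulse(5e6, 0.4, 50e6)


@pytest.fixture(scope="session")
def static_series(pulse):
    """Noiseless single static boundary at 30.00 mm, 2 s at 90 Hz."""
    scen = sm.SimScenario(
        boundary_trajectories=[lambda t: np.full_like(t, 30.0)],
        echo_amplitudes=[1.0],
        per_transducer_gain=(1.0,),
        noise_snr=None,
        duration=2.0,
    )
    series, truth = sm.simulate_frame_series(scen, pulse)
    return series, truth


@pytest.fixture(scope="session")
def bench(pulse):
    """Short (6 s) noisy bench-test emulation with ground truth."""
    scen = sm.make_mechanical_test_scenario(duration=6.0, seed=3)
    series, truth = sm.simulate_frame_series(scen, pulse)
    return series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
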