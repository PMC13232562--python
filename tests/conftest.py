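import numpy as np
import pytest

from optopace import PacingProtocol, HeartModelParams, simulate_ecg
from optopace import oisi, synth


@pytest.fixture(scope="session")
def tachy85():
    """8.5-Hz full-capture run: trace + ground truth (shortened rests)."""
    params = HeartModelParams(seed=11)
    proto = PacingProtocol.tachypacing(8.5, rest_pre_s=5, stim_s=10,
                                       rest_post_s=5)
    trace, truth = simulate_ecg(params, proto)
    return trace, truth


@pytest.fixture(scope="session")
def tachy14():
    """14-Hz 2:1 regime with a 100-ms refractory period."""
    params = HeartModelParams(sinus_rate_hz=7.5, erp_ms=100.0, seed=1)
    proto = PacingProtocol.tachypacing(14.0, rest_pre_s=5, stim_s=10,
                                       rest_post_s=5)
    trace, truth = simulate_ecg(params, proto)
    return trace, truth


@pytest.fixture(scope="session")
def spectro():
    """Extinction matrix + semi-infinite pathlength model at 525/637 nm."""
    return oisi.default_extinction(), oisi.pathlength_semiinfinite()


@pytest.fixture(scope="session")
def small_scene():
    """Drift-free 3-block scene at reduced field size for round trips."""
    return synth.make_hemo_scene(shape=(64, 64), n_blocks=3, lead_in_s=10.0,
                                 drift_frac=(0.0, 0.0), photon_budget=1e5,
                                 seed=1)
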