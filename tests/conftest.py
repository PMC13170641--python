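import numpy as np
import pytest

from parosc import OdeParams, WavePinParams, param_set


@pytest.fixture(scope="session")
def high_params() -> OdeParams:
    return param_set("high_feedback")


@pytest.fixture(scope="session")
def low_params() -> OdeParams:
    return param_set("low_feedback")


@pytest.fixture(scope="session")
def wp_params() -> WavePinParams:
    return WavePinParams()


@pytest.fixture(scope="session")
def high_attractors(high_params):
    """Stable fixed points of the high-feedback regime, keyed by quadrant."""
    from parosc import classify_quadrant, default_dead_zone, find_steady_states

    dz = default_dead_zone(high_params)
    out = {}
    for fp in find_steady_states(high_params):
        if fp.is_stable:
            out[classify_quadrant(fp.state, dz)] = fp.state
    return out


@pytest.fixture(scope="session")
def uniform_embryo():
    """Noise-free synthetic embryo with uniform membrane amplitude 100."""
    from parosc import EmbryoTruth, make_embryo_image

    return make_embryo_image(EmbryoTruth(noise_sigma=0.0))
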