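import numpy as np
import pytest

import ciliatransport as ct


@pytest.fixture(scope="session")
def quiet_preset():
    """A small, fast transport preset with no arrivals and no drift."""
    return ct.TransportPreset(
        name="quiet",
        duration_min=0.25,
        rate_antero=0.0,
        rate_retro=0.0,
        path_length_um=10.0,
        frame_shape=(48, 160),
        drift_step_px=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def busy_preset():
    """A short two-direction preset at wild-type-like velocities."""
    return ct.TransportPreset(
        name="busy",
        duration_min=1.0,
        rate_antero=4.0,
        rate_retro=2.5,
        v_antero_mean=1.1,
        v_antero_sd=0.15,
        v_retro_mean=0.8,
        v_retro_sd=0.1,
        path_length_um=12.0,
        frame_shape=(48, 192),
        drift_step_px=0.3,
        seed=2024,
    )


@pytest.fixture(scope="session")
def busy_movie(busy_preset):
    movie, ground_truth, drift = ct.simulate_transport_movie(busy_preset)
    return movie, ground_truth, drift


def make_textured_frame(shape=(40, 60), seed=0, background=30.0, amplitude=12.0):
    """A static structured frame for registration tests."""
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(rng.standard_normal(shape), 2.0)
    tex *= amplitude / tex.std()
    return np.clip(background + tex, 0, None)
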