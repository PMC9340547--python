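"""Shared fixtures: phantoms reused across test modules.

Heavier phantoms are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from waveonset.spectral import make_phase_kymograph
from waveonset.synth import PhantomSpec, generate_phantom_kymograph


@pytest.fixture(scope="session")
def gradient_phantom():
    """Default phantom kymograph: P 133→153 min, pulse, growth, noise."""
    spec = PhantomSpec(rng_seed=7)
    kym, gt = generate_phantom_kymograph(spec)
    return spec, kym, gt


@pytest.fixture(scope="session")
def static_phantom():
    """Static-domain noiseless phantom, P 130→150 min, oscillating from t=0."""
    spec = PhantomSpec(
        proximal_period=130.0,
        distal_period=150.0,
        growth_rate=0.0,
        noise_sd=0.0,
        pulse_amplitude=0.0,
        pulse_peak_time=-260.0,  # onset at t = 0
        rng_seed=7,
    )
    kym, gt = generate_phantom_kymograph(spec)
    return spec, kym, gt


@pytest.fixture(scope="session")
def static_phase_kymograph(static_phantom):
    _, kym, gt = static_phantom
    return make_phase_kymograph(kym, onset_frame=0), gt
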