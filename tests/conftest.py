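"""Shared fixtures.

The two expensive computations — the reduced bending-energy curve and the
monodisperse geometric-RSA jamming traces — are built once per session and
shared by the module tests and the acceptance tests.
"""

import warnings

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from vesadh.rsa import run_geometric_rsa
from vesadh.shape import bending_energy_curve

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

DISK_D = 100.0  # nm, nominal vesicle diameter


@pytest.fixture(scope="session")
def eb_curve():
    """Reduced E_b(alpha_f) curve over the measured alpha range."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bending_energy_curve(alpha_min=0.02, alpha_max=0.21, step=0.005)


@pytest.fixture(scope="session")
def mono_jamming_traces():
    """Five monodisperse geometric-RSA runs on an 80-diameter periodic box."""
    def mono(n, rng):
        return np.full(n, DISK_D)

    box = (80 * DISK_D, 80 * DISK_D)
    return [run_geometric_rsa(mono, box, n_attempts=6_000_000, seed=s)
            for s in range(5)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
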