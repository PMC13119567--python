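"""Shared fixtures: simulations and fitted pipelines are expensive, so the
default-condition objects are built once per session."""

import numpy as np
import pytest

from microgait import GaitMicroDoppler, WalkParams


@pytest.fixture(scope="session")
def default_params():
    return WalkParams()


@pytest.fixture(scope="session")
def default_model(default_params):
    return GaitMicroDoppler.from_simulation(default_params)


@pytest.fixture(scope="session")
def default_fit(default_model):
    return default_model.fit()


@pytest.fixture(scope="session")
def noisy_whitened():
    """Whitened set of a noisy echo: receiver noise keeps every covariance
    eigenvalue well above the regularization floor."""
    from microgait.whiten import embed, zca_whiten

    p = WalkParams(snr_db=20.0, seed=7)
    m = GaitMicroDoppler.from_simulation(p)
    cm = embed(m.echo.samples, 20)
    return cm, zca_whiten(cm)


def tone(freq, n, dt, decay=0.0, amp=1.0):
    k = np.arange(n)
    return amp * np.exp((-decay + 2j * np.pi * freq) * k * dt)
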