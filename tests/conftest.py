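import numpy as np
import pytest

import cimscal as c


def make_gaussian_trace(
    amplitude=1000.0,
    center=25.0,
    sigma=0.5,
    baseline=0.0,
    step=0.05,
    lo=20.0,
    hi=30.0,
    noise_sd=0.0,
    seed=0,
    analyte="pep1",
    separation_time=100.0,
):
    """A synthetic single-Gaussian ATD on a regular grid."""
    t = np.arange(lo, hi + step / 2, step)
    y = amplitude * np.exp(-((t - center) ** 2) / (2 * sigma**2)) + baseline
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
        y = np.clip(y, 0, None)
    return c.ATDTrace(analyte, separation_time, t, y)


@pytest.fixture
def gaussian_trace():
    return make_gaussian_trace()


@pytest.fixture(scope="session")
def noiseless_dataset():
    inst = c.InstrumentModel(perturbation_amplitude=0.0, noise_sd=0.0)
    return c.generate_dataset(instrument=inst, seed=11)


@pytest.fixture(scope="session")
def noisy_dataset():
    return c.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def calibrants():
    return c.default_calibrants()
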