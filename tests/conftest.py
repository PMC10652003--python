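import numpy as np
import pytest

from pullkin.simulate import generate_recording, healthy_params, tear_params


@pytest.fixture(scope="session")
def healthy_rodent():
    """One healthy rodent recording with default (realistic-noise) settings."""
    rec, truth = generate_recording(healthy_params("rodent", seed=11), subject_id="R01")
    return rec, truth


@pytest.fixture(scope="session")
def healthy_human():
    rec, truth = generate_recording(healthy_params("human", seed=12), subject_id="H01")
    return rec, truth


@pytest.fixture(scope="session")
def tear_rodent():
    rec, truth = generate_recording(tear_params("rodent", seed=13), subject_id="R02")
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def half_sine_trace(fps=60.0, period_s=0.5, amplitude=100.0, n_periods=3, phase=-0.01):
    """Mean-centered multi-period sine whose positive excursions are half-sines.

    A small negative phase puts the first up-crossing just inside the trace so
    every period contributes one crossing-bounded segment.
    """
    t = np.arange(0, n_periods * period_s, 1 / fps)
    y = amplitude * np.sin(2 * np.pi * t / period_s + phase)
    return y - y.mean()
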