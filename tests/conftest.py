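import numpy as np
import pytest

from dynamos import TimeSeries, TrialSpec, generate_trial


@pytest.fixture(scope="session")
def small_clean_trial():
    """Noise-free three-repetition trial (12 true movements)."""
    spec = TrialSpec(n_reps=3, static_lead=5.0, noise_sd=0.0, drift_amplitude=0.0)
    return generate_trial(spec, seed=123)


@pytest.fixture(scope="session")
def small_noisy_trial():
    spec = TrialSpec(n_reps=3, static_lead=5.0)
    return generate_trial(spec, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_series(values, fs=100.0):
    return TimeSeries(np.asarray(values, dtype=float), fs=fs)
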