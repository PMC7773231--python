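import numpy as np
import pytest

from flimkit import DecayCurve, DecayModelSpec, TimeGrid, eval_model


@pytest.fixture
def grid64():
    """64 bins over 10 ns — fast grid for unit tests."""
    return TimeGrid(n_bins=64, bin_width_ns=10.0 / 64)


@pytest.fixture
def grid256():
    """The default acquisition window: 256 bins over 10 ns."""
    return TimeGrid(n_bins=256, bin_width_ns=10.0 / 256)


@pytest.fixture
def mono_spec():
    return DecayModelSpec.mono_exp(Z=10.0, A=100.0, tau=2.0)


@pytest.fixture
def noiseless_mono(grid256, mono_spec):
    """Noiseless mono-exponential sampled at bin centers."""
    return DecayCurve(grid256, eval_model(mono_spec, grid256))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
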