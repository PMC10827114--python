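import numpy as np
import pytest

from lpa.containers import LaminarRecording, LaminarSignal
from lpa.synthetic import SyntheticConfig, generate


@pytest.fixture
def depths_26():
    return np.arange(26) * 40.0


@pytest.fixture
def small_recording():
    """A tiny deterministic broadband recording: 4 channels, 2 trials, 2.5 kHz."""
    rng = np.random.default_rng(42)
    fs = 2500.0
    n_samp = 2000
    pot = rng.standard_normal((4, n_samp, 2)) * 1e-4
    return LaminarRecording(
        potentials=pot,
        depths_um=np.arange(4) * 40.0,
        fs_hz=fs,
        trial_onsets=np.array([500, 500]),
        stim_labels=["white", "white"],
    )


def make_signal(values, kind="CSD", dt=1e-3, spacing=40.0):
    values = np.asarray(values, dtype=float)
    return LaminarSignal(
        values=values,
        depths_um=np.arange(values.shape[0]) * spacing,
        t=np.arange(values.shape[1]) * dt,
        dt=dt,
        kind=kind,
    )


@pytest.fixture
def make_laminar_signal():
    return make_signal


@pytest.fixture
def default_dataset():
    """One synthetic dataset at the default study conditions."""
    return generate(SyntheticConfig(), seed=1)


@pytest.fixture
def noiseless_csd_dataset():
    """Four populations (2 internal + 2 external emulated), noiseless CSD."""
    cfg = SyntheticConfig(n_internal=2, n_external=2, snr_mua=None, snr_csd=None)
    return generate(cfg, seed=7)
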