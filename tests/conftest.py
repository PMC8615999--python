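import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from kfcs.connectivity import CsEnParams
from kfcs.pipeline_select import compute_matrices
from kfcs.preprocess import bandpass_epochs
from kfcs.synthgen import SynthConfig, generate_epoch_set

# shared synthetic-subject geometry, small enough to keep the suite fast
N_CHANNELS = 16
FS = 125.0
HUBS = frozenset({1, 5, 9})
N_PER_CLASS = 20


def make_subject(gain_braking, gain_normal=0.0, seed=11, n_per_class=N_PER_CLASS,
                 subject_id="synth"):
    cfg = SynthConfig(
        n_epochs_per_class=n_per_class,
        n_channels=N_CHANNELS,
        fs=FS,
        hub_channels=HUBS,
        class_gains={"braking": gain_braking, "normal": gain_normal},
        noise_sd=1.0,
        seed=seed,
    )
    return bandpass_epochs(generate_epoch_set(cfg, subject_id))


@pytest.fixture(scope="session")
def sep_epochs():
    """A clearly separable subject: strong hub coupling only while braking."""
    return make_subject(gain_braking=2.5, seed=11, subject_id="sep")


@pytest.fixture(scope="session")
def sep_matrices(sep_epochs):
    return compute_matrices(sep_epochs, CsEnParams(), normalize=True)


@pytest.fixture(scope="session")
def null_epochs():
    """A null subject: identical class distributions (no coupling at all)."""
    return make_subject(gain_braking=0.0, seed=12, subject_id="null")


@pytest.fixture(scope="session")
def null_matrices(null_epochs):
    return compute_matrices(null_epochs, CsEnParams(), normalize=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
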