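import numpy as np
import pytest

from neuragem.baselines import make_rnn_baseline
from neuragem.model import NeuraGemModel, TrainConfig, run_training
from neuragem.tasks import generate_cst


@pytest.fixture(scope="session")
def cst_stream():
    return generate_cst(seed=0)


@pytest.fixture(scope="session")
def trained_ng(cst_stream):
    model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=0), seed=0)
    traj = run_training(model, cst_stream)
    return model, traj


@pytest.fixture(scope="session")
def trained_rnn_short(cst_stream):
    model = make_rnn_baseline("short", seed=0)
    traj = run_training(model, cst_stream)
    return model, traj


@pytest.fixture(scope="session")
def trained_rnn_long(cst_stream):
    model = make_rnn_baseline("long", seed=0)
    traj = run_training(model, cst_stream)
    return model, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
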