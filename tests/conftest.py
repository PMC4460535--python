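"""Shared fixtures: small synthetic sessions with known planted signal."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from blockdecode.config import PipelineConfig
from blockdecode.pipeline import prepare_session

#: small-but-decodable session defaults used across tests
SESSION_KW = dict(n_runs=2, n_voxels=60, n_informative=10,
                  effect_scale=1.4, white_sd=1.0, ar1_coeff=0.4,
                  selection_k=None)

#: compact NN settings so model selection stays fast on small data
NN_SPEC = {"name": "nn", "hidden_grid": [8], "n_restarts": 2,
           "max_epochs": 200}


@lru_cache(maxsize=8)
def _session(seed: int, **overrides):
    kw = {**SESSION_KW, **overrides}
    cfg = PipelineConfig(seed=seed, **kw)
    return prepare_session(cfg)


def make_session(seed: int = 0, **overrides):
    """Simulated + preprocessed session: (examples, truth, schedule)."""
    return _session(seed, **overrides)


@pytest.fixture(scope="session")
def session():
    return make_session(0)


@pytest.fixture(scope="session")
def strong_session():
    """Nearly noise-free session: planted classes are easily separable."""
    return make_session(1, effect_scale=3.0, white_sd=0.3, ar1_coeff=0.2)


@pytest.fixture(scope="session")
def trained_net(session):
    from blockdecode import train_nn
    examples, _, _ = session
    return train_nn(examples, hidden_grid=(8,), n_restarts=2, seed=0,
                    max_epochs=200)


def random_net(rng: np.random.Generator, n_in: int = 7, n_hidden: int = 5,
               n_out: int = 4):
    """A random (untrained) net with identity scaler, for oracle checks."""
    from blockdecode import TrainedNet
    return TrainedNet(V=rng.standard_normal((n_hidden, n_in)),
                      hidden_bias=rng.standard_normal(n_hidden),
                      W=rng.standard_normal((n_out, n_hidden)),
                      output_bias=rng.standard_normal(n_out))
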