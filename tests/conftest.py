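"""Shared fixtures.

The expensive artifacts -- a smoke-scale training corpus, the two trained
networks and a pseudo-experimental curve -- are built once per session
and shared by the model, inference and acceptance tests.  Sizes are the
desk-scale study conditions described in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sasmc.dataset import (DEFAULT_BASE_PARAMS, apply_q_cutoff, build_dataset,
                           generate_curve)
from sasmc.fixtures import PSEUDO_EXPERIMENT_TRUTH, desk_config
from sasmc.models import TrainingConfig, train_forward, train_surrogate
from sasmc.potentials import InteractionParams

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: Paper-selected momentum-transfer cutoff used for the forward net.
Q_CUTOFF = 0.0677


#: Desk-scale batch size: a few hundred samples per epoch need smaller
#: batches than the full-scale default to keep the update count sensible.
TRAIN_CFG = TrainingConfig(seed=0, batch_size=16)


@pytest.fixture(scope="session")
def smoke_corpus():
    """600 simulated curves at desk scale (docs/methods.md)."""
    return build_dataset(600, desk_config(seed=0), seed=0)


@pytest.fixture(scope="session")
def forward_model(smoke_corpus):
    truncated = apply_q_cutoff(smoke_corpus, Q_CUTOFF)
    return train_forward(truncated, config=TRAIN_CFG), truncated


@pytest.fixture(scope="session")
def surrogate_model(smoke_corpus):
    return train_surrogate(smoke_corpus, config=TRAIN_CFG)


@pytest.fixture(scope="session")
def pseudo_experiment():
    """Fresh MC curve at held-out truth with 2% noise and a sigma column."""
    z, k = PSEUDO_EXPERIMENT_TRUTH
    curve = generate_curve(
        InteractionParams(**{**DEFAULT_BASE_PARAMS, "z_eff": z,
                             "kappa_inv": k}),
        desk_config(seed=9001), noise_fraction=0.02,
        rng=np.random.default_rng(7))
    return curve, (z, k)
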