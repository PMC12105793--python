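"""Shared fixtures.

Expensive artifacts (the reference trajectory, the desk-scale dataset and
trained model) are session-scoped and generated once; everything is produced
programmatically so the repository ships no data files.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import invaert_cvsim as ic
from invaert_cvsim.cvsim6 import SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Desk-scale study size: 2000 simulator pairs (full scale is 54000).
DESK_N = 2000
DESK_SEED = 7


@pytest.fixture(scope="session")
def default_params():
    return ic.default_parameters()


@pytest.fixture(scope="session")
def default_traj(default_params):
    """Reference 12-cycle adaptive implicit (Radau) run, dense 1 ms output."""
    traj = ic.simulate(default_params, SimulationConfig())
    assert traj.ok
    return traj


@pytest.fixture(scope="session")
def stiffness_profile(default_traj):
    """Eigenvalue/SR history over the last two cycles of the default run."""
    return ic.eigen_history(default_traj)


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale dataset: 2000 prior draws through the simulator, split
    4000/54000-proportional validation + 3:1 train/test."""
    prior = ic.PriorSpec.synthetic()
    V = ic.sample_prior(prior, DESK_N, seed=DESK_SEED)
    ds = ic.build_dataset(V, seed=DESK_SEED)
    return ic.split_dataset(ds, "synthetic", seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_model(desk_dataset):
    """inVAErt bundle trained at the desk-scale profile."""
    cfg = ic.TrainingConfig.desk_scale()
    cfg.seed = DESK_SEED
    return ic.train_invaert(desk_dataset, cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny simulator dataset for fast unit tests of the training plumbing."""
    prior = ic.PriorSpec.synthetic()
    V = ic.sample_prior(prior, 120, seed=3)
    ds = ic.build_dataset(V, seed=3)
    return ic.split_dataset(ds, "synthetic", seed=3)


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """Quickly trained bundle: exercises every component's mechanics (not
    its accuracy)."""
    cfg = ic.TrainingConfig.desk_scale(
        epochs_emulator=80, epochs_flow=40, epochs_vae=40, batch_size=32)
    cfg.seed = 3
    return ic.train_invaert(small_dataset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
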