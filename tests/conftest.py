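import glob
import json
import os

import numpy as np
import pytest

FIXTURE_DIR = os.path.join(os.path.dirname(__file__), "fixtures")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _load_sharded_checkpoint(pattern: str):
    """Assemble an AgentParams from sharded JSON files (each < 64 kB)."""
    from replan.agent import AgentConfig, AgentParams, _param_shapes

    paths = sorted(glob.glob(pattern))
    if not paths:
        return None
    config = None
    tensors = {}
    for p in paths:
        with open(p) as f:
            blob = json.load(f)
        if "config" in blob:
            config = AgentConfig(**blob["config"])
        for k, v in blob.get("tensors", {}).items():
            tensors[k] = np.asarray(v, dtype=float)
    if config is None:
        return None
    expected = _param_shapes(config)
    if set(tensors) != set(expected):
        return None
    for k, shape in expected.items():
        tensors[k] = tensors[k].reshape(shape)
    return AgentParams(config, tensors)


@pytest.fixture(scope="session")
def trained_agent():
    """A trained agent shared by the analysis/acceptance tests.

    Prefers the bundled pretrained checkpoint (60 hidden units, produced by
    `replan.training.train` with the package's default hyperparameters over
    a long run; regenerable with scripts/train_fixture.py).  If the bundled
    files are absent, falls back to a short training run so the analysis
    mechanics are exercised regardless.
    """
    params = _load_sharded_checkpoint(
        os.path.join(FIXTURE_DIR, "agent_fixture_shard*.json"))
    if params is not None:
        return params
    from replan.synth import gen_agent_fixture

    return gen_agent_fixture(seed=0, hidden_units=48, batches=1500,
                             baseline_factor=0.0)
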