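import numpy as np
import pytest

from sebiograph.config import RunConfig
from sebiograph.graph_io import BioGraph, GraphBank
from sebiograph.synthetic_data import SimPreset, generate_bank


def two_triangle_graph(noise_seed: int = 0) -> BioGraph:
    """Six nodes in two bridged triangles; features separate the triangles."""
    adj = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
        adj[i, j] = adj[j, i] = 1.0
    rng = np.random.default_rng(noise_seed)
    feats = np.array([[5.0, 5.0]] * 3 + [[-5.0, -5.0]] * 3)
    feats += 0.1 * rng.standard_normal((6, 2))
    labels = np.array([1, 1, 1, 2, 2, 2])
    return BioGraph([f"n{i}" for i in range(6)], adj, feats, labels)


@pytest.fixture
def toy_graph() -> BioGraph:
    return two_triangle_graph()


@pytest.fixture
def toy_bank(toy_graph) -> GraphBank:
    return GraphBank([toy_graph], ["auxiliary"])


@pytest.fixture
def toy_cfg() -> RunConfig:
    return RunConfig(
        hidden_dim=8,
        decoder_dim=4,
        ways=2,
        shots=2,
        queries=1,
        cluster_counts=[3],
        seed=0,
    )


def tiny_preset(**overrides) -> SimPreset:
    """A fast-to-train bank for trainer unit tests."""
    base = dict(
        n_auxiliary=2,
        nodes=60,
        classes=3,
        feature_dim=8,
        p_in=0.2,
        p_out=0.02,
        separation=4.0,
        label_fraction=0.5,
        seed=0,
    )
    base.update(overrides)
    return SimPreset(**base)


@pytest.fixture
def tiny_bank() -> GraphBank:
    return generate_bank(tiny_preset())


@pytest.fixture
def tiny_cfg() -> RunConfig:
    return RunConfig(
        hidden_dim=8,
        decoder_dim=4,
        ways=3,
        shots=3,
        queries=3,
        episodes_per_epoch=20,
        epochs=2,
        optimizer="adam",
        gamma=0.01,
        eval_shots=5,
        eval_splits=2,
        seed=0,
    )
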