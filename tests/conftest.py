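import numpy as np
import pytest

from flustim.embeddings import EmbeddingStore
from flustim.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_store():
    """2-D store with easy geometry: two orthogonal pairs."""
    return EmbeddingStore({
        "apple": np.array([1.0, 0.0]),
        "pear": np.array([0.9, 0.1]),
        "hammer": np.array([0.0, 1.0]),
        "saw": np.array([0.1, 0.9]),
    })


def store_from_angles(angles_deg):
    """Unit 2-D vectors at the given angles, named w0, w1, ..."""
    vecs = {}
    for i, a in enumerate(angles_deg):
        r = np.deg2rad(a)
        vecs[f"w{i}"] = np.array([np.cos(r), np.sin(r)])
    return EmbeddingStore(vecs)


def chain_store(similarities):
    """Store of 2-D vectors t0..tn whose consecutive cosine similarities are
    exactly the given values (cumulative angles)."""
    angles = [0.0]
    for s in similarities:
        angles.append(angles[-1] + np.degrees(np.arccos(s)))
    vecs = {}
    for i, a in enumerate(angles):
        r = np.deg2rad(a)
        vecs[f"t{i}"] = np.array([np.cos(r), np.sin(r)])
    return EmbeddingStore(vecs), [f"t{i}" for i in range(len(angles))]


@pytest.fixture(scope="session")
def small_dataset():
    """Semantic-fluency-only study, 6 participants, reused across tests."""
    cfg = SimulationConfig(n_participants=6, tasks=("semantic_fluency",), seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def full_small_dataset():
    """All three tasks, 4 participants."""
    cfg = SimulationConfig(n_participants=4, seed=9)
    return simulate_dataset(cfg)
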