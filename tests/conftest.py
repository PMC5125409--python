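import numpy as np
import pytest

from artspeech import synthdata


@pytest.fixture(scope="session")
def noiseless_spec() -> synthdata.GroundTruthSpec:
    """Idealized study conditions: no sensor noise, no missing samples."""
    return synthdata.GroundTruthSpec(
        noise_sd=0.0, missing_rate=0.0, seed=11, session_duration=3.0
    )


@pytest.fixture(scope="session")
def ground_truth(noiseless_spec) -> synthdata.GroundTruthModel:
    return synthdata.make_ground_truth_model(noiseless_spec)


@pytest.fixture(scope="session")
def small_corpus(ground_truth, noiseless_spec) -> synthdata.SimulatedCorpus:
    """Three noiseless 3 s sentences with planted trajectories."""
    return synthdata.simulate_corpus(ground_truth, 3, noiseless_spec)


@pytest.fixture(scope="session")
def exact_model():
    """Planted model whose profile sums to 1 (no unmodelled variance)."""
    profile = [(n, f / 0.6214) for n, f in synthdata.DEFAULT_VARIANCE_PROFILE]
    spec = synthdata.GroundTruthSpec(
        variance_profile=profile, noise_sd=0.0, missing_rate=0.0, seed=7
    )
    return synthdata.make_ground_truth_model(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
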