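import numpy as np
import pytest

from photonhmm import hmm, simulate


@pytest.fixture(scope="session")
def apo_model():
    return simulate.make_macrostate_fixture("apo")


@pytest.fixture(scope="session")
def apo_true_hmm(apo_model):
    return hmm.H2MMModel(apo_model.rate_matrix, apo_model.efficiencies,
                         apo_model.stationary, apo_model.clock_period)


@pytest.fixture(scope="session")
def apo_dataset(apo_model):
    """600 bursts from the apo fixture (shared across read-only tests)."""
    stream, bursts, truth = simulate.simulate_dataset(apo_model, 600, seed=101)
    rec = hmm.PhotonRecords.from_stream(stream, bursts)
    return stream, bursts, truth, rec


@pytest.fixture(scope="session")
def two_state_model():
    Q = np.array([[-2000.0, 2000.0], [2000.0, -2000.0]])
    return simulate.GroundTruthModel(Q, np.array([0.9, 0.1]),
                                     burst_duration_mean=3e-3)


@pytest.fixture(scope="session")
def two_state_dataset(two_state_model):
    stream, bursts, truth = simulate.simulate_dataset(two_state_model, 300, seed=55)
    rec = hmm.PhotonRecords.from_stream(stream, bursts)
    return stream, bursts, truth, rec
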