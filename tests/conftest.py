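import numpy as np
import pytest

import leverpop as lp


@pytest.fixture(scope="session")
def std_session():
    """A mid-sized session with all three archetypes, cell-type boosts and a
    planted context gain; shared across test modules."""
    bc = lp.BehaviorConfig(n_block_pairs=2, rewards_per_block=15, seed=101)
    nc = lp.NeuralConfig(n_neurons=60, seed=202, context_gain=1.4,
                         cluster_proportions=(0.4, 0.35, 0.25), noise_sd=5.0)
    events, rec, truth = lp.generate_session(bc, nc)
    return dict(behavior=bc, neural=nc, events=events, rec=rec, truth=truth)


@pytest.fixture(scope="session")
def std_traces(std_session):
    return lp.preprocess_session(std_session["rec"])


@pytest.fixture(scope="session")
def std_press_tensor(std_session, std_traces):
    return lp.build_tensor(std_traces, std_session["events"], alignment="press")


@pytest.fixture(scope="session")
def std_cue_tensor(std_session, std_traces):
    return lp.build_tensor(std_traces, std_session["events"], alignment="cue_onset")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
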