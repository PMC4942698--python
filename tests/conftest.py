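import numpy as np
import pytest

from seqmeg.decode import predict_state_probabilities, train_state_classifiers
from seqmeg.synth import (SyntheticConfig, extract_epochs, make_state_patterns,
                          simulate_localizer)
from seqmeg.task import build_task_graph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def graph():
    return build_task_graph()


@pytest.fixture(scope="session")
def T(graph):
    return graph.transition_matrix


@pytest.fixture(scope="session")
def small_config():
    """Reduced sensor count for fast decoder tests."""
    return SyntheticConfig(n_sensors=32)


@pytest.fixture(scope="session")
def localizer_set(small_config):
    """A small labelled localizer: (epochs, labels, times_ms)."""
    rng = np.random.default_rng(7)
    pat = make_state_patterns(small_config.n_states, small_config.n_sensors, rng)
    ts, _ = simulate_localizer(small_config, pat, 8, rng)
    epochs, labels, times_ms = extract_epochs(ts)
    return epochs, labels, times_ms, pat


@pytest.fixture(scope="session")
def trained_classifiers(localizer_set):
    epochs, labels, times_ms, _ = localizer_set
    return train_state_classifiers(epochs, labels, 0.006, times_ms)


def decode_trials(classifiers, trials):
    """Helper: decode a list of (time x sensor) arrays."""
    return [predict_state_probabilities(classifiers, ts.data).data
            for ts in trials]
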