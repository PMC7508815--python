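"""Shared fixtures: small deterministic sessions and cohorts."""

import numpy as np
import pytest

from cwcst.behavior import remove_invalid_trials
from cwcst.inference import make_params
from cwcst.simulate import default_group_means, simulate_generative
from cwcst.task import build_deck


@pytest.fixture(scope="session")
def deck():
    return build_deck()


@pytest.fixture(scope="session")
def wprl_params():
    return make_params("wprl", default_group_means("wprl"))


@pytest.fixture(scope="session")
def wprl_session(wprl_params):
    """One full preprocessed session of a weighted-parallel-RL agent."""
    sess = simulate_generative(wprl_params, seed=20)
    return remove_invalid_trials(list(sess.trials))[0]


@pytest.fixture(scope="session")
def random_sessions():
    """Short preprocessed sessions from agents with randomized parameters.

    Used for identity and invariant checks that should hold for any valid
    parameter setting and any data.
    """
    rng = np.random.default_rng(77)
    sessions = []
    for i in range(12):
        means = {
            "alpha_mb_pos": rng.uniform(0.2, 0.95),
            "alpha_mb_neg": rng.uniform(0.2, 0.95),
            "gamma_mb": rng.uniform(0.1, 0.95),
            "alpha_mf_pos": rng.uniform(0.0, 0.5),
            "alpha_mf_neg": rng.uniform(0.0, 0.5),
            "gamma_mf": rng.uniform(0.1, 0.95),
            "tau": rng.uniform(0.1, 1.5),
            "w": rng.uniform(0.1, 0.9),
        }
        params = make_params("wprl", means)
        sess = simulate_generative(params, seed=500 + i, switch_count=8)
        sessions.append(remove_invalid_trials(list(sess.trials))[0])
    return sessions
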