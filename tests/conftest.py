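"""Shared fixtures: solved gaits for the three walker formulations.

Session-scoped so the Newton shooting (and numba compilation) happens once.
The circular-feet gait is reached by a short continuation in foot radius,
mirroring how sweeps seed their shots.
"""

import numpy as np
import pytest

from compassgait import limit_cycle as lc
from compassgait.walkers import WalkerParams, make_model

# fixture configurations: stable mid-grid gaits
POINT_PARAMS = WalkerParams(beta=0.03, gamma=0.009)
CIRC_PARAMS = WalkerParams(beta=0.01, gamma=0.005, r=0.13)

#: tight integration tolerances for cross-form invariance checks
TIGHT = {"rtol": 1e-12, "atol": 1e-12}


@pytest.fixture(scope="session")
def point_el():
    model = make_model("point_el", POINT_PARAMS)
    sol = lc.find_period_one(model, lc.cold_start_guess("point_el",
                                                        POINT_PARAMS))
    assert sol is not None and sol.stable
    return model, sol


@pytest.fixture(scope="session")
def point_ham():
    model = make_model("point_ham", POINT_PARAMS)
    sol = lc.find_period_one(model, lc.cold_start_guess("point_ham",
                                                        POINT_PARAMS))
    assert sol is not None and sol.stable
    return model, sol


@pytest.fixture(scope="session")
def point_el_tight():
    model = make_model("point_el", POINT_PARAMS)
    sol = lc.find_period_one(model, lc.cold_start_guess("point_el",
                                                        POINT_PARAMS),
                             **TIGHT)
    return model, sol


@pytest.fixture(scope="session")
def point_ham_tight():
    model = make_model("point_ham", POINT_PARAMS)
    sol = lc.find_period_one(model, lc.cold_start_guess("point_ham",
                                                        POINT_PARAMS),
                             **TIGHT)
    return model, sol


@pytest.fixture(scope="session")
def circular():
    guess = lc.cold_start_guess(
        "circular", WalkerParams(beta=CIRC_PARAMS.beta, gamma=CIRC_PARAMS.gamma,
                                 r=0.01))
    sol = None
    for r in (0.01, 0.05, 0.09, 0.13):
        p = WalkerParams(beta=CIRC_PARAMS.beta, gamma=CIRC_PARAMS.gamma, r=r)
        s = lc.find_period_one(make_model("circular", p), guess)
        if s is not None:
            guess, sol = s.fixed_state, s
    model = make_model("circular", CIRC_PARAMS)
    assert sol is not None and sol.stable
    return model, sol


def random_states(convention, n, seed=0):
    """Physically plausible random states for property tests."""
    rng = np.random.default_rng(seed)
    q1 = rng.uniform(-0.3, 0.3, n)
    q2 = rng.uniform(-0.5, 0.5, n)
    v1 = rng.uniform(-0.4, 0.1, n)
    v2 = rng.uniform(-0.3, 0.3, n)
    if convention == "POINT_HAM":
        v1, v2 = v1 * 1.05, v2 * 0.03  # momentum scale (p_phi ~ beta)
    return np.stack([q1, q2, v1, v2], axis=1)
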