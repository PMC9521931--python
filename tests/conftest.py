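import numpy as np
import pytest

import coupledgames as cg

# Printed payoff tables of the composite game (row-player values) for the
# base Prisoner's Dilemma coupled to the Snow Drift and Stag Hunt presets.
# These are inputs frozen from the published tables; build_direct_matrix
# must reproduce them cell for cell.
TABLE2_SD = np.array(
    [
        [3, 3, 8, 8, 0, 0, 5, 5],
        [3, 3, 8, 8, 1, 1, 3, 3],
        [4, 4, 6, 6, 0, 0, 5, 5],
        [4, 4, 6, 6, 1, 1, 3, 3],
        [5, 10, 5, 10, 1, 6, 1, 6],
        [5, 10, 5, 10, 2, 4, 2, 4],
        [6, 8, 6, 8, 1, 6, 1, 6],
        [6, 8, 6, 8, 2, 4, 2, 4],
    ],
    dtype=float,
)
TABLE2_SH = np.array(
    [
        [4, 4, 4, 4, 1, 1, 1, 1],
        [4, 4, 4, 4, 0, 0, 5, 5],
        [3, 3, 8, 8, 1, 1, 1, 1],
        [3, 3, 8, 8, 0, 0, 5, 5],
        [6, 6, 6, 6, 2, 2, 2, 2],
        [6, 6, 6, 6, 1, 6, 1, 6],
        [5, 10, 5, 10, 2, 2, 2, 2],
        [5, 10, 5, 10, 1, 6, 1, 6],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def pd_base():
    return cg.preset("prisoners_dilemma")


@pytest.fixture(scope="session")
def snow_drift():
    return cg.preset("snow_drift")


@pytest.fixture(scope="session")
def stag_hunt():
    return cg.preset("stag_hunt")


@pytest.fixture(scope="session")
def m_sd(pd_base, snow_drift):
    return cg.build_direct_matrix(pd_base, snow_drift)


@pytest.fixture(scope="session")
def m_sh(pd_base, stag_hunt):
    return cg.build_direct_matrix(pd_base, stag_hunt)


def random_game(rng, labels=("d", "u"), lo=-5.0, hi=5.0):
    r, s, t, p = rng.uniform(lo, hi, size=4)
    return cg.SymmetricGame2x2(r, s, t, p, labels)


def random_anti_coordination(rng, labels=("d", "u")):
    while True:
        g = random_game(rng, labels)
        if cg.classify_game(g) is cg.GameClass.ANTI_COORDINATION and g.temptation != g.sucker:
            return g
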