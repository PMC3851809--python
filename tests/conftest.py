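import numpy as np
import pytest

from groupnet.simulate import make_roster, pilot_demo
from groupnet.survey_io import SociometricNetwork


def net_from_arcs(n, arcs, respondents=None, wave="w1", relation="advice"):
    """Network on ids "1".."n" from integer arc pairs (0-based)."""
    roster = make_roster(n)
    ids = roster.ids
    str_arcs = frozenset((ids[e], ids[a]) for e, a in arcs)
    resp = (
        frozenset(ids[i] for i in respondents)
        if respondents is not None
        else frozenset(ids)
    )
    return SociometricNetwork(
        roster=roster, wave=wave, relation=relation, arcs=str_arcs, respondents=resp
    )


def random_digraph(n, rng, p=None):
    """Random 0-based arc set, Bernoulli(p) per ordered pair."""
    if p is None:
        p = rng.uniform(0.05, 0.6)
    return {
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }


def complete_arcs(n):
    return {(i, j) for i in range(n) for j in range(n) if i != j}


@pytest.fixture(scope="session")
def demo():
    return pilot_demo(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20131001)
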