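import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phyloconverge as pc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return pc.table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20120620)


def random_tree(n_tips, seed, model="pda_uniform"):
    g = np.random.default_rng(seed)
    return pc.random_topology([f"t{i}" for i in range(n_tips)], model=model, rng=g)


def random_character(tree, n_states, seed, p_missing=0.0):
    g = np.random.default_rng(seed)
    states = [f"s{i}" for i in range(n_states)]
    out = {}
    for t in tree.tip_labels:
        if p_missing and g.random() < p_missing:
            out[t] = None
        else:
            out[t] = states[int(g.integers(n_states))]
    return pc.CharacterMap(out)
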