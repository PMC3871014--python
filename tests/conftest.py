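import numpy as np
import pandas as pd
import pytest

import spinestats as ss


def interval_network(length: float = 100.0) -> ss.LinearNetwork:
    nodes = pd.DataFrame(dict(id=[1, 2], x=[0.0, length], y=[0.0, 0.0], parent=[-1, 1]))
    return ss.build_network(nodes)


def y_tree() -> ss.LinearNetwork:
    """Trunk of 50 μm with daughters of 30 and 40 μm (ids 3 and 4)."""
    nodes = pd.DataFrame(
        dict(id=[1, 2, 3, 4], x=[0.0, 50.0, 80.0, 50.0], y=[0.0, 0.0, 0.0, 40.0], parent=[-1, 1, 2, 2])
    )
    return ss.build_network(nodes)


@pytest.fixture
def interval():
    return interval_network()


@pytest.fixture
def ytree():
    return y_tree()


@pytest.fixture
def rand_tree():
    return ss.generate_tree(ss.TreeSpec(), np.random.default_rng(6))


@pytest.fixture
def csr_pattern(rand_tree):
    rng = np.random.default_rng(11)
    pat = ss.place_spines(rand_tree, ss.PlacementSpec(mode="csr", intensity=0.4), rng)
    return ss.assign_types(pat, ss.TypeSpec(), rng)


def spines_on_interval(net, offsets, types=None, div=7, experiment=1):
    seg = net.seg_ids[0]
    types = types or ["mushroom"] * len(offsets)
    spines = [
        ss.make_spine(net, ss.NetworkLocation(seg, o), t, div=div, experiment=experiment)
        for o, t in zip(offsets, types)
    ]
    return ss.SpinePattern(network=net, spines=spines)
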