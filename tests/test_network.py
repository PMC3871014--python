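"""Geometry primitives on the linear network: construction, distances,
ball lengths, circle counts, neighbors, and SWC/CSV round trips."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

import spinestats as ss
from spinestats.exceptions import (
    InsufficientNeighborsError,
    StructuralError,
    ValidationError,
)

from conftest import interval_network, spines_on_interval, y_tree


# ------------------------------------------------------------------- building
def test_single_segment_network(interval):
    assert interval.total_length == pytest.approx(100.0)
    assert list(interval.seg_order) == [1]


def test_y_tree_orders_and_length(ytree):
    assert ytree.total_length == pytest.approx(120.0)
    orders = dict(zip(ytree.seg_ids, ytree.seg_order))
    assert orders[2] == 1 and orders[3] == 2 and orders[4] == 2


def test_cycle_raises():
    nodes = pd.DataFrame(dict(id=[1, 2, 3], x=[0, 1, 2], y=[0, 0, 0]))
    edges = pd.DataFrame(dict(parent=[1, 2, 3], child=[2, 3, 1], length=[1, 1, 1]))
    with pytest.raises(StructuralError):
        ss.build_network(nodes, edges)


def test_disconnected_raises():
    nodes = pd.DataFrame(dict(id=[1, 2, 3, 4], x=[0, 1, 5, 6], y=[0] * 4, parent=[-1, 1, -1, 3]))
    with pytest.raises(StructuralError):
        ss.build_network(nodes)


def test_nonpositive_length_raises():
    nodes = pd.DataFrame(dict(id=[1, 2], x=[0, 1], y=[0, 0]))
    edges = pd.DataFrame(dict(parent=[1], child=[2], length=[0.0]))
    with pytest.raises(ValidationError):
        ss.build_network(nodes, edges)


def test_branch_order_increments_only_at_bifurcations():
    # chain of 3 segments then a bifurcation: orders 1,1,1 then 2,2
    nodes = pd.DataFrame(
        dict(
            id=[1, 2, 3, 4, 5, 6],
            x=[0, 10, 20, 30, 40, 30],
            y=[0, 0, 0, 0, 0, 10],
            parent=[-1, 1, 2, 3, 4, 4],
        )
    )
    net = ss.build_network(nodes)
    orders = dict(zip(net.seg_ids, net.seg_order))
    assert orders[2] == orders[3] == orders[4] == 1
    assert orders[5] == orders[6] == 2


# ------------------------------------------------------------------ distances
def test_distance_same_segment(interval):
    a = ss.NetworkLocation(2, 10.0)
    b = ss.NetworkLocation(2, 35.0)
    assert interval.distance(a, b) == pytest.approx(25.0)


def test_distance_through_branch_node(ytree):
    a = ss.NetworkLocation(3, 10.0)
    b = ss.NetworkLocation(4, 15.0)
    assert ytree.distance(a, b) == pytest.approx(25.0)


def test_distance_off_network_raises(interval):
    with pytest.raises(ValidationError):
        interval.distance(ss.NetworkLocation(2, 150.0), ss.NetworkLocation(2, 10.0))


def _nx_oracle_distance(net, a, b):
    """Independent shortest-path oracle: node graph plus temporary location nodes."""
    g = nx.Graph()
    for i in range(net.n_segments):
        g.add_edge(("n", net.seg_parent[i]), ("n", net.seg_child[i]), weight=net.seg_length[i])
    for name, loc in (("a", a), ("b", b)):
        si = net.segment_index(loc.segment)
        g.add_edge((name,), ("n", net.seg_parent[si]), weight=loc.offset)
        g.add_edge((name,), ("n", net.seg_child[si]), weight=net.seg_length[si] - loc.offset)
    if a.segment == b.segment:
        g.add_edge(("a",), ("b",), weight=abs(a.offset - b.offset))
    return nx.shortest_path_length(g, ("a",), ("b",), weight="weight")


def test_distance_matches_graph_oracle():
    net = ss.generate_tree(ss.TreeSpec(branch_prob=0.9, max_order=4), np.random.default_rng(2))
    assert net.n_segments >= 10
    rng = np.random.default_rng(3)
    for _ in range(100):
        a = net.location_at_arc(rng.uniform(0, net.total_length))
        b = net.location_at_arc(rng.uniform(0, net.total_length))
        assert net.distance(a, b) == pytest.approx(_nx_oracle_distance(net, a, b), abs=1e-9)


def test_metric_axioms_on_sampled_triples(rand_tree):
    rng = np.random.default_rng(4)
    locs = [rand_tree.location_at_arc(rng.uniform(0, rand_tree.total_length)) for _ in range(12)]
    for a in locs[:6]:
        assert rand_tree.distance(a, a) == 0.0
        for b in locs[6:]:
            dab = rand_tree.distance(a, b)
            assert dab == pytest.approx(rand_tree.distance(b, a))
            for c in locs[3:9]:
                assert dab <= rand_tree.distance(a, c) + rand_tree.distance(c, b) + 1e-9


def test_pairwise_distances_match_scalar(csr_pattern):
    d = csr_pattern.pairwise_distances()
    net = csr_pattern.network
    rng = np.random.default_rng(5)
    idx = rng.integers(0, csr_pattern.n, size=(30, 2))
    for i, j in idx:
        expected = net.distance(csr_pattern.spines[i].location, csr_pattern.spines[j].location)
        assert d[i, j] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------- ball length
def test_ball_two_arms(interval):
    p = ss.NetworkLocation(2, 50.0)
    assert interval.ball_length(p, 10.0) == pytest.approx(20.0)


def test_ball_three_arms_at_branch_node(ytree):
    p = ss.NetworkLocation(3, 0.0)  # exactly at the bifurcation
    assert ytree.ball_length(p, 5.0) == pytest.approx(15.0)


def test_ball_saturates_at_total_length(ytree):
    p = ss.NetworkLocation(2, 25.0)
    assert ytree.ball_length(p, 1e6) == pytest.approx(ytree.total_length)


def test_ball_negative_t_raises(interval):
    with pytest.raises(ValidationError):
        interval.ball_length(ss.NetworkLocation(2, 50.0), -1.0)


def _discretized_ball(net, p, t, step=0.01):
    arcs = np.arange(step / 2, net.total_length, step)
    covered = sum(step for a in arcs if net.distance(p, net.location_at_arc(a)) <= t)
    return covered


def test_ball_matches_discretization_oracle(rand_tree):
    rng = np.random.default_rng(8)
    p = rand_tree.location_at_arc(rng.uniform(0, rand_tree.total_length))
    ecc = rand_tree.eccentricity(p)
    for t in rng.uniform(0, ecc * 1.1, size=8):
        assert rand_tree.ball_length(p, t) == pytest.approx(
            _discretized_ball(rand_tree, p, t), abs=0.05
        )


def test_ball_monotone_in_t(rand_tree):
    p = rand_tree.location_at_arc(rand_tree.total_length * 0.3)
    ts = np.linspace(0, rand_tree.total_length, 50)
    vals = [rand_tree.ball_length(p, t) for t in ts]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


# --------------------------------------------------------------- circle count
def test_circle_interior_point(interval):
    assert interval.circle_count(ss.NetworkLocation(2, 50.0), 5.0) == 2


def test_circle_beyond_eccentricity(ytree):
    assert ytree.circle_count(ss.NetworkLocation(2, 10.0), 500.0) == 0


def test_circle_nonpositive_r_raises(interval):
    with pytest.raises(ValidationError):
        interval.circle_count(ss.NetworkLocation(2, 50.0), 0.0)


def _discretized_circle(net, p, r, step=0.001):
    arcs = []
    for si in range(net.n_segments):
        L = net.seg_length[si]
        offs = np.arange(0, L, step)
        arcs.extend((net.seg_ids[si], o) for o in offs)
    # count sign changes of (distance - r) along each segment separately
    count = 0
    for si in range(net.n_segments):
        L = net.seg_length[si]
        offs = np.concatenate([np.arange(0, L, step), [L]])
        d = np.array(
            [net.distance(p, ss.NetworkLocation(net.seg_ids[si], o)) for o in offs]
        )
        sign = np.sign(d - r)
        count += int(np.sum(sign[:-1] * sign[1:] < 0))
    return count


def test_circle_matches_sign_change_oracle():
    net = y_tree()
    rng = np.random.default_rng(9)
    for _ in range(12):
        p = net.location_at_arc(rng.uniform(0, net.total_length))
        r = rng.uniform(0.5, net.eccentricity(p) * 0.95)
        assert net.circle_count(p, r) == _discretized_circle(net, p, r)


def test_ball_derivative_equals_circle_count(rand_tree):
    """Away from nodes and tips, d(ball length)/dt equals the circle count."""
    rng = np.random.default_rng(10)
    p = rand_tree.location_at_arc(rand_tree.total_length * 0.4)
    eps = 1e-5
    for r in rng.uniform(1.0, rand_tree.eccentricity(p) * 0.9, size=6):
        m = rand_tree.circle_count(p, r)
        deriv = (rand_tree.ball_length(p, r + eps) - rand_tree.ball_length(p, r - eps)) / (2 * eps)
        # skip radii whose circle lands within eps of a node
        dn = rand_tree.location_to_node_distances(p)
        if np.min(np.abs(dn - r)) < 10 * eps:
            continue
        assert deriv == pytest.approx(m, abs=1e-3)


def test_batch_circle_counts_match_scalar(rand_tree):
    rng = np.random.default_rng(12)
    p = rand_tree.location_at_arc(rand_tree.total_length * 0.6)
    radii = rng.uniform(0.1, rand_tree.eccentricity(p), size=40)
    batch = rand_tree.circle_counts_batch(p, radii)
    for r, m in zip(radii, batch):
        assert m == rand_tree.circle_count(p, r)


# ------------------------------------------------------------------ neighbors
def test_nearest_neighbors_on_segment(interval):
    pat = spines_on_interval(interval, [0.0, 1.0, 3.0, 7.0])
    nbrs = ss.nearest_neighbors(pat, 0, 3)
    assert [d for _, d in nbrs] == pytest.approx([1.0, 3.0, 7.0])


def test_nearest_neighbor_tie_break_by_index(interval):
    pat = spines_on_interval(interval, [5.0, 5.0, 8.0])
    nbrs = ss.nearest_neighbors(pat, 0, 2)
    assert nbrs[0] == (1, 0.0)


def test_nearest_neighbors_insufficient(interval):
    pat = spines_on_interval(interval, [1.0, 2.0])
    with pytest.raises(InsufficientNeighborsError):
        ss.nearest_neighbors(pat, 0, 3)


def test_nearest_neighbors_match_bruteforce():
    rng = np.random.default_rng(13)
    tree = ss.generate_tree(ss.TreeSpec(branch_prob=0.9, max_order=4), rng)
    pat = ss.place_spines(tree, ss.PlacementSpec(mode="csr", intensity=0.8), rng)
    assert pat.n >= 20
    net = pat.network
    for i in rng.integers(0, pat.n, size=10):
        got = ss.nearest_neighbors(pat, int(i), 3)
        brute = sorted(
            (
                (net.distance(pat.spines[i].location, pat.spines[j].location), j)
                for j in range(pat.n)
                if j != i
            ),
        )[:3]
        assert [j for j, _ in got] == [j for _, j in brute]


# ------------------------------------------------------------------------ I/O
def test_annotation_round_trip(tmp_path, ytree):
    spines = [
        ss.make_spine(ytree, ss.NetworkLocation(2, 12.345678), "mushroom", div=7),
        ss.make_spine(ytree, ss.NetworkLocation(3, 1.5), "stubby", div=14),
        ss.make_spine(ytree, ss.NetworkLocation(4, 39.9), "thin", div=21),
    ]
    pat = ss.SpinePattern(network=ytree, spines=spines, dendrite_id="fix")
    ss.write_annotations(pat, tmp_path / "t.swc", tmp_path / "t.csv")
    back = ss.read_annotations(tmp_path / "t.swc", tmp_path / "t.csv")
    assert back.n == 3
    for a, b in zip(pat.spines, back.spines):
        assert b.location.segment == a.location.segment
        assert b.location.offset == pytest.approx(a.location.offset, abs=1e-6)
        assert b.spine_type == a.spine_type
        assert b.soma_distance == pytest.approx(a.soma_distance, abs=1e-6)
    back.validate()


def test_offnetwork_spine_dropped(tmp_path, interval):
    ss.write_swc(interval, tmp_path / "i.swc")
    pd.DataFrame(
        dict(x=[50.0, 50.0], y=[0.5, 10.0], type=["mushroom", "thin"], div=[7, 7], experiment=[1, 1])
    ).to_csv(tmp_path / "s.csv", index=False)
    pat = ss.read_annotations(tmp_path / "i.swc", tmp_path / "s.csv", snap_tolerance=2.0)
    assert pat.n == 1
    assert pat.n_dropped == 1


def test_swc_two_roots_raises(tmp_path):
    (tmp_path / "bad.swc").write_text("1 1 0 0 0 0.5 -1\n2 3 1 0 0 0.5 -1\n")
    with pytest.raises(StructuralError):
        ss.read_swc(tmp_path / "bad.swc")


def test_simulated_patterns_satisfy_sd_bo_invariants(csr_pattern):
    csr_pattern.validate()
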