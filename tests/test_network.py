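"""Interaction graph construction and KMT-to-centrosome connectivity."""

import networkx as nx
import numpy as np
import pytest

from spindlekit.network import (
    InteractionGraph,
    build_interaction_graph,
    connectivity_sweep,
    kmt_paths_to_centrosome,
    mt_pair_distance_angle,
)
from spindlekit.traces import ChromosomeRect, MicrotubuleTrace, SpindleReconstruction

from conftest import random_polyline


def _line(tid, a, b, n=4):
    t = np.linspace(0, 1, n)[:, None]
    return MicrotubuleTrace(id=tid, points=np.asarray(a, float) + t * (np.asarray(b, float) - np.asarray(a, float)))


def _rec(traces):
    return SpindleReconstruction(traces=traces)


def test_pair_distance_angle_parallel_and_identical():
    a = _line(0, [0, 0, 0], [3000, 0, 0])
    b = _line(1, [0, 100, 0], [3000, 100, 0])
    d, beta = mt_pair_distance_angle(a, b)
    assert d == pytest.approx(100.0)
    assert beta == pytest.approx(0.0)
    d2, beta2 = mt_pair_distance_angle(a, a)
    assert d2 == 0.0 and beta2 == 0.0


def test_handmade_four_trace_adjacency():
    t0 = _line(0, [0, 0, 0], [2000, 0, 0])
    t1 = _line(1, [0, 40, 0], [2000, 40, 0])      # near, parallel to t0
    t2 = _line(2, [1000, -30, 0], [1000, -30, 2000])  # near t0 but orthogonal
    t3 = _line(3, [0, 5000, 0], [2000, 5000, 0])  # parallel but far away
    g = build_interaction_graph(_rec([t0, t1, t2, t3]), a_max=50.0, beta_max=35.0)
    # manual enumeration: only (0,1) satisfies both thresholds
    assert {tuple(sorted(e[:2])) for e in g.edges()} == {(0, 1)}


def test_negative_thresholds_give_edgeless_graph():
    rng = np.random.default_rng(1)
    traces = [MicrotubuleTrace(id=i, points=random_polyline(rng)) for i in range(10)]
    g = build_interaction_graph(_rec(traces), a_max=-1.0, beta_max=35.0)
    assert g.graph.number_of_edges() == 0
    # zero thresholds still connect coincident traces
    twin = [traces[0], MicrotubuleTrace(id=99, points=traces[0].points.copy())]
    g2 = build_interaction_graph(_rec(twin), a_max=0.0, beta_max=0.0)
    assert {tuple(sorted(e[:2])) for e in g2.edges()} == {(0, 99)}


def test_spatial_index_matches_all_pairs():
    rng = np.random.default_rng(2)
    traces = [MicrotubuleTrace(id=i, points=random_polyline(rng)) for i in range(200)]
    rec = _rec(traces)
    fast = build_interaction_graph(rec, a_max=150.0, beta_max=45.0)
    slow = build_interaction_graph(rec, a_max=150.0, beta_max=45.0, use_spatial_index=False)
    assert {tuple(sorted(e[:2])) for e in fast.edges()} == {
        tuple(sorted(e[:2])) for e in slow.edges()
    }
    for (u, v, a, b), (u2, v2, a2, b2) in zip(sorted(fast.edges()), sorted(slow.edges())):
        assert a == pytest.approx(a2, rel=1e-9) and b == pytest.approx(b2, rel=1e-9)


def test_chain_hop_count_and_direct_connection():
    # KMT near the plate, S1 bridging, S2 touching the centrosome region
    kmt = _line(0, [4500, 0, 0], [6500, 0, 0])
    s1 = _line(1, [2800, 30, 0], [4800, 30, 0])
    s2 = _line(2, [500, 60, 0], [3100, 60, 0])
    rec = _rec([kmt, s1, s2])
    g = build_interaction_graph(rec, a_max=80.0, beta_max=10.0, d=2000.0)
    assert g.centrosome_connected == {2}
    hops = kmt_paths_to_centrosome(g, [0])
    assert hops == {0: 2}
    # a KMT reaching the centrosome region itself counts zero interactions
    long_kmt = _line(3, [1000, 0, 100], [6500, 0, 100])
    rec2 = _rec([long_kmt])
    g2 = build_interaction_graph(rec2, a_max=80.0, beta_max=10.0, d=2000.0)
    assert kmt_paths_to_centrosome(g2, [3]) == {3: 0}
    with pytest.raises(KeyError):
        kmt_paths_to_centrosome(g2, [42])


def _bfs_oracle(graph: nx.Graph, sources, node):
    """Plain breadth-first search, independent of the Dijkstra path."""
    from collections import deque

    if node in sources:
        return 0
    seen = set(sources)
    q = deque((s, 0) for s in sources)
    while q:
        u, d = q.popleft()
        for w in graph.neighbors(u):
            if w in seen:
                continue
            if w == node:
                return d + 1
            seen.add(w)
            q.append((w, d + 1))
    return None


def test_dijkstra_equals_bfs_on_random_graphs():
    rng = np.random.default_rng(3)
    for trial in range(50):
        n = int(rng.integers(5, 25))
        g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
        connected = frozenset(int(x) for x in rng.choice(n, size=max(1, n // 5), replace=False))
        ig = InteractionGraph(graph=g, centrosome_connected=connected, a_max=1, beta_max=1, d=1)
        kmts = list(range(n))
        hops = kmt_paths_to_centrosome(ig, kmts)
        for k in kmts:
            assert hops[k] == _bfs_oracle(g, connected, k)


def test_connectivity_sweep_monotone_and_consistent(small_spindle):
    recon, truth = small_spindle
    a_grid = [20.0, 60.0, 120.0]
    b_grid = [10.0, 35.0]
    frac = connectivity_sweep(recon, truth, a_grid, b_grid, d=2000.0)
    assert frac.shape == (3, 2)
    assert np.all(np.diff(frac, axis=0) >= -1e-12)
    assert np.all(np.diff(frac, axis=1) >= -1e-12)
    # single-cell sweep agrees with the direct computation
    g = build_interaction_graph(recon, truth, a_max=60.0, beta_max=35.0, d=2000.0)
    kmts = [t for t, c in truth.items() if c == "KMT"]
    hops = kmt_paths_to_centrosome(g, kmts)
    direct = sum(1 for h in hops.values() if h is not None) / len(kmts)
    assert frac[1, 1] == pytest.approx(direct)
    # shrinking the centrosome radius never increases the connected fraction
    frac_small_d = connectivity_sweep(recon, truth, [60.0], [35.0], d=1200.0)
    assert frac_small_d[0, 0] <= frac[1, 1] + 1e-12
    with pytest.raises(ValueError):
        connectivity_sweep(recon, truth, [], [10.0])


def test_typical_connected_kmt_needs_at_most_two_interactions():
    """On a dense synthetic spindle the KMTs that do reach the centrosome
    typically do so directly or via one or two spindle microtubules."""
    from spindlekit.synthetic import SynthSpindleConfig, generate_reconstruction

    cfg = SynthSpindleConfig(n_mts_total=1500, n_kmts=150, smt_fraction_of_nonkmt=0.85, seed=4)
    recon = generate_reconstruction(cfg)
    truth = {t.id: t.mt_class for t in recon.traces}
    g = build_interaction_graph(recon, truth, a_max=80.0, beta_max=35.0, d=2000.0,
                                sample_spacing=100.0)
    kmts = [t for t, c in truth.items() if c == "KMT"]
    hops = kmt_paths_to_centrosome(g, kmts)
    reached = [h for h in hops.values() if h is not None]
    assert len(reached) >= 0.2 * len(kmts)
    assert np.median(reached) <= 2
    # direct connections per chromosome in the observed 1-3 range
    direct = sum(1 for h in reached if h == 0)
    assert 1.0 <= direct / 12 <= 3.5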