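"""Microtubule interaction network and KMT-to-centrosome connectivity.

Two traces interact when their minimum segment-to-segment distance is at
most ``a_max`` and the acute angle between their end-to-end chords is at
most ``beta_max``.  A trace is "centrosome connected" when it approaches
the mother centriole within ``d``.  The number of interactions a KMT
needs to reach a centrosome-connected microtubule (0 = itself connected)
is the shortest-path hop count in the resulting graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    chord_angle_deg,
    point_segments_distance,
    polyline_min_distance,
    resample_polyline,
    segment_pair_distances,
)
from .traces import MicrotubuleTrace, SpindleReconstruction

__all__ = [
    "mt_pair_distance_angle",
    "build_interaction_graph",
    "kmt_paths_to_centrosome",
    "connectivity_sweep",
    "InteractionGraph",
]


def mt_pair_distance_angle(trace_a: MicrotubuleTrace, trace_b: MicrotubuleTrace) -> tuple[float, float]:
    """(min distance nm, acute chord angle in degrees) for a trace pair.

    The distance is the exact minimum over all line-segment pairs; the
    angle is measured between the chords through each trace's start and
    end points, which suppresses the effect of local distortions.
    """
    a = polyline_min_distance(trace_a.points, trace_b.points)
    beta = chord_angle_deg(trace_a.points, trace_b.points)
    return a, beta


@dataclass
class InteractionGraph:
    """Threshold-defined interaction graph over microtubule traces."""

    graph: nx.Graph                       # nodes: trace ids; edge attrs: a, beta
    centrosome_connected: frozenset
    a_max: float
    beta_max: float
    d: float
    centriole_distance: dict = field(default_factory=dict)  # trace id -> nm

    @property
    def vertices(self) -> list:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple]:
        return [(u, v, d["a"], d["beta"]) for u, v, d in self.graph.edges(data=True)]


def _padded_segments(traces: Sequence[MicrotubuleTrace]):
    """Per-trace segment arrays padded to a common count (pad = repeat of
    the last segment, which only duplicates candidate distances)."""
    smax = max(len(t.points) - 1 for t in traces)
    n = len(traces)
    A = np.empty((n, smax, 3))
    B = np.empty((n, smax, 3))
    for i, t in enumerate(traces):
        s = len(t.points) - 1
        A[i, :s] = t.points[:-1]
        B[i, :s] = t.points[1:]
        A[i, s:] = t.points[-2]
        B[i, s:] = t.points[-1]
    return A, B


def _pairs_min_distance(A, B, ia, ib, chunk: int = 1500) -> np.ndarray:
    """Exact min segment-pair distance for many trace pairs, vectorised."""
    smax = A.shape[1]
    out = np.empty(len(ia))
    for lo in range(0, len(ia), chunk):
        sl = slice(lo, lo + chunk)
        m = len(ia[sl])
        p0 = np.broadcast_to(A[ia[sl]][:, :, None, :], (m, smax, smax, 3)).reshape(-1, 3)
        p1 = np.broadcast_to(B[ia[sl]][:, :, None, :], (m, smax, smax, 3)).reshape(-1, 3)
        q0 = np.broadcast_to(A[ib[sl]][:, None, :, :], (m, smax, smax, 3)).reshape(-1, 3)
        q1 = np.broadcast_to(B[ib[sl]][:, None, :, :], (m, smax, smax, 3)).reshape(-1, 3)
        d = segment_pair_distances(p0, p1, q0, q1).reshape(m, smax * smax)
        out[sl] = d.min(axis=1)
    return out


def _candidate_pairs(traces: Sequence[MicrotubuleTrace], radius: float, spacing: float):
    """Trace-id pairs whose sampled points come within ``radius + spacing``.

    Sampling points at arc-length spacing <= ``spacing`` guarantees that a
    segment-pair distance <= radius implies sampled points within
    radius + spacing, so no qualifying pair can be missed.
    """
    pts = []
    owner = []
    for i, tr in enumerate(traces):
        p = resample_polyline(tr.points, spacing)
        pts.append(p)
        owner.append(np.full(len(p), i))
    pts = np.vstack(pts)
    owner = np.concatenate(owner)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius + spacing, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    oa = owner[pairs[:, 0]]
    ob = owner[pairs[:, 1]]
    mask = oa != ob
    lo = np.minimum(oa[mask], ob[mask])
    hi = np.maximum(oa[mask], ob[mask])
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def build_interaction_graph(
    recon: SpindleReconstruction,
    labels: Optional[dict[int, str]] = None,
    a_max: float = 50.0,
    beta_max: float = 35.0,
    d: float = 2000.0,
    sample_spacing: float = 250.0,
    include_classes: Optional[set] = None,
    use_spatial_index: bool = True,
) -> InteractionGraph:
    """Build the interaction graph of a reconstruction.

    A spatial index over points resampled along each trace prunes the
    pair candidates without missing any qualifying pair; the reported
    distances are always the exact segment-pair minima.  Non-positive
    thresholds simply yield an edgeless graph.  ``include_classes``
    restricts which traces participate (e.g. exclude AMTs as path
    intermediates).
    """
    traces = recon.traces
    if labels is not None and include_classes is not None:
        traces = [t for t in traces if labels.get(t.id) in include_classes]
    g = nx.Graph()
    cent_dist: dict[int, float] = {}
    for tr in traces:
        g.add_node(tr.id)
        cent_dist[tr.id] = point_segments_distance(recon.pole, tr.points)
    connected = frozenset(tid for tid, dist in cent_dist.items() if dist <= d)

    # negative thresholds yield an edgeless graph; zero thresholds still
    # connect coincident traces (a = 0, beta = 0)
    if a_max >= 0 and beta_max >= 0 and len(traces) > 1:
        if use_spatial_index:
            cand = _candidate_pairs(traces, a_max, sample_spacing)
        else:
            n = len(traces)
            cand = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        if len(cand):
            ia, ib = cand[:, 0], cand[:, 1]
            A, B = _padded_segments(traces)
            dist = _pairs_min_distance(A, B, ia, ib)
            # chord angles, vectorised; zero-length chords get no edges
            chords = np.array([t.points[-1] - t.points[0] for t in traces])
            norms = np.linalg.norm(chords, axis=1)
            ok_chord = (norms[ia] > 0) & (norms[ib] > 0)
            cosang = np.abs(np.einsum("ij,ij->i", chords[ia], chords[ib])) / np.where(
                ok_chord, norms[ia] * norms[ib], 1.0
            )
            beta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            keep = ok_chord & (dist <= a_max) & (beta <= beta_max)
            for i, j, a, b in zip(ia[keep], ib[keep], dist[keep], beta[keep]):
                g.add_edge(traces[i].id, traces[j].id, a=float(a), beta=float(b))
    return InteractionGraph(
        graph=g, centrosome_connected=connected,
        a_max=a_max, beta_max=beta_max, d=d, centriole_distance=cent_dist,
    )


def kmt_paths_to_centrosome(
    graph: InteractionGraph, kmt_ids: Sequence
) -> dict:
    """Minimal number of interactions for each KMT to reach a
    centrosome-connected microtubule.

    0 means the KMT itself is centrosome connected; a chain
    KMT-S1-S2(connected) counts 2 interactions.  Unreachable KMTs map to
    ``None``.  Uses Dijkstra with unit edge weights.
    """
    g = graph.graph
    for k in kmt_ids:
        if k not in g:
            raise KeyError(f"unknown trace id {k}")
    if graph.centrosome_connected:
        dist = nx.multi_source_dijkstra_path_length(
            g, sources=set(graph.centrosome_connected) & set(g.nodes), weight=lambda u, v, d: 1
        )
    else:
        dist = {}
    return {k: (int(dist[k]) if k in dist else None) for k in kmt_ids}


def connectivity_sweep(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    a_grid: Sequence[float],
    beta_grid: Sequence[float],
    d: float = 2000.0,
    sample_spacing: float = 250.0,
) -> np.ndarray:
    """Fraction of KMTs that reach the centrosome, per (a, beta) threshold.

    Returns a (len(a_grid), len(beta_grid)) matrix of fractions in [0, 1],
    non-decreasing along both axes.  Pair metrics are computed once at the
    loosest thresholds and re-filtered per grid cell.
    """
    a_grid = list(a_grid)
    beta_grid = list(beta_grid)
    if not a_grid or not beta_grid:
        raise ValueError("grids must be non-empty")
    big = build_interaction_graph(
        recon, labels, a_max=max(a_grid), beta_max=max(beta_grid), d=d,
        sample_spacing=sample_spacing,
    )
    kmt_ids = [tid for tid, c in labels.items() if c == "KMT" and tid in big.graph]
    out = np.zeros((len(a_grid), len(beta_grid)))
    if not kmt_ids:
        return out
    edges = big.edges()
    for i, a in enumerate(a_grid):
        for j, b in enumerate(beta_grid):
            g = nx.Graph()
            g.add_nodes_from(big.graph.nodes)
            g.add_edges_from(
                (u, v) for u, v, ea, eb in edges if ea <= a and eb <= b
            )
            sub = InteractionGraph(
                graph=g, centrosome_connected=big.centrosome_connected,
                a_max=a, beta_max=b, d=d,
            )
            hops = kmt_paths_to_centrosome(sub, kmt_ids)
            out[i, j] = sum(1 for h in hops.values() if h is not None) / len(kmt_ids)
    return out
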