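"""Low-level 3D geometry for polyline microtubule traces.

All routines work in nanometres on ``(n, 3)`` float arrays.  Microtubule
traces are piecewise-linear curves; distances between traces are minima
over all segment pairs, computed analytically (no sampling).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polyline_length",
    "segment_pair_distances",
    "polyline_min_distance",
    "chord_angle_deg",
    "point_segments_distance",
    "resample_polyline",
]


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def segment_pair_distances(p0, p1, q0, q1):
    """Minimum distances between segments [p0,p1] and [q0,q1], vectorised.

    Inputs broadcast on the leading axis; each of the four arguments is an
    (m, 3) array.  Returns an (m,) array of Euclidean minimum distances.
    Uses the standard clamped closest-point parameterisation (Lumelsky).
    """
    p0 = np.atleast_2d(np.asarray(p0, float))
    p1 = np.atleast_2d(np.asarray(p1, float))
    q0 = np.atleast_2d(np.asarray(q0, float))
    q1 = np.atleast_2d(np.asarray(q1, float))
    u = p1 - p0
    v = q1 - q0
    w0 = p0 - q0
    a = np.einsum("ij,ij->i", u, u)
    b = np.einsum("ij,ij->i", u, v)
    c = np.einsum("ij,ij->i", v, v)
    d = np.einsum("ij,ij->i", u, w0)
    e = np.einsum("ij,ij->i", v, w0)
    D = a * c - b * b

    eps = 1e-12 * np.maximum(1.0, np.maximum(a, c))
    parallel = D <= eps

    sN = np.where(parallel, 0.0, b * e - c * d)
    sD = np.where(parallel, 1.0, D)
    tN = np.where(parallel, e, a * e - b * d)
    tD = np.where(parallel, np.where(c > eps, c, 1.0), D)

    # clamp s to [0, 1]
    neg = sN < 0
    sN = np.where(neg, 0.0, sN)
    tN = np.where(neg, e, tN)
    tD = np.where(neg, np.where(c > eps, c, 1.0), tD)
    over = sN > sD
    sN = np.where(over, sD, sN)
    tN = np.where(over, e + b, tN)
    tD = np.where(over, np.where(c > eps, c, 1.0), tD)

    # clamp t to [0, 1], recompute s where needed
    neg_t = tN < 0
    tN = np.where(neg_t, 0.0, tN)
    s_new = np.where(a > eps, np.clip(-d / np.where(a > eps, a, 1.0), 0.0, 1.0), 0.0)
    sN = np.where(neg_t, s_new * sD, sN)
    over_t = tN > tD
    tN = np.where(over_t, tD, tN)
    s_new2 = np.where(a > eps, np.clip((-d + b) / np.where(a > eps, a, 1.0), 0.0, 1.0), 0.0)
    sN = np.where(over_t, s_new2 * sD, sN)

    s = np.where(np.abs(sD) > 0, sN / np.where(sD == 0, 1.0, sD), 0.0)
    t = np.where(np.abs(tD) > 0, tN / np.where(tD == 0, 1.0, tD), 0.0)
    diff = w0 + s[:, None] * u - t[:, None] * v
    return np.linalg.norm(diff, axis=1)


def polyline_min_distance(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """Minimum distance between two polylines over all segment pairs."""
    pts_a = np.asarray(pts_a, float)
    pts_b = np.asarray(pts_b, float)
    na = pts_a.shape[0] - 1
    nb = pts_b.shape[0] - 1
    if na < 1 or nb < 1:
        raise ValueError("both polylines need at least one segment")
    ia, ib = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    ia = ia.ravel()
    ib = ib.ravel()
    d = segment_pair_distances(pts_a[ia], pts_a[ia + 1], pts_b[ib], pts_b[ib + 1])
    return float(d.min())


def chord_angle_deg(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """Acute angle (degrees, in [0, 90]) between the end-to-end chords.

    The chord of a trace runs from its first to its last point; local
    wiggles of the polyline do not affect the angle.  Raises
    ``ValueError`` for a zero-length chord.
    """
    ca = np.asarray(pts_a[-1], float) - np.asarray(pts_a[0], float)
    cb = np.asarray(pts_b[-1], float) - np.asarray(pts_b[0], float)
    na = np.linalg.norm(ca)
    nb = np.linalg.norm(cb)
    if na == 0 or nb == 0:
        raise ValueError("zero-length chord: angle undefined")
    cosang = abs(float(np.dot(ca, cb)) / (na * nb))
    return float(np.degrees(np.arccos(min(1.0, cosang))))


def point_segments_distance(point: np.ndarray, pts: np.ndarray) -> float:
    """Minimum distance from a point to a polyline (min over segments)."""
    p = np.asarray(point, float)
    pts = np.asarray(pts, float)
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.where(denom > 0, np.einsum("ij,ij->i", p - a, ab) / np.where(denom == 0, 1, denom), 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return float(np.linalg.norm(closest - p, axis=1).min())


def resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Points along a polyline at most ``spacing`` apart (arc-length based).

    Always includes the original endpoints; used to seed spatial indices so
    that a query radius of ``a_max + spacing`` cannot miss a pair whose true
    minimum distance is <= a_max.
    """
    pts = np.asarray(pts, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    n = max(2, int(np.ceil(total / spacing)) + 1)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, pts[:, k])
    return out
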