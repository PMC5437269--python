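"""Geometric and statistical analysis of half-spindle reconstructions.

Implements the microtubule classification used for *C. elegans* mitotic
half spindles (KMT / SMT / AMT), endpoint-distance CDFs, axial density
profiles, filtered length distributions, the radial distribution function
of KMT attachment sites on the metaphase plate, per-chromosome attachment
statistics, and the z-endpoint density used as a stitching-quality check.

All distances in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import point_segments_distance
from .traces import MicrotubuleTrace, SpindleReconstruction

__all__ = [
    "classify",
    "end_distance_cdf",
    "density_along_axis",
    "length_distribution",
    "attachment_rdf",
    "chromosome_attachment_stats",
    "z_endpoint_density",
    "attachment_points",
    "plane_crossing_points",
    "disk_sampler",
    "pole_facing_end",
    "EndDistanceCDF",
    "AxialDensityProfile",
    "LengthDistributionResult",
    "RDFResult",
    "AttachmentStats",
    "ZEndpointDensity",
]

DEFAULT_CONE_HALF_ANGLE = 18.4  # degrees, pole-to-chromosome classification cone


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def _in_kinetochore_zone(recon: SpindleReconstruction, point: np.ndarray, pad: float) -> bool:
    """Whether a point lies in the ribosome-free slab pole-side of a chromosome."""
    s = float(recon.axial_coord(point)[0])
    if not (recon.plate_position - recon.kinetochore_zone_thickness <= s <= recon.plate_position + pad):
        return False
    u, v = recon.plane_coords(point)[0]
    return any(r.contains_uv(u, v, pad=pad) for r in recon.chromosome_rects)


def classify(
    recon: SpindleReconstruction,
    cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    zone_pad: float = 100.0,
) -> dict[int, str]:
    """Assign each trace exactly one class label: KMT, SMT or AMT.

    A microtubule with an end in the ribosome-free zone around a
    chromosome is a KMT (this rule takes precedence).  Among the rest,
    those whose length-weighted centre of mass falls inside the cone of
    half-angle ``cone_half_angle`` (degrees) opening from the mother
    centriole towards the chromosomes are SMTs; all others are AMTs.
    """
    if not recon.chromosome_rects:
        raise ValueError("reconstruction has no chromosome rectangles")
    tan_cone = math.tan(math.radians(cone_half_angle))
    labels: dict[int, str] = {}
    for tr in recon.traces:
        if _in_kinetochore_zone(recon, tr.points[0], zone_pad) or _in_kinetochore_zone(
            recon, tr.points[-1], zone_pad
        ):
            labels[tr.id] = "KMT"
            continue
        com = tr.centre_of_mass()
        s = float(recon.axial_coord(com)[0])
        rho = float(recon.radial_dist(com)[0])
        labels[tr.id] = "SMT" if (s > 0 and rho <= s * tan_cone) else "AMT"
    return labels


# --------------------------------------------------------------------------
# endpoint-distance CDFs
# --------------------------------------------------------------------------


@dataclass
class EndDistanceCDF:
    """Empirical CDF of pole-facing end distances to the mother centriole."""

    distances: np.ndarray  # sorted, nm
    fraction_within: float
    radius: float

    def cdf(self, r: float) -> float:
        return float(np.searchsorted(self.distances, r, side="right")) / len(self.distances)


def pole_facing_end(recon: SpindleReconstruction, trace: MicrotubuleTrace) -> np.ndarray:
    """The end with the smaller axial coordinate (trace polarity is not
    annotated in the data; polarity comes from light microscopy)."""
    s = recon.axial_coord(np.vstack([trace.points[0], trace.points[-1]]))
    return trace.points[0] if s[0] <= s[1] else trace.points[-1]


def end_distance_cdf(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    mt_class: str,
    radius: float = 2000.0,
) -> EndDistanceCDF:
    """CDF of distances of a class's pole-facing ends from the mother
    centriole, plus the fraction within ``radius`` nm."""
    ends = [pole_facing_end(recon, tr) for tr in recon.traces if labels.get(tr.id) == mt_class]
    if not ends:
        raise ValueError(f"no traces of class {mt_class!r}")
    d = np.sort(np.linalg.norm(np.asarray(ends) - recon.pole, axis=1))
    frac = float(np.searchsorted(d, radius, side="right")) / len(d)
    return EndDistanceCDF(distances=d, fraction_within=frac, radius=radius)


# --------------------------------------------------------------------------
# axial density
# --------------------------------------------------------------------------


@dataclass
class AxialDensityProfile:
    positions: np.ndarray  # nm along axis
    counts: dict[str, np.ndarray]  # per class
    ratio_kmt_smt: np.ndarray  # NaN where undefined (0/0)


def trace_crosses_plane(axial_vertex_coords: np.ndarray, p: float) -> bool:
    """Whether any polyline segment straddles the plane at axial position p.

    Half-open convention: a segment [lo, hi) crosses iff lo <= p < hi.
    """
    x = axial_vertex_coords
    lo = np.minimum(x[:-1], x[1:])
    hi = np.maximum(x[:-1], x[1:])
    return bool(np.any((lo <= p) & (p < hi)))


def density_along_axis(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    n_planes: int = 20,
) -> AxialDensityProfile:
    """Count traces crossing evenly spaced planes between pole and plate."""
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    positions = np.linspace(0.0, recon.plate_position, n_planes + 2)[1:-1]
    counts = {c: np.zeros(len(positions), dtype=int) for c in ("KMT", "SMT", "AMT")}
    axial = {tr.id: recon.axial_coord(tr.points) for tr in recon.traces}
    for tr in recon.traces:
        cls = labels.get(tr.id)
        if cls is None:
            continue
        x = axial[tr.id]
        for j, p in enumerate(positions):
            if trace_crosses_plane(x, p):
                counts[cls][j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = counts["KMT"] / counts["SMT"].astype(float)
    ratio[(counts["KMT"] == 0) & (counts["SMT"] == 0)] = np.nan
    return AxialDensityProfile(positions=positions, counts=counts, ratio_kmt_smt=ratio)


# --------------------------------------------------------------------------
# length distributions with boundary/short filters
# --------------------------------------------------------------------------


@dataclass
class LengthDistributionResult:
    edges: np.ndarray
    histograms: dict[str, np.ndarray]
    lengths: dict[str, np.ndarray]
    n_total: int
    n_excluded_boundary: int
    n_excluded_short: int


def _near_boundary(points: np.ndarray, bounds: np.ndarray, margin: float) -> bool:
    ends = points[[0, -1]]
    return bool(
        np.any(ends - bounds[0] < margin) or np.any(bounds[1] - ends < margin)
    )


def length_distribution(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    boundary_margin: float = 250.0,
    min_length: float = 100.0,
    bin_width: float = 500.0,
) -> LengthDistributionResult:
    """Per-class length histograms after the standard exclusion filters.

    Traces with an endpoint closer than ``boundary_margin`` to the
    reconstruction volume boundary (they may leave the volume) and traces
    shorter than ``min_length`` are removed before binning.  The two
    filters commute and are idempotent; exclusion tallies are reported.
    """
    if recon.volume_bounds is None:
        raise ValueError("reconstruction has no volume bounds")
    n_bdry = n_short = 0
    per_class: dict[str, list] = {c: [] for c in ("KMT", "SMT", "AMT")}
    for tr in recon.traces:
        boundary = _near_boundary(tr.points, recon.volume_bounds, boundary_margin)
        short = tr.length < min_length
        n_bdry += boundary
        n_short += short
        if boundary or short:
            continue
        cls = labels.get(tr.id)
        if cls is not None:
            per_class[cls].append(tr.length)
    lengths = {c: np.asarray(v, float) for c, v in per_class.items()}
    max_len = max((v.max() for v in lengths.values() if len(v)), default=bin_width)
    edges = np.arange(0.0, max_len + bin_width, bin_width)
    hists = {c: np.histogram(v, bins=edges)[0] for c, v in lengths.items()}
    return LengthDistributionResult(
        edges=edges,
        histograms=hists,
        lengths=lengths,
        n_total=len(recon.traces),
        n_excluded_boundary=n_bdry,
        n_excluded_short=n_short,
    )


# --------------------------------------------------------------------------
# attachment-point radial distribution function
# --------------------------------------------------------------------------


def attachment_points(recon: SpindleReconstruction, labels: dict[int, str]) -> np.ndarray:
    """KMT chromosome-facing ends projected on the plane of cell division,
    as (n, 2) in-plane (u, v) coordinates (nm)."""
    pts = []
    for tr in recon.traces:
        if labels.get(tr.id) != "KMT":
            continue
        s = recon.axial_coord(np.vstack([tr.points[0], tr.points[-1]]))
        end = tr.points[0] if s[0] > s[1] else tr.points[-1]
        pts.append(recon.plane_coords(end)[0])
    return np.asarray(pts, float).reshape(-1, 2)


@dataclass
class RDFResult:
    edges: np.ndarray       # nm
    g: np.ndarray           # normalized pair density per annulus
    pair_counts: np.ndarray
    reference_mean: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def peak_distance(self, lo: float = 0.0, hi: float = np.inf) -> float:
        sel = (self.centers >= lo) & (self.centers <= hi) & np.isfinite(self.g)
        c = self.centers[sel]
        return float(c[np.argmax(self.g[sel])])


def _pair_hist(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    iu = np.triu_indices(len(points), k=1)
    return np.histogram(d[iu], bins=edges)[0]


def _uniform_in_rects(rng, rects, centers_uv, n) -> np.ndarray:
    areas = np.array([r.area_nm2 for r in rects])
    idx = rng.choice(len(rects), size=n, p=areas / areas.sum())
    out = np.empty((n, 2))
    for i, k in enumerate(idx):
        r = rects[k]
        out[i, 0] = r.center_uv[0] + (rng.random() - 0.5) * r.width
        out[i, 1] = r.center_uv[1] + (rng.random() - 0.5) * r.height
    return out


def plane_crossing_points(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    axis_fraction: float,
    cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    classes: tuple = ("KMT", "SMT"),
) -> tuple[np.ndarray, float]:
    """In-plane (u, v) crossing points of traces through the plane at a
    fraction of the half-spindle length, restricted to the classification
    cone; returns the points and the cone radius at that plane (both nm).

    Feed these to :func:`attachment_rdf` with a disk reference sampler to
    measure in-slice microtubule neighbour densities (the 25% / 75%
    half-spindle-length analyses).
    """
    p = axis_fraction * recon.plate_position
    cone_r = p * math.tan(math.radians(cone_half_angle))
    pts = []
    for tr in recon.traces:
        if labels.get(tr.id) not in classes:
            continue
        x = recon.axial_coord(tr.points)
        for i in range(len(x) - 1):
            lo, hi = (x[i], x[i + 1]) if x[i] <= x[i + 1] else (x[i + 1], x[i])
            if lo <= p < hi and hi > lo:
                t = (p - x[i]) / (x[i + 1] - x[i])
                q = tr.points[i] + t * (tr.points[i + 1] - tr.points[i])
                uv = recon.plane_coords(q)[0]
                if np.hypot(*uv) <= cone_r:
                    pts.append(uv)
    return np.asarray(pts, float).reshape(-1, 2), cone_r


def disk_sampler(radius: float):
    """Uniform reference sampler on a disk (for in-slice RDFs)."""

    def sample(rng, n):
        r = radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * math.pi, n)
        return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

    return sample


def attachment_rdf(
    recon: SpindleReconstruction,
    labels: dict[int, str],
    n_random: int = 10000,
    bin_width: float = 20.0,
    max_distance: float = 1000.0,
    seed: int = 0,
    points: Optional[np.ndarray] = None,
    reference_sampler=None,
) -> RDFResult:
    """Radial distribution function of KMT attachment points on the plate.

    Annulus-binned pair counts of the projected attachment points, divided
    by the mean pair counts of ``n_random`` ensembles of the same number of
    points placed uniformly in the same chromosome rectangles.  g(r) ~ 1
    indicates random placement; a suppressed core plus a near peak
    indicates excluded-volume packing.

    ``points`` may supply (n, 2) in-plane coordinates directly (used e.g.
    for in-slice neighbour densities of plane-crossing points).
    """
    if points is None:
        points = attachment_points(recon, labels)
    points = np.asarray(points, float)
    if len(points) < 2:
        raise ValueError("need at least 2 attachment points")
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts = _pair_hist(points, edges)
    rng = np.random.default_rng(seed)
    ref = np.zeros((n_random, len(edges) - 1))
    for i in range(n_random):
        if reference_sampler is not None:
            rp = reference_sampler(rng, len(points))
        else:
            rp = _uniform_in_rects(rng, recon.chromosome_rects, None, len(points))
        ref[i] = _pair_hist(rp, edges)
    ref_mean = ref.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ref_mean > 0, counts / np.where(ref_mean == 0, 1, ref_mean), np.nan)
    return RDFResult(edges=edges, g=g, pair_counts=counts, reference_mean=ref_mean)


# --------------------------------------------------------------------------
# per-chromosome attachment statistics
# --------------------------------------------------------------------------


@dataclass
class AttachmentStats:
    counts: np.ndarray            # KMTs per chromosome
    areas_um2: np.ndarray
    density_per_um2: np.ndarray
    pearson_r: Optional[float]    # None when undefined
    end_morphology: dict[str, dict[str, float]]  # per end: fraction open/closed/undetermined


def chromosome_attachment_stats(
    recon: SpindleReconstruction,
    labels: dict[int, str],
) -> AttachmentStats:
    """KMT counts and surface densities per chromosome rectangle, their
    Pearson correlation with rectangle area, and end-morphology tallies."""
    if not recon.chromosome_rects:
        raise ValueError("no chromosome rectangles")
    pts = attachment_points(recon, labels)
    counts = np.zeros(len(recon.chromosome_rects), dtype=int)
    for u, v in pts:
        for k, r in enumerate(recon.chromosome_rects):
            if r.contains_uv(u, v, pad=1.0):
                counts[k] += 1
                break
    areas = np.array([r.area_nm2 for r in recon.chromosome_rects]) / 1e6  # um^2
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = counts / areas
    nonzero = counts > 0
    if nonzero.sum() < 3:
        r_val = None
    elif np.std(counts) == 0 or np.std(areas) == 0:
        r_val = None
    else:
        r_val = float(stats.pearsonr(counts, areas)[0])

    morph: dict[str, dict[str, float]] = {}
    kmts = [tr for tr in recon.traces if labels.get(tr.id) == "KMT"]
    for which in ("chromosome", "pole"):
        tally = {m: 0 for m in ("open", "closed", "undetermined")}
        for tr in kmts:
            s = recon.axial_coord(np.vstack([tr.points[0], tr.points[-1]]))
            chromo_first = s[0] > s[1]
            if which == "chromosome":
                tally[tr.end_start if chromo_first else tr.end_end] += 1
            else:
                tally[tr.end_end if chromo_first else tr.end_start] += 1
        tot = sum(tally.values())
        morph[which] = {m: (tally[m] / tot if tot else math.nan) for m in tally}
    return AttachmentStats(
        counts=counts, areas_um2=areas, density_per_um2=dens, pearson_r=r_val, end_morphology=morph
    )


# --------------------------------------------------------------------------
# z endpoint density (stitching QC)
# --------------------------------------------------------------------------


@dataclass
class ZEndpointDensity:
    bin_edges: np.ndarray
    bin_kind: list  # "section" or "boundary"
    counts: np.ndarray
    density: np.ndarray  # counts / bin width


def z_endpoint_bins(section_boundaries_z: np.ndarray) -> tuple[np.ndarray, list]:
    """Bins alternating between section interiors (central 50% of each
    section) and section boundaries (25% of each adjacent section)."""
    zb = np.asarray(section_boundaries_z, float)
    if len(zb) < 2:
        raise ValueError("need at least 2 section boundaries (1 section)")
    edges = []
    kinds = []
    for i in range(len(zb) - 1):
        lo, hi = zb[i], zb[i + 1]
        t = hi - lo
        edges.append((lo + 0.25 * t, hi - 0.25 * t))
        kinds.append("section")
        if i < len(zb) - 2:
            t_next = zb[i + 2] - zb[i + 1]
            edges.append((hi - 0.25 * t, hi + 0.25 * t_next))
            kinds.append("boundary")
    flat = [edges[0][0]] + [e[1] for e in edges]
    return np.asarray(flat), kinds


def z_endpoint_density(recon: SpindleReconstruction) -> ZEndpointDensity:
    """Density of trace endpoints along z, normalized per bin width, with
    bins lying either inside a section or across a section boundary.  A
    smooth curve indicates good section-to-section stitching."""
    if recon.section_boundaries_z is None:
        raise ValueError("reconstruction has no section boundaries")
    edges, kinds = z_endpoint_bins(recon.section_boundaries_z)
    z = np.array([p[2] for tr in recon.traces for p in (tr.points[0], tr.points[-1])])
    counts, _ = np.histogram(z, bins=edges)
    widths = np.diff(edges)
    return ZEndpointDensity(bin_edges=edges, bin_kind=kinds, counts=counts, density=counts / widths)
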