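"""Synthetic stand-ins for the electron-tomography and light-microscopy data.

Real half-spindle reconstructions, EB-comet movies and FRAP profile
series are not publicly deposited; this module generates data with the
same statistical structure, carrying ground-truth labels so every
analysis in the package can be validated against a known answer.

The default spindle emulates a *C. elegans* metaphase half spindle:
~8331 microtubules of which ~227 are KMTs whose plus-ends tile 12
chromosome rectangles on the metaphase plate with a ~127 nm hard-core
spacing, SMT/AMT minus-ends clustered within 3 um of the mother
centriole, and class-specific length laws (AMT exponential, SMT
exponential plus a flat tail, KMT near-uniform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import IntensityProfileSeries, RegionSpec, SpotSet
from .traces import (
    ChromosomeRect,
    MicrotubuleTrace,
    SpindleReconstruction,
    _orthonormal_basis,
)

__all__ = [
    "SynthSpindleConfig",
    "SynthCometConfig",
    "SynthFrapConfig",
    "CometMovie",
    "generate_reconstruction",
    "generate_comet_movie",
    "generate_frap_series",
    "PackingError",
    "default_chromosome_rects",
    "COMET_SPEED_PRESETS",
]


class PackingError(RuntimeError):
    """Too many attachment points for the available plate area/spacing."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def default_chromosome_rects(ring_radius: float = 2800.0) -> list[ChromosomeRect]:
    """Twelve chromosome rectangles on a ring in the plate plane.

    Areas span ~0.35-2.1 um^2 (total ~11.8 um^2) so the default 227 KMTs
    give a surface density of ~19 per um^2 and per-chromosome counts in
    the observed 6-50 range, roughly proportional to area.
    """
    areas_um2 = [0.35, 0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 1.0, 1.1, 1.3, 1.6, 2.1]
    rects = []
    for k, area in enumerate(areas_um2):
        ang = 2 * math.pi * k / len(areas_um2)
        width = min(1300.0, area * 1e6 / 700.0)
        height = area * 1e6 / width
        rects.append(
            ChromosomeRect(
                center_uv=(ring_radius * math.cos(ang), ring_radius * math.sin(ang)),
                width=width,
                height=height,
            )
        )
    return rects


@dataclass
class LengthLaws:
    """Per-class microtubule length laws (um).

    SMT lengths follow an exponential body with a flat (uniform) tail,
    mirroring the observed exponential-then-flatter shape; the exact tail
    law is a modelling choice and fully configurable.
    """

    amt_mean: float = 1.6
    smt_mean: float = 1.6
    smt_tail_range: tuple[float, float] = (2.0, 6.0)
    smt_tail_weight: float = 0.2
    kmt_range: tuple[float, float] = (0.0, 6.5)

    def sample(self, rng: np.random.Generator, mt_class: str, n: int) -> np.ndarray:
        if mt_class == "AMT":
            return rng.exponential(self.amt_mean, n)
        if mt_class == "SMT":
            tail = rng.random(n) < self.smt_tail_weight
            out = rng.exponential(self.smt_mean, n)
            out[tail] = rng.uniform(*self.smt_tail_range, tail.sum())
            return out
        if mt_class == "KMT":
            return rng.uniform(*self.kmt_range, n)
        raise ValueError(mt_class)


#: Default per-end morphology probabilities (open, closed, undetermined).
#: Among annotated KMT ends, ~71% are open at the chromosome and ~38% at
#: the pole in metaphase (79%/41% in anaphase); ~30% of ends stay
#: undetermined.
END_MORPHOLOGY_PRESETS = {
    "metaphase": {
        "KMT": {"chromosome": (0.497, 0.203, 0.30), "pole": (0.266, 0.434, 0.30)},
        "SMT": {"plus": (0.45, 0.25, 0.30), "minus": (0.20, 0.50, 0.30)},
        "AMT": {"plus": (0.45, 0.25, 0.30), "minus": (0.20, 0.50, 0.30)},
    },
    "anaphase": {
        "KMT": {"chromosome": (0.553, 0.147, 0.30), "pole": (0.287, 0.413, 0.30)},
        "SMT": {"plus": (0.45, 0.25, 0.30), "minus": (0.20, 0.50, 0.30)},
        "AMT": {"plus": (0.45, 0.25, 0.30), "minus": (0.20, 0.50, 0.30)},
    },
}


@dataclass
class SynthSpindleConfig:
    """Parameters of a synthetic half-spindle reconstruction.

    Lengths in the length laws and ``half_spindle_length`` are in um;
    all other geometry is in nm.
    """

    n_mts_total: int = 8331
    n_kmts: int = 227
    half_spindle_length: float = 6.5  # um, centrosome to plate
    cone_half_angle: float = 18.4     # degrees
    n_chromosomes: int = 12
    chromosome_rects: list = field(default_factory=default_chromosome_rects)
    min_attachment_spacing: float = 127.0  # nm hard core on the plate
    smt_minus_cluster_scale: float = 1.5   # um, radial decay of nucleation density
    length_laws: LengthLaws = field(default_factory=LengthLaws)
    polyline_noise: float = 20.0  # nm
    vertex_spacing: float = 500.0  # nm
    volume_bounds: tuple = ((-2500.0, -8250.0, -3000.0), (7200.0, 8250.0, 3000.0))
    stage: str = "metaphase"
    end_morphology_probs: Optional[dict] = None
    smt_fraction_of_nonkmt: float = 0.17
    kinetochore_zone_thickness: float = 500.0
    section_thickness: float = 300.0  # nm, for z QC bins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mts_total < 0 or self.n_kmts < 0:
            raise ValueError("counts must be >= 0")
        if self.n_kmts > self.n_mts_total:
            raise ValueError("n_kmts cannot exceed n_mts_total")
        if self.min_attachment_spacing <= 0:
            raise ValueError("min_attachment_spacing must be > 0")
        if len(self.chromosome_rects) != self.n_chromosomes:
            if self.chromosome_rects is not None and len(self.chromosome_rects) > 0:
                self.n_chromosomes = len(self.chromosome_rects)
        if self.end_morphology_probs is None:
            self.end_morphology_probs = END_MORPHOLOGY_PRESETS[self.stage]
        for cls in self.end_morphology_probs.values():
            for probs in cls.values():
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError("end morphology probabilities must sum to 1")


# --------------------------------------------------------------------------
# spindle generation
# --------------------------------------------------------------------------

_MORPH = ("open", "closed", "undetermined")


def _allocate_counts(n: int, areas: np.ndarray, lo: int = 6, hi: int = 50) -> np.ndarray:
    """Allocate n attachments proportionally to area, clipped to [lo, hi]."""
    if n == 0:
        return np.zeros(len(areas), dtype=int)
    raw = n * areas / areas.sum()
    counts = np.clip(np.floor(raw).astype(int), lo, hi)
    rem = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    i = 0
    step = 1 if rem > 0 else -1
    while rem != 0 and i < 10 * len(areas):
        k = order[i % len(areas)]
        c = counts[k] + step
        if lo <= c <= hi:
            counts[k] = c
            rem -= step
        i += 1
    if rem != 0:
        raise PackingError("cannot satisfy per-chromosome attachment bounds")
    return counts


def _hard_core_points(
    rng, rect: ChromosomeRect, n: int, spacing: float, existing: list, max_tries: int = 20000
):
    """Dart-throwing with a hard-core minimum distance inside a rectangle.

    The core is enforced against ``existing`` points too, so the spacing
    holds across neighbouring chromosome rectangles as well.
    """
    pts: list = []
    tries = 0
    cu, cv = rect.center_uv
    while len(pts) < n:
        if tries > max_tries:
            raise PackingError(
                f"cannot place {n} attachments with {spacing} nm spacing "
                f"in a {rect.width:.0f}x{rect.height:.0f} nm rectangle"
            )
        tries += 1
        p = np.array([cu + (rng.random() - 0.5) * rect.width, cv + (rng.random() - 0.5) * rect.height])
        if all(
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= spacing**2
            for cloud in (pts, existing)
            for q in cloud
        ):
            pts.append(p)
    existing.extend(pts)
    return np.asarray(pts).reshape(-1, 2)


def _radial_cluster_distance(rng, scale_um: float, n: int, hi_um: float = 3.0) -> np.ndarray:
    """Radial distances (nm) with density ~ r^2 exp(-r/scale) on [0, hi].

    This is a uniform-per-volume nucleation density decaying exponentially
    with distance from the centriole; it reproduces the observed
    minus-end distance CDF (only about half the SMT ends lie within 2 um
    in 3D even though all are within 3 um).
    """
    out = np.empty(n)
    got = 0
    while got < n:
        cand = rng.exponential(scale_um, 2 * (n - got) + 8)
        w = rng.random(len(cand))
        cand = cand[(cand <= hi_um) & (w <= (cand / hi_um) ** 2)]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out * 1000.0


def _unit_from_axis_angle(rng, phi: float) -> np.ndarray:
    """Unit vector at polar angle phi from +x, uniform azimuth."""
    psi = rng.uniform(0, 2 * math.pi)
    return np.array([math.cos(phi), math.sin(phi) * math.cos(psi), math.sin(phi) * math.sin(psi)])


def _polyline(rng, start: np.ndarray, end: np.ndarray, spacing: float, noise: float) -> np.ndarray:
    """Lightly noised straight chord; endpoints are kept exact."""
    length = float(np.linalg.norm(end - start))
    n = max(2, int(math.ceil(length / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    if noise > 0 and n > 2:
        pts[1:-1] += rng.normal(0.0, noise, (n - 2, 3))
    return pts


def _draw_morphology(rng, probs) -> str:
    return _MORPH[rng.choice(3, p=np.asarray(probs, float))]


def generate_reconstruction(config: SynthSpindleConfig) -> SpindleReconstruction:
    """Generate a labelled synthetic half-spindle reconstruction.

    The pole (mother centriole) sits at the origin with the spindle axis
    along +x and the metaphase plate at ``half_spindle_length``.  KMTs run
    from hard-core-sampled attachment points on the chromosome rectangles
    towards the pole; SMTs grow inside the classification cone from
    clustered minus-ends; AMTs radiate outside the cone.  Output traces
    carry ground-truth ``mt_class`` labels; determinism is guaranteed by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L_nm = config.half_spindle_length * 1000.0
    laws = config.length_laws
    bounds = np.asarray(config.volume_bounds, float)
    cone = math.radians(config.cone_half_angle)
    traces: list[MicrotubuleTrace] = []
    tid = 0

    n_kmt = min(config.n_kmts, config.n_mts_total)
    n_rest = config.n_mts_total - n_kmt
    n_smt = int(round(n_rest * config.smt_fraction_of_nonkmt))
    n_amt = n_rest - n_smt

    # the same in-plane basis the reconstruction frame will report
    u_vec, v_vec = _orthonormal_basis(np.array([1.0, 0.0, 0.0]))

    # --- KMTs: plate attachment points with hard-core spacing ----------
    if n_kmt:
        if not config.chromosome_rects:
            raise PackingError("no chromosome rectangles to attach to")
        areas = np.array([r.area_nm2 for r in config.chromosome_rects])
        lo = 6 if n_kmt >= 6 * len(areas) else 0
        counts = _allocate_counts(n_kmt, areas, lo=lo, hi=max(50, n_kmt))
        probs = config.end_morphology_probs["KMT"]
        placed: list = []
        for rect, cnt in zip(config.chromosome_rects, counts):
            uv = _hard_core_points(rng, rect, int(cnt), config.min_attachment_spacing, placed)
            for u, v in uv:
                plus = L_nm * np.array([1.0, 0, 0]) + u * u_vec + v * v_vec
                length = laws.sample(rng, "KMT", 1)[0] * 1000.0
                chord = float(np.linalg.norm(plus))
                length = min(length, chord - 10.0)
                direction = -plus / chord  # towards the pole
                minus = plus + direction * length
                pts = _polyline(rng, minus, plus, config.vertex_spacing, config.polyline_noise)
                traces.append(
                    MicrotubuleTrace(
                        id=tid, points=pts, mt_class="KMT",
                        end_start=_draw_morphology(rng, probs["pole"]),
                        end_end=_draw_morphology(rng, probs["chromosome"]),
                    )
                )
                tid += 1

    # --- SMTs: clustered minus-ends, growth inside the cone ------------
    margin = math.radians(4.0)
    probs_smt = config.end_morphology_probs["SMT"]
    if n_smt:
        r_minus = _radial_cluster_distance(rng, config.smt_minus_cluster_scale, n_smt)
        lengths = laws.sample(rng, "SMT", n_smt) * 1000.0
        for k in range(n_smt):
            minus = _unit_from_axis_angle(rng, rng.uniform(0.0, cone - margin)) * r_minus[k]
            phi = rng.uniform(0.0, cone - margin)
            direction = _unit_from_axis_angle(rng, phi)
            # keep the plus end clear of the plate's kinetochore zone
            max_ax = L_nm - config.kinetochore_zone_thickness - 200.0
            max_len = (max_ax - minus[0]) / max(direction[0], 1e-9)
            length = min(lengths[k], max_len)
            plus = minus + direction * length
            pts = _polyline(rng, minus, plus, config.vertex_spacing, config.polyline_noise)
            traces.append(
                MicrotubuleTrace(
                    id=tid, points=pts, mt_class="SMT",
                    end_start=_draw_morphology(rng, probs_smt["minus"]),
                    end_end=_draw_morphology(rng, probs_smt["plus"]),
                )
            )
            tid += 1

    # --- AMTs: radiate outside the cone ---------------------------------
    probs_amt = config.end_morphology_probs["AMT"]
    if n_amt:
        r_minus = _radial_cluster_distance(rng, config.smt_minus_cluster_scale, n_amt)
        lengths = laws.sample(rng, "AMT", n_amt) * 1000.0
        tan_out = math.tan(cone + margin)
        for k in range(n_amt):
            for _ in range(200):
                phi = math.acos(rng.uniform(-1.0, math.cos(cone + margin)))
                direction = _unit_from_axis_angle(rng, phi)
                minus = _unit_from_axis_angle(rng, rng.uniform(0, math.pi)) * r_minus[k]
                # clip to the volume so the trace stays inside the box
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_exit = np.concatenate(
                        [(bounds[1] - minus) / direction, (bounds[0] - minus) / direction]
                    )
                max_len = float(np.min(t_exit[t_exit > 0], initial=np.inf)) - 100.0
                length = min(lengths[k], max_len)
                if length <= 0:
                    continue
                plus = minus + direction * length
                com = 0.5 * (minus + plus)
                rho = math.hypot(com[1], com[2])
                if com[0] <= 0 or rho > com[0] * tan_out:  # truly outside the cone
                    break
            pts = _polyline(rng, minus, plus, config.vertex_spacing, config.polyline_noise)
            traces.append(
                MicrotubuleTrace(
                    id=tid, points=pts, mt_class="AMT",
                    end_start=_draw_morphology(rng, probs_amt["minus"]),
                    end_end=_draw_morphology(rng, probs_amt["plus"]),
                )
            )
            tid += 1

    n_sections = max(2, int(math.ceil((bounds[1][2] - bounds[0][2]) / config.section_thickness)))
    section_z = np.linspace(bounds[0][2], bounds[1][2], n_sections + 1)
    return SpindleReconstruction(
        traces=traces,
        pole=np.zeros(3),
        axis=np.array([1.0, 0.0, 0.0]),
        plate_position=L_nm,
        chromosome_rects=list(config.chromosome_rects),
        kinetochore_zone_thickness=config.kinetochore_zone_thickness,
        volume_bounds=bounds,
        stage=config.stage,
        section_boundaries_z=section_z,
    )


# --------------------------------------------------------------------------
# comet movies
# --------------------------------------------------------------------------

#: Regional comet speeds (um/s) mirroring the live-imaging estimates:
#: 0.34 in the spindle, 0.49 at chromosomes, 0.27 in the inner and 0.73 in
#: the outer astral region.
COMET_SPEED_PRESETS = {
    "spindle": 0.34,
    "chromosomes": 0.49,
    "inner_astral": 0.27,
    "outer_astral": 0.73,
}


@dataclass
class SynthCometConfig:
    """Synthetic EB-comet movie parameters (single region per movie)."""

    region: RegionSpec = field(default_factory=lambda: RegionSpec("spindle", 2.5, 5.0))
    speed: float = 0.34          # um/s, radial; positive = outward
    birth_rate: float = 40.0     # comets/s appearing in the region
    lifetime: float = 2.0        # s, exponential mean
    n_frames: int = 80
    frame_interval: float = 0.25  # s (one plane every 250 ms)
    shape: tuple[int, int] = (220, 220)
    pixel_size: float = 0.1      # um/px
    centrosome_px: tuple[float, float] = (110.0, 110.0)
    psf_sigma: float = 1.2       # px
    amplitude: float = 60.0
    background: float = 100.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0 (direction handled separately)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")

    @classmethod
    def preset(cls, kind: str, **overrides) -> "SynthCometConfig":
        from .dynamics import DEFAULT_REGIONS

        kw = dict(region=DEFAULT_REGIONS[kind], speed=COMET_SPEED_PRESETS[kind])
        kw.update(overrides)
        return cls(**kw)


@dataclass
class CometMovie:
    frames: np.ndarray      # (T, H, W) float
    times: np.ndarray       # s
    pixel_size: float       # um/px
    centrosome_px: np.ndarray
    truth: SpotSet          # ground-truth positions per frame
    tracks: list            # per-comet dicts: birth time, frames, positions


def _render_spot(frame: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    h, w = frame.shape
    rad = int(math.ceil(4 * sigma))
    r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
    c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    frame[r0:r1, c0:c1] += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


def generate_comet_movie(config: SynthCometConfig) -> CometMovie:
    """Render a synthetic comet movie plus ground-truth tracks.

    Comets are born at Poisson rate inside the region, move radially at
    the configured speed, live an exponential lifetime and are rendered
    as Gaussian PSF blobs on a noisy background.
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    times = np.arange(T) * config.frame_interval
    t_end = times[-1] + config.frame_interval
    cen = np.asarray(config.centrosome_px, float)
    speed_px = config.speed / config.pixel_size  # px/s

    # comet births over the movie duration
    n_born = rng.poisson(config.birth_rate * t_end)
    tracks = []
    for _ in range(n_born):
        t0 = rng.uniform(0.0, t_end)
        life = rng.exponential(config.lifetime)
        # uniform-in-area radius within the annulus
        rin, rout = config.region.r_in / config.pixel_size, config.region.r_out / config.pixel_size
        rad = math.sqrt(rng.uniform(rin**2, rout**2))
        ang = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.sin(ang), math.cos(ang)])
        p0 = cen + rad * direction
        frames_in = []
        positions = []
        for k, t in enumerate(times):
            if t0 <= t <= t0 + life:
                pos = p0 + direction * speed_px * (t - t0)
                if 0 <= pos[0] < config.shape[0] and 0 <= pos[1] < config.shape[1]:
                    frames_in.append(k)
                    positions.append(pos)
        if frames_in:
            tracks.append({"t0": t0, "frames": frames_in, "positions": np.asarray(positions)})

    frames = np.full((T, *config.shape), float(config.background))
    per_frame: list = [[] for _ in range(T)]
    for tr in tracks:
        for k, pos in zip(tr["frames"], tr["positions"]):
            _render_spot(frames[k], pos[0], pos[1], config.amplitude, config.psf_sigma)
            per_frame[k].append(pos)
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, frames.shape)
    truth = SpotSet(
        positions=[np.asarray(p, float).reshape(-1, 2) for p in per_frame], times=times
    )
    return CometMovie(
        frames=frames, times=times, pixel_size=config.pixel_size,
        centrosome_px=cen, truth=truth, tracks=tracks,
    )


# --------------------------------------------------------------------------
# FRAP profile series
# --------------------------------------------------------------------------


@dataclass
class SynthFrapConfig:
    """Synthetic FRAP profile-series parameters.

    The chromatin peak sits at position 0; the bleach trough starts
    ``trough_start`` um pole-side of it and drifts at ``drift_velocity``
    towards the chromosomes.  The trough depth recovers as a weighted sum
    of a fast exponential (tau_fast) and a linear ramp of duration
    tau_slow, mimicking SMT- and KMT-driven turnover.
    """

    bleach_depth: float = 0.6          # fraction of local intensity removed
    bleach_width: float = 1.0          # um FWHM of the trough
    drift_velocity: float = 0.03       # um/s toward the chromosomes
    tau_fast: float = 5.0              # s
    tau_slow: float = 20.0             # s (ramp duration)
    weight_fast: float = 0.5
    chromatin_peak_position: float = 0.0  # um
    chromatin_peak_width: float = 0.8     # um (Gaussian sigma)
    chromatin_peak_amplitude: float = 1.0
    baseline: float = 1.0
    trough_start: float = -2.5         # um (pole side of the peak)
    profile_halfspan: float = 6.0      # um on each side of the peak
    dx: float = 0.05                   # um sampling
    duration: float = 60.0             # s
    dt: float = 1.0                    # s
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bleach_depth <= 1.0):
            raise ValueError("bleach depth must be within [0, 1]")
        if self.bleach_width <= 0:
            raise ValueError("bleach width must be > 0")
        if self.bleach_width >= 2 * self.profile_halfspan:
            raise ValueError("bleach width must be smaller than the profile")
        if not (0.0 <= self.weight_fast <= 1.0):
            raise ValueError("weight_fast must be within [0, 1]")


def generate_frap_series(config: SynthFrapConfig) -> IntensityProfileSeries:
    """Profiles with a Gaussian chromatin peak and a drifting, recovering
    photobleach trough (positions in nm, as in measured profiles)."""
    rng = np.random.default_rng(config.seed)
    x = np.arange(-config.profile_halfspan, config.profile_halfspan + config.dx / 2, config.dx)
    times = np.arange(0.0, config.duration + config.dt / 2, config.dt)
    sig_tr = config.bleach_width / 2.355  # FWHM -> sigma
    prof = np.empty((len(times), len(x)))
    for k, t in enumerate(times):
        base = config.baseline + config.chromatin_peak_amplitude * np.exp(
            -0.5 * ((x - config.chromatin_peak_position) / config.chromatin_peak_width) ** 2
        )
        recovered = config.weight_fast * (1 - math.exp(-t / config.tau_fast)) + (
            1 - config.weight_fast
        ) * min(t / config.tau_slow, 1.0)
        depth = config.bleach_depth * (1.0 - recovered)
        center = config.trough_start + config.drift_velocity * t
        trough = depth * np.exp(-0.5 * ((x - center) / sig_tr) ** 2)
        prof[k] = base * (1.0 - trough)
        if config.noise_sd > 0:
            prof[k] += rng.normal(0.0, config.noise_sd, len(x))
    return IntensityProfileSeries(positions=x * 1000.0, intensities=prof, times=times)
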