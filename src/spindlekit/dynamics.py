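"""Dynamic-imaging analyses: EB-comet velocimetry and FRAP profiles.

Growing microtubule plus-ends carry EBP-2 comets; their speed and
direction per spindle region are estimated by spatio-temporal correlation
of detected comet positions, which sidesteps per-comet linking in the
crowded spindle.  FRAP intensity-profile series along the pole-to-pole
axis are analysed for bleach-mark drift (relative to the chromatin peak)
and recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import linregress
from skimage.feature import peak_local_max

__all__ = [
    "SpotSet",
    "RegionSpec",
    "IntensityProfileSeries",
    "detect_spots",
    "stcorr_velocity",
    "frap_profile_analysis",
    "VelocityEstimate",
    "FrapProfileAnalysis",
    "EstimationError",
]


class EstimationError(RuntimeError):
    """Raised when an estimator has too little data in the queried region."""


@dataclass
class SpotSet:
    """Detected or ground-truth 2D spot positions per frame (pixels)."""

    positions: list  # list over frames of (n_i, 2) arrays, (row, col) px
    times: np.ndarray  # s, strictly increasing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if len(self.positions) != len(self.times):
            raise ValueError("positions and times length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.positions = [np.asarray(p, float).reshape(-1, 2) for p in self.positions]


@dataclass(frozen=True)
class RegionSpec:
    """Annular (optionally sector-limited) analysis region about the
    centrosome, mimicking the spindle / chromosomes / inner- and
    outer-astral regions of the live-imaging analysis."""

    kind: str  # spindle | chromosomes | inner_astral | outer_astral | custom
    r_in: float  # um
    r_out: float  # um
    angle_range: Optional[tuple[float, float]] = None  # radians, optional sector

    def __post_init__(self) -> None:
        if not (0 <= self.r_in < self.r_out):
            raise ValueError("need 0 <= r_in < r_out")

    def contains(self, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
        ok = (r >= self.r_in) & (r < self.r_out)
        if self.angle_range is not None:
            lo, hi = self.angle_range
            th = np.mod(theta - lo, 2 * np.pi)
            ok &= th <= np.mod(hi - lo, 2 * np.pi)
        return ok


#: Default analysis regions (radii in um from the centrosome).
DEFAULT_REGIONS = {
    "inner_astral": RegionSpec("inner_astral", 0.5, 2.5),
    "spindle": RegionSpec("spindle", 2.5, 5.0),
    "chromosomes": RegionSpec("chromosomes", 5.0, 7.0),
    "outer_astral": RegionSpec("outer_astral", 7.0, 10.0),
}


@dataclass
class IntensityProfileSeries:
    """Axial intensity profiles over time (common position grid)."""

    positions: np.ndarray  # nm along the pole-to-pole axis
    intensities: np.ndarray  # (n_times, n_positions)
    times: np.ndarray  # s

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        self.times = np.asarray(self.times, float)
        if self.intensities.shape != (len(self.times), len(self.positions)):
            raise ValueError("intensities must be (n_times, n_positions)")


# --------------------------------------------------------------------------
# spot detection
# --------------------------------------------------------------------------


def detect_spots(
    frames: np.ndarray,
    threshold: float = 4.0,
    min_separation: int = 3,
    times: Optional[np.ndarray] = None,
    sigma_small: float = 1.0,
    sigma_large: float = 4.0,
) -> SpotSet:
    """Detect comet-like blobs in each frame.

    Difference-of-Gaussians band-pass, local maxima at least
    ``min_separation`` px apart and above ``threshold`` (in units of the
    band-passed image's robust s.d.), then sub-pixel refinement by local
    intensity centroid.  Constant frames yield no spots.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (T, H, W) stack")
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    out = []
    for im in frames:
        bp = ndimage.gaussian_filter(im, sigma_small) - ndimage.gaussian_filter(im, sigma_large)
        scale = 1.4826 * np.median(np.abs(bp - np.median(bp)))
        if scale == 0:
            scale = float(bp.std())  # noise-free frames: sparse spots drive the MAD to zero
        if scale == 0:
            out.append(np.empty((0, 2)))
            continue
        peaks = peak_local_max(
            bp, min_distance=min_separation, threshold_abs=threshold * scale, exclude_border=2
        )
        refined = []
        for r, c in peaks:
            r0, r1 = max(r - 2, 0), min(r + 3, im.shape[0])
            c0, c1 = max(c - 2, 0), min(c + 3, im.shape[1])
            w = bp[r0:r1, c0:c1] - bp[r0:r1, c0:c1].min()
            if w.sum() == 0:
                refined.append((float(r), float(c)))
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            refined.append(((rr * w).sum() / w.sum(), (cc * w).sum() / w.sum()))
        out.append(np.asarray(refined, float).reshape(-1, 2))
    return SpotSet(positions=out, times=np.asarray(times, float))


# --------------------------------------------------------------------------
# spatio-temporal correlation velocimetry
# --------------------------------------------------------------------------


@dataclass
class VelocityEstimate:
    speed: float        # um/s, magnitude of radial velocity
    sign: int           # +1 away from the centrosome, -1 towards it
    displacement: float  # um, fitted mean peak displacement at the lag used
    lag: float           # s
    n_pairs: int

    @property
    def velocity(self) -> float:
        return self.sign * self.speed


def _radial_fields(
    positions: np.ndarray,
    centrosome_px: np.ndarray,
    region: RegionSpec,
    pixel_size: float,
    r_grid: np.ndarray,
    n_sectors: int,
    sigma_r: float,
):
    """Resynthesize anisotropic-wavelet radial profiles per azimuthal sector.

    Each spot contributes a Mexican-hat (Ricker) wavelet along its radius;
    the orthogonal (azimuthal) extent is represented by the sector width,
    which keeps circumferential motion permissible.
    """
    rel = (positions - centrosome_px) * pixel_size
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 0], rel[:, 1])
    ok = region.contains(r, theta)
    r = r[ok]
    theta = theta[ok]
    fields = np.zeros((n_sectors, len(r_grid)))
    if len(r) == 0:
        return fields, 0
    sector = np.floor((theta + np.pi) / (2 * np.pi) * n_sectors).astype(int) % n_sectors
    for rk, sk in zip(r, sector):
        x = (r_grid - rk) / sigma_r
        fields[sk] += (1 - x**2) * np.exp(-0.5 * x**2)  # Ricker wavelet
    return fields, len(r)


def stcorr_velocity(
    spots: SpotSet,
    region: RegionSpec,
    centrosome_px: Sequence[float],
    pixel_size: float,
    dt: float = 0.6,
    n_sectors: int = 24,
    sigma_r_px: float = 0.5,
    max_speed: float = 1.5,
    min_spots: int = 30,
) -> VelocityEstimate:
    """Radial comet velocity in a region by spatio-temporal correlation.

    Spot sets of frame pairs separated by (approximately) ``dt`` are
    resynthesized into per-sector radial wavelet fields, cross-correlated
    along the radius, averaged over sectors, circumferential positions and
    frame pairs, and the mean correlation peak is located by a Gaussian
    fit.  Velocity = peak displacement / dt; positive = outward.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    centrosome_px = np.asarray(centrosome_px, float)
    dr = pixel_size / 2.0
    sigma_r = sigma_r_px * pixel_size
    r_grid = np.arange(max(region.r_in - 0.5, 0.0), region.r_out + 0.5, dr)
    max_shift = int(math.ceil(max_speed * dt / dr))

    # pair frames separated by ~dt; the achievable lag on the frame grid
    # may differ from the request, so the realised lag is used throughout
    times = spots.times
    pairs = []
    for i, t in enumerate(times):
        j = int(np.argmin(np.abs(times - (t + dt))))
        if j > i and abs(times[j] - t - dt) < 0.3 * dt:
            pairs.append((i, j, times[j] - t))
    if not pairs:
        raise EstimationError("no frame pairs at the requested lag")
    lag = float(np.median([p[2] for p in pairs]))
    pairs = [(i, j) for i, j, l in pairs if abs(l - lag) < 1e-9]

    lags = np.arange(-max_shift, max_shift + 1)
    acc = np.zeros(len(lags))
    n_spots_used = 0
    n_used_pairs = 0
    for i, j in pairs:
        fa, na = _radial_fields(spots.positions[i], centrosome_px, region, pixel_size, r_grid, n_sectors, sigma_r)
        fb, nb = _radial_fields(spots.positions[j], centrosome_px, region, pixel_size, r_grid, n_sectors, sigma_r)
        if na == 0 or nb == 0:
            continue
        n_spots_used += na + nb
        n_used_pairs += 1
        for s in range(n_sectors):
            a = fa[s]
            b = fb[s]
            if not a.any() or not b.any():
                continue
            for k, ell in enumerate(lags):
                if ell >= 0:
                    acc[k] += float(a[: len(a) - ell] @ b[ell:])
                else:
                    acc[k] += float(a[-ell:] @ b[: len(b) + ell])
    if n_used_pairs == 0 or n_spots_used < min_spots:
        raise EstimationError("too few spots in region to estimate a velocity")

    # Gaussian fit around the correlation peak for sub-grid displacement
    k0 = int(np.argmax(acc))
    w = 4
    sel = slice(max(k0 - w, 0), min(k0 + w + 1, len(lags)))
    x = lags[sel] * dr
    y = acc[sel]
    y0 = y.min()

    def gauss(xx, amp, mu, sig):
        return amp * np.exp(-0.5 * ((xx - mu) / sig) ** 2)

    try:
        popt, _ = curve_fit(
            gauss, x, y - y0, p0=[max(y.max() - y0, 1e-9), lags[k0] * dr, 2 * dr], maxfev=10000
        )
        disp = float(popt[1])
    except RuntimeError:
        disp = float(lags[k0] * dr)
    speed = abs(disp) / lag
    sign = 1 if disp >= 0 else -1
    return VelocityEstimate(speed=speed, sign=sign, displacement=disp, lag=lag, n_pairs=n_used_pairs)


# --------------------------------------------------------------------------
# FRAP profile analysis
# --------------------------------------------------------------------------


@dataclass
class FrapProfileAnalysis:
    velocity: float            # um/s, positive toward the chromosomes
    velocity_stderr: float
    times: np.ndarray
    trough_positions: np.ndarray  # nm, relative to the chromatin peak
    recovery: np.ndarray          # trough amplitude / mirrored-position amplitude
    half_time: Optional[float]    # s


def _gauss_offset(xx, a, mu, sig, c):
    return a * np.exp(-0.5 * ((xx - mu) / sig) ** 2) + c


def _fit_gaussian_peak(
    x: np.ndarray, y: np.ndarray, window: float, exclude: Optional[tuple] = None
) -> np.ndarray:
    """Gaussian + offset fitted around the global maximum.

    ``exclude`` masks out an interval (e.g. the bleach trough) so the dip
    does not bias the peak centre.  Returns (a, mu, sig, c).
    """
    i0 = int(np.argmax(y))
    sel = np.abs(x - x[i0]) <= window
    if exclude is not None:
        sel &= ~((x >= exclude[0]) & (x <= exclude[1]))
    p0 = [y[i0] - y[sel].min(), x[i0], window / 3, y[sel].min()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(_gauss_offset, x[sel], y[sel], p0=p0, maxfev=10000)
    return popt


def _quadratic_trough(x: np.ndarray, y: np.ndarray, guess: float, window: float) -> float:
    """Trough location from the vertex of a quadratic fit around a guess."""
    sel = np.abs(x - guess) <= window
    if sel.sum() < 3:
        raise EstimationError("too few samples around the trough")
    c = np.polyfit(x[sel], y[sel], 2)
    if c[0] <= 0:
        raise EstimationError("no convex trough found")
    return float(-c[1] / (2 * c[0]))


def frap_profile_analysis(
    series: IntensityProfileSeries,
    peak_window: float = 2000.0,   # nm, chromatin Gaussian fit window
    trough_window: float = 1000.0,  # nm, quadratic fit window
    plateau_tail: float = 10.0,     # s
    min_dip: float = 0.03,          # minimum fractional dip to accept a mark
    max_step: float = 600.0,        # nm, largest credible frame-to-frame motion
) -> FrapProfileAnalysis:
    """Bleach-mark drift and recovery from an axial profile series.

    Profiles are aligned per time point on the chromatin peak (Gaussian
    fit); the photobleached trough is located as the vertex of a quadratic
    fit; its drift velocity comes from a linear fit of position vs time
    (positive toward the chromosomes).  Recovery compares the intensity at
    the trough centre with the intensity at the position mirrored across
    the chromatin peak; the half-time is when recovery first reaches
    halfway between its initial value and its plateau.
    """
    x = series.positions
    troughs = []
    recov = []
    last_pos = None
    for k, t in enumerate(series.times):
        y = series.intensities[k]
        try:
            p1 = _fit_gaussian_peak(x, y, peak_window)
            # locate the trough roughly, then refit the peak with the
            # trough masked out so the dip cannot bias the alignment
            base1 = _gauss_offset(x, *p1)
            mask = np.abs(x - p1[1]) > peak_window / 2
            ratio = ndimage.uniform_filter1d(y / base1, 5)
            rough = x[mask][int(np.argmin(ratio[mask]))]
            p2 = _fit_gaussian_peak(
                x, y, peak_window, exclude=(rough - 1.5 * trough_window, rough + 1.5 * trough_window)
            )
        except RuntimeError as e:
            raise EstimationError(f"chromatin peak fit failed at t={t}") from e
        peak = float(p2[1])
        xa = x - peak
        # trough position on the baseline-normalised profile, so the
        # sloping chromatin flank does not displace the vertex
        yn = y / _gauss_offset(x, *p2)
        guess = rough - peak
        if last_pos is not None and abs(guess - last_pos) > max_step:
            guess = last_pos  # a real mark cannot jump; re-search locally
        try:
            pos = _quadratic_trough(xa, yn, guess, trough_window)
            dip = 1.0 - float(np.interp(pos, xa, yn))
            if dip < min_dip or (last_pos is not None and abs(pos - last_pos) > max_step):
                raise EstimationError("trough indistinguishable from background")
            last_pos = pos
        except EstimationError:
            # mark fully recovered / indistinguishable from background:
            # excluded from the drift fit, recovery read at the last
            # resolved mark position
            if last_pos is None:
                raise
            pos = math.nan
        troughs.append(pos)
        eval_pos = pos if math.isfinite(pos) else last_pos
        i_tr = float(np.interp(eval_pos, xa, y))
        i_mir = float(np.interp(-eval_pos, xa, y))
        recov.append(i_tr / i_mir if i_mir != 0 else np.nan)
    troughs = np.asarray(troughs)
    recov = np.asarray(recov)

    dist = np.abs(troughs)  # nm from the chromatin peak
    ok = np.isfinite(dist)
    if ok.sum() < 3:
        raise EstimationError("too few resolved trough positions for a drift fit")
    fit = linregress(series.times[ok], dist[ok])
    velocity = -fit.slope / 1000.0  # nm/s -> um/s; positive toward chromosomes
    stderr = fit.stderr / 1000.0 if fit.stderr is not None else math.nan

    plateau = float(np.nanmean(recov[series.times >= series.times[-1] - plateau_tail]))
    r0 = recov[0]
    half = r0 + 0.5 * (plateau - r0)
    half_time: Optional[float] = None
    if plateau > r0:
        above = np.nonzero(recov >= half)[0]
        if len(above):
            i = above[0]
            if i == 0:
                half_time = float(series.times[0])
            else:
                t0, t1 = series.times[i - 1], series.times[i]
                y0, y1 = recov[i - 1], recov[i]
                half_time = float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))
    return FrapProfileAnalysis(
        velocity=float(velocity),
        velocity_stderr=float(stderr),
        times=series.times,
        trough_positions=troughs,
        recovery=recov,
        half_time=half_time,
    )
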