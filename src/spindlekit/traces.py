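"""Containers for 3D microtubule reconstructions of a half spindle.

Coordinates are in nanometres.  The half-spindle axis frame places the
mother centriole of the pole at the origin with the unit ``axis`` vector
pointing towards the chromosomes; the metaphase plate sits at
``plate_position`` nm along that axis.  Chromosome surfaces available for
kinetochore-microtubule (KMT) attachment are modelled as coplanar
rectangles in the plate plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import polyline_length

END_MORPHOLOGIES = ("open", "closed", "undetermined")
MT_CLASSES = ("KMT", "SMT", "AMT")


@dataclass
class MicrotubuleTrace:
    """A single traced microtubule: an ordered polyline with end labels.

    ``end_start`` / ``end_end`` give the tip morphology (open, closed or
    undetermined) at the first and last polyline vertex respectively.
    ``mt_class`` is an optional ground-truth or assigned class label.
    """

    id: int
    points: np.ndarray  # (n, 3) nm
    end_start: str = "undetermined"
    end_end: str = "undetermined"
    mt_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 2:
            raise ValueError(f"trace {self.id}: points must be an (n>=2, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"trace {self.id}: non-finite coordinates")
        for e in (self.end_start, self.end_end):
            if e not in END_MORPHOLOGIES:
                raise ValueError(f"trace {self.id}: unknown end morphology {e!r}")
        if self.mt_class is not None and self.mt_class not in MT_CLASSES:
            raise ValueError(f"trace {self.id}: unknown class {self.mt_class!r}")

    @property
    def length(self) -> float:
        """Arc length in nm."""
        return polyline_length(self.points)

    def centre_of_mass(self) -> np.ndarray:
        """Length-weighted centre of mass (segment midpoints weighted by length)."""
        mids = 0.5 * (self.points[:-1] + self.points[1:])
        w = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if w.sum() == 0:
            return self.points.mean(axis=0)
        return (mids * w[:, None]).sum(axis=0) / w.sum()


@dataclass
class ChromosomeRect:
    """Rectangular chromosome attachment surface in the plate plane.

    ``center_uv`` is the rectangle centre in the in-plane (u, v) basis of
    the reconstruction, ``width``/``height`` its extents, all nm.
    """

    center_uv: tuple[float, float]
    width: float
    height: float

    @property
    def area_nm2(self) -> float:
        return float(self.width * self.height)

    def contains_uv(self, u: float, v: float, pad: float = 0.0) -> bool:
        cu, cv = self.center_uv
        return (abs(u - cu) <= self.width / 2 + pad) and (abs(v - cv) <= self.height / 2 + pad)


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis (u, v) orthogonal to the axis."""
    axis = np.asarray(axis, float)
    helper = np.array([0.0, 1.0, 0.0]) if abs(axis[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


@dataclass
class SpindleReconstruction:
    """A half-spindle reconstruction: traces plus the frame geometry."""

    traces: list[MicrotubuleTrace]
    pole: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mother centriole, nm
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    plate_position: float = 6500.0  # nm along axis
    chromosome_rects: list[ChromosomeRect] = field(default_factory=list)
    kinetochore_zone_thickness: float = 500.0  # nm, pole-side slab on each rectangle
    volume_bounds: Optional[np.ndarray] = None  # (2, 3) [[lo], [hi]] nm
    stage: str = "metaphase"
    section_boundaries_z: Optional[np.ndarray] = None  # nm, for stitching QC

    def __post_init__(self) -> None:
        self.pole = np.asarray(self.pole, float)
        self.axis = np.asarray(self.axis, float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("degenerate spindle axis")
        self.axis = self.axis / n
        if self.volume_bounds is not None:
            self.volume_bounds = np.asarray(self.volume_bounds, float).reshape(2, 3)

    # -- frame helpers ---------------------------------------------------
    @property
    def basis_uv(self) -> tuple[np.ndarray, np.ndarray]:
        return _orthonormal_basis(self.axis)

    def axial_coord(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points along the axis from the pole (nm)."""
        return (np.atleast_2d(points) - self.pole) @ self.axis

    def plane_coords(self, points: np.ndarray) -> np.ndarray:
        """(u, v) in-plane coordinates of points (nm)."""
        u, v = self.basis_uv
        rel = np.atleast_2d(points) - self.pole
        return np.stack([rel @ u, rel @ v], axis=1)

    def radial_dist(self, points: np.ndarray) -> np.ndarray:
        """Distance of points from the spindle axis (nm)."""
        return np.linalg.norm(self.plane_coords(points), axis=1)

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.traces)

    def trace_by_id(self, tid: int) -> MicrotubuleTrace:
        for t in self.traces:
            if t.id == tid:
                return t
        raise KeyError(f"no trace with id {tid}")

    def with_labels(self, labels: dict[int, str]) -> "SpindleReconstruction":
        """Copy with ``mt_class`` set from a {trace id: class} mapping."""
        new = [replace(t, mt_class=labels.get(t.id, t.mt_class)) for t in self.traces]
        return replace(self, traces=new)

    def lengths(self, ids: Optional[Sequence[int]] = None) -> np.ndarray:
        sel = self.traces if ids is None else [self.trace_by_id(i) for i in ids]
        return np.array([t.length for t in sel])
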