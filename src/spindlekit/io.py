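"""File formats: trace sets, parameter files and tabular outputs.

The pipeline's native trace formats are

* ``json`` — a single lossless document holding traces (nm coordinates),
  end annotations, class labels and the spindle frame geometry;
* ``csv`` — a points table ``trace_id, vertex, x, y, z`` plus a JSON
  sidecar ``<stem>.meta.json`` with per-trace annotations and frame
  geometry;
* ``amira_spatialgraph_ascii`` — a read-only subset of the Amira
  HxSpatialGraph ASCII format (VERTEX / EDGE / POINT sections), the
  format the original filament tracings lived in.

Simulation parameter files are YAML or JSON mirroring the parameter
table's keys.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .simulate import HistogramProfile, SimParams, TruncatedExponentialProfile
from .traces import ChromosomeRect, MicrotubuleTrace, SpindleReconstruction

__all__ = [
    "read_traces",
    "write_traces",
    "read_sim_params",
    "write_sim_params",
    "write_comet_movie",
    "read_comet_movie",
    "write_frap_series",
    "read_frap_series",
    "TraceFormatError",
]

DIALECTS = ("json", "csv", "amira_spatialgraph_ascii")


class TraceFormatError(ValueError):
    """Malformed trace file; message names the offending location."""


# --------------------------------------------------------------------------
# JSON / CSV round trip
# --------------------------------------------------------------------------


def _recon_meta(recon: SpindleReconstruction) -> dict:
    return {
        "pole": recon.pole.tolist(),
        "axis": recon.axis.tolist(),
        "plate_position": recon.plate_position,
        "kinetochore_zone_thickness": recon.kinetochore_zone_thickness,
        "chromosome_rects": [
            {"center_uv": list(r.center_uv), "width": r.width, "height": r.height}
            for r in recon.chromosome_rects
        ],
        "volume_bounds": None if recon.volume_bounds is None else recon.volume_bounds.tolist(),
        "stage": recon.stage,
        "section_boundaries_z": None
        if recon.section_boundaries_z is None
        else list(np.asarray(recon.section_boundaries_z, float)),
    }


def _recon_from_meta(meta: dict, traces: list[MicrotubuleTrace]) -> SpindleReconstruction:
    return SpindleReconstruction(
        traces=traces,
        pole=np.asarray(meta["pole"], float),
        axis=np.asarray(meta["axis"], float),
        plate_position=float(meta["plate_position"]),
        chromosome_rects=[
            ChromosomeRect(tuple(r["center_uv"]), r["width"], r["height"])
            for r in meta.get("chromosome_rects", [])
        ],
        kinetochore_zone_thickness=float(meta.get("kinetochore_zone_thickness", 500.0)),
        volume_bounds=None if meta.get("volume_bounds") is None else np.asarray(meta["volume_bounds"]),
        stage=meta.get("stage", "metaphase"),
        section_boundaries_z=None
        if meta.get("section_boundaries_z") is None
        else np.asarray(meta["section_boundaries_z"], float),
    )


def write_traces(recon: SpindleReconstruction, path, dialect: str = "json") -> None:
    """Write a reconstruction in the given dialect (json or csv)."""
    path = Path(path)
    if dialect == "json":
        doc = {
            "format": "spindlekit-traces",
            "meta": _recon_meta(recon),
            "traces": [
                {
                    "id": int(t.id),
                    "points": np.round(t.points, 4).tolist(),
                    "end_start": t.end_start,
                    "end_end": t.end_end,
                    "mt_class": t.mt_class,
                }
                for t in recon.traces
            ],
        }
        path.write_text(json.dumps(doc))
    elif dialect == "csv":
        rows = []
        for t in recon.traces:
            for k, p in enumerate(t.points):
                rows.append((t.id, k, p[0], p[1], p[2]))
        pd.DataFrame(rows, columns=["trace_id", "vertex", "x", "y", "z"]).to_csv(
            path, index=False, float_format="%.4f"
        )
        meta = _recon_meta(recon)
        meta["trace_annotations"] = {
            str(t.id): {"end_start": t.end_start, "end_end": t.end_end, "mt_class": t.mt_class}
            for t in recon.traces
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta))
    else:
        raise TraceFormatError(f"unknown write dialect {dialect!r}")


def read_traces(path, dialect: Optional[str] = None) -> SpindleReconstruction:
    """Read a reconstruction; the dialect is inferred from the suffix when
    not given (.json, .csv, .am)."""
    path = Path(path)
    if dialect is None:
        dialect = {".json": "json", ".csv": "csv", ".am": "amira_spatialgraph_ascii"}.get(
            path.suffix.lower()
        )
        if dialect is None:
            raise TraceFormatError(f"cannot infer dialect from suffix of {path.name}")
    if dialect not in DIALECTS:
        raise TraceFormatError(f"unknown dialect {dialect!r}")
    if dialect == "json":
        return _read_json(path)
    if dialect == "csv":
        return _read_csv(path)
    return _read_amira(path)


def _read_json(path: Path) -> SpindleReconstruction:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise TraceFormatError(f"{path.name}: invalid JSON at line {e.lineno}: {e.msg}") from e
    if doc.get("format") != "spindlekit-traces":
        raise TraceFormatError(f"{path.name}: missing 'spindlekit-traces' format marker")
    traces = []
    for i, t in enumerate(doc["traces"]):
        try:
            traces.append(
                MicrotubuleTrace(
                    id=int(t["id"]),
                    points=np.asarray(t["points"], float),
                    end_start=t.get("end_start", "undetermined"),
                    end_end=t.get("end_end", "undetermined"),
                    mt_class=t.get("mt_class"),
                )
            )
        except (KeyError, ValueError) as e:
            raise TraceFormatError(f"{path.name}: trace entry {i}: {e}") from e
    return _recon_from_meta(doc["meta"], traces)


def _read_csv(path: Path) -> SpindleReconstruction:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"{path.name}: {e}") from e
    required = {"trace_id", "vertex", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TraceFormatError(f"{path.name}: missing columns {sorted(required - set(df.columns))}")
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise TraceFormatError(f"{meta_path.name}: sidecar metadata file not found")
    meta = json.loads(meta_path.read_text())
    ann = meta.get("trace_annotations", {})
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("vertex")
        if not np.array_equal(grp["vertex"].to_numpy(), np.arange(len(grp))):
            raise TraceFormatError(f"{path.name}: trace {tid}: vertices not contiguous from 0")
        a = ann.get(str(tid), {})
        traces.append(
            MicrotubuleTrace(
                id=int(tid),
                points=grp[["x", "y", "z"]].to_numpy(float),
                end_start=a.get("end_start", "undetermined"),
                end_end=a.get("end_end", "undetermined"),
                mt_class=a.get("mt_class"),
            )
        )
    return _recon_from_meta(meta, traces)


# --------------------------------------------------------------------------
# Amira SpatialGraph ASCII subset
# --------------------------------------------------------------------------


def _read_amira(path: Path) -> SpindleReconstruction:
    """Parse the VERTEX/EDGE/POINT sections of an ASCII HxSpatialGraph.

    Each EDGE becomes one trace, using its EdgePointCoordinates.  Anything
    outside the supported subset raises a loud error.
    """
    text = path.read_text()
    if "AmiraMesh 3D ASCII" not in text.splitlines()[0]:
        raise TraceFormatError(f"{path.name}: line 1: not an AmiraMesh 3D ASCII file")
    defines = dict(re.findall(r"define\s+(\w+)\s+(\d+)", text))
    for need in ("VERTEX", "EDGE", "POINT"):
        if need not in defines:
            raise TraceFormatError(f"{path.name}: missing 'define {need}'")
    n_edge, n_point = int(defines["EDGE"]), int(defines["POINT"])

    markers = {
        m.group(2): m.group(1)
        for m in re.finditer(
            r"(?:VERTEX|EDGE|POINT)\s*{\s*(?:float|int)\[?\d?\]?\s+(\w+)\s*}\s*@(\d+)", text
        )
    }
    blocks = {}
    for m in re.finditer(r"^@(\d+)\s*$([^@]*)", text, flags=re.M):
        blocks[m.group(1)] = m.group(2)

    def block_for(field: str) -> np.ndarray:
        tag = next((k for k, v in markers.items() if v == field), None)
        if tag is None or tag not in blocks:
            raise TraceFormatError(f"{path.name}: missing data section for {field}")
        return np.array(blocks[tag].split(), dtype=float)

    conn = block_for("EdgeConnectivity").astype(int).reshape(n_edge, 2)  # noqa: F841
    npts = block_for("NumEdgePoints").astype(int)
    coords = block_for("EdgePointCoordinates").reshape(n_point, 3)
    if npts.sum() != n_point:
        raise TraceFormatError(f"{path.name}: NumEdgePoints sum {npts.sum()} != POINT count {n_point}")
    traces = []
    offset = 0
    for i, n in enumerate(npts):
        if n < 2:
            raise TraceFormatError(f"{path.name}: edge {i}: fewer than 2 points")
        traces.append(MicrotubuleTrace(id=i, points=coords[offset : offset + n]))
        offset += n
    bounds = np.vstack([coords.min(axis=0) - 1.0, coords.max(axis=0) + 1.0])
    return SpindleReconstruction(traces=traces, volume_bounds=bounds)


# --------------------------------------------------------------------------
# comet movies and FRAP profile series
# --------------------------------------------------------------------------


def write_comet_movie(movie, path) -> None:
    """Multi-page TIFF plus a JSON sidecar with times, calibration and
    ground-truth spot positions."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "times_s": movie.times.tolist(),
        "pixel_size_um": movie.pixel_size,
        "centrosome_px": movie.centrosome_px.tolist(),
        "truth": [p.tolist() for p in movie.truth.positions],
    }
    path.with_suffix(".tracks.json").write_text(json.dumps(sidecar))


def read_comet_movie(path):
    """Read a movie written by :func:`write_comet_movie`."""
    import tifffile

    from .dynamics import SpotSet
    from .synthetic import CometMovie

    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".tracks.json").read_text())
    times = np.asarray(meta["times_s"], float)
    truth = SpotSet(
        positions=[np.asarray(p, float).reshape(-1, 2) for p in meta["truth"]], times=times
    )
    return CometMovie(
        frames=frames,
        times=times,
        pixel_size=float(meta["pixel_size_um"]),
        centrosome_px=np.asarray(meta["centrosome_px"], float),
        truth=truth,
        tracks=[],
    )


def write_frap_series(series, path) -> None:
    """Long-format CSV: position_nm, time_s, intensity."""
    n_t, n_x = series.intensities.shape
    pd.DataFrame(
        {
            "position_nm": np.tile(series.positions, n_t),
            "time_s": np.repeat(series.times, n_x),
            "intensity": series.intensities.ravel(),
        }
    ).to_csv(path, index=False)


def read_frap_series(path):
    from .dynamics import IntensityProfileSeries

    df = pd.read_csv(path)
    times = np.unique(df["time_s"].to_numpy())
    positions = np.unique(df["position_nm"].to_numpy())
    piv = df.pivot(index="time_s", columns="position_nm", values="intensity")
    return IntensityProfileSeries(
        positions=positions, intensities=piv.to_numpy(), times=times
    )


# --------------------------------------------------------------------------
# simulation parameter files
# --------------------------------------------------------------------------


def write_sim_params(params: SimParams, path) -> None:
    prof = params.nucleation_profile
    if isinstance(prof, TruncatedExponentialProfile):
        pdoc = {"kind": "truncated_exponential", "scale": prof.scale, "lo": prof.lo, "hi": prof.hi}
    elif isinstance(prof, HistogramProfile):
        pdoc = {"kind": "histogram", "edges": list(prof.edges), "weights": list(prof.weights)}
    else:
        raise ValueError("unsupported nucleation profile type for serialisation")
    doc = {
        "model_kind": params.model_kind,
        "v_g": params.v_g,
        "v_d": params.v_d,
        "kappa": params.kappa,
        "r": "inf" if math.isinf(params.r) else params.r,
        "L": params.L,
        "R": params.R,
        "nucleation_profile": pdoc,
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=1))


def read_sim_params(path) -> SimParams:
    path = Path(path)
    doc = (
        yaml.safe_load(path.read_text())
        if path.suffix in (".yaml", ".yml")
        else json.loads(path.read_text())
    )
    pdoc = doc.pop("nucleation_profile", None)
    if pdoc is not None:
        if pdoc["kind"] == "truncated_exponential":
            doc["nucleation_profile"] = TruncatedExponentialProfile(
                scale=pdoc["scale"], lo=pdoc.get("lo", 0.0), hi=pdoc.get("hi", 3.0)
            )
        elif pdoc["kind"] == "histogram":
            doc["nucleation_profile"] = HistogramProfile(
                edges=tuple(pdoc["edges"]), weights=tuple(pdoc["weights"])
            )
        else:
            raise ValueError(f"unknown nucleation profile kind {pdoc['kind']!r}")
    if doc.get("r") == "inf":
        doc["r"] = math.inf
    return SimParams(**doc)
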