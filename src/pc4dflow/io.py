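"""On-disk representations: NIfTI volumes, JSON metadata, CSV tables.

Dataset layout (one directory per acquisition)::

    vx.nii.gz, vy.nii.gz, vz.nii.gz   4D (x, y, z, t) velocity components, mm/s
    mag.nii.gz                        4D magnitude
    meta.json                         geometry/timing metadata (venc, cycle_ms,
                                      trigger_times_ms, voxel_size, origin,
                                      coverage, stage, coordinate convention)

Write then read is the identity on every field: voxel data are stored as
float64 and metadata as JSON. Readers validate consistency (shapes, timing
monotonicity, presence of venc) and reject malformed datasets naming the
offending file rather than reinterpreting them.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .fields import COORDINATE_CONVENTION, FlowCurve, PlaneDefinition, VelocityField4D
from .flowquant import VesselContour
from .pathlines import PathlineSet

_COMPONENT_FILES = ("vx.nii.gz", "vy.nii.gz", "vz.nii.gz")
_MAG_FILE = "mag.nii.gz"
_META_FILE = "meta.json"


def _affine(field: VelocityField4D) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(field.voxel_size)
    aff[:3, 3] = field.origin
    return aff


def _save_4d(path: Path, data_t_first: np.ndarray, affine: np.ndarray) -> None:
    # Internal layout is (t, x, y, z); NIfTI wants (x, y, z, t).
    img = nib.Nifti1Image(np.moveaxis(data_t_first, 0, -1).astype(np.float64), affine)
    nib.save(img, str(path))


def write_dataset(field: VelocityField4D, path) -> None:
    """Write a 4D dataset directory (velocity components, magnitude, metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(field)
    for c, name in enumerate(_COMPONENT_FILES):
        _save_4d(path / name, field.velocity[c], aff)
    _save_4d(path / _MAG_FILE, field.magnitude, aff)
    meta = {
        "voxel_size_mm": field.voxel_size.tolist(),
        "origin_mm": field.origin.tolist(),
        "trigger_times_ms": field.trigger_times_ms.tolist(),
        "cycle_ms": float(field.cycle_ms),
        "venc_mm_s": float(field.venc),
        "coverage": field.coverage,
        "covered_ms": float(field.covered_ms),
        "stage": field.stage,
        "coordinate_convention": COORDINATE_CONVENTION,
    }
    (path / _META_FILE).write_text(json.dumps(meta, indent=2))


def read_dataset(path) -> VelocityField4D:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / _META_FILE
    if not meta_path.exists():
        raise FormatError(f"missing metadata file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("venc_mm_s", "cycle_ms", "trigger_times_ms", "voxel_size_mm", "origin_mm"):
        if key not in meta:
            raise FormatError(f"metadata {meta_path} lacks required key {key!r}")

    comps = []
    for name in _COMPONENT_FILES:
        f = path / name
        if not f.exists():
            raise FormatError(f"missing velocity component file: {f}")
        comps.append(np.moveaxis(np.asarray(nib.load(str(f)).dataobj, dtype=float), -1, 0))
    mag_path = path / _MAG_FILE
    if not mag_path.exists():
        raise FormatError(f"missing magnitude file: {mag_path}")
    mag = np.moveaxis(np.asarray(nib.load(str(mag_path)).dataobj, dtype=float), -1, 0)

    shapes = {c.shape for c in comps} | {mag.shape}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent volume shapes across files in {path}: {shapes}")

    try:
        return VelocityField4D(
            velocity=np.stack(comps),
            magnitude=mag,
            voxel_size=np.asarray(meta["voxel_size_mm"], dtype=float),
            origin=np.asarray(meta["origin_mm"], dtype=float),
            trigger_times_ms=np.asarray(meta["trigger_times_ms"], dtype=float),
            cycle_ms=float(meta["cycle_ms"]),
            venc=float(meta["venc_mm_s"]),
            coverage=meta.get("coverage", "full"),
            covered_ms=float(meta.get("covered_ms", meta["cycle_ms"])),
            stage=meta.get("stage", "wrapped"),
        )
    except ValueError as exc:
        raise FormatError(f"invalid dataset in {path}: {exc}") from exc


def write_series(series, nii_path, json_path) -> None:
    """Write a 2D series: NIfTI (nu, nv, 1, t) + JSON (plane, timing, venc)."""
    from .fields import Series2D  # local import keeps module load order simple

    assert isinstance(series, Series2D)
    data = np.moveaxis(series.v_through, 0, -1)  # (nu, nv, t)
    mag = np.moveaxis(series.magnitude, 0, -1)
    # layout: (nu, nv, t, 2) with channel 0 = v_through, 1 = magnitude
    img = nib.Nifti1Image(np.stack([data, mag], axis=-1), np.eye(4))
    nib.save(img, str(nii_path))
    meta = {
        "plane": series.plane.to_dict(),
        "trigger_times_ms": series.trigger_times_ms.tolist(),
        "cycle_ms": float(series.cycle_ms),
        "venc_mm_s": float(series.venc),
        "coverage": series.coverage,
        "covered_ms": float(series.covered_ms),
        "coordinate_convention": COORDINATE_CONVENTION,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def read_series(nii_path, json_path):
    from .fields import Series2D

    meta_path = Path(json_path)
    if not meta_path.exists():
        raise FormatError(f"missing series metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "venc_mm_s" not in meta:
        raise FormatError(f"series metadata {meta_path} lacks venc_mm_s")
    arr = np.asarray(nib.load(str(nii_path)).dataobj, dtype=float)  # (nu, nv, t, 2)
    v = np.moveaxis(arr[..., 0], -1, 0)
    mag = np.moveaxis(arr[..., 1], -1, 0)
    return Series2D(
        v_through=v,
        magnitude=mag,
        valid=~np.isnan(v[0]),
        plane=PlaneDefinition.from_dict(meta["plane"]),
        trigger_times_ms=np.asarray(meta["trigger_times_ms"], dtype=float),
        cycle_ms=float(meta["cycle_ms"]),
        venc=float(meta["venc_mm_s"]),
        coverage=meta.get("coverage", "full"),
        covered_ms=float(meta.get("covered_ms", meta["cycle_ms"])),
    )


def write_mask(mask: np.ndarray, field: VelocityField4D, path) -> None:
    """Write a boolean volume as NIfTI (uint8) with the field's geometry."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(field))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_plane(plane: PlaneDefinition, path) -> None:
    Path(path).write_text(json.dumps(plane.to_dict(), indent=2))


def read_plane(path) -> PlaneDefinition:
    try:
        return PlaneDefinition.from_dict(json.loads(Path(path).read_text()))
    except KeyError as exc:
        raise FormatError(f"plane file {path} lacks field {exc}") from exc


def write_flow_curve(curve: FlowCurve, csv_path, json_path=None) -> None:
    """Flow curve as CSV (time_ms, flow_ml_s) plus a JSON sidecar of scalars."""
    df = pd.DataFrame({"time_ms": curve.time_ms, "flow_ml_s": curve.flow_ml_s})
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            "stroke_volume_ml": float(curve.stroke_volume_ml),
            "peak_flow_ml_s": float(curve.peak_flow_ml_s),
            "coverage": curve.coverage,
            "covered_ms": float(curve.covered_ms),
            "vessel_label": curve.vessel_label,
        }
        Path(json_path).write_text(json.dumps(sidecar, indent=2))


def read_flow_curve(csv_path, json_path=None) -> FlowCurve:
    df = pd.read_csv(csv_path)
    for col in ("time_ms", "flow_ml_s"):
        if col not in df.columns:
            raise FormatError(f"flow-curve CSV {csv_path} lacks column {col!r}")
    meta = json.loads(Path(json_path).read_text()) if json_path else {}
    t = df["time_ms"].to_numpy(dtype=float)
    q = df["flow_ml_s"].to_numpy(dtype=float)
    from .flowquant import _cyclic_sv_ml  # avoid cycle at module import

    sv = meta.get("stroke_volume_ml")
    covered = meta.get("covered_ms")
    coverage = meta.get("coverage", "full")
    if sv is None:
        cycle = covered if covered is not None else t[-1] + (t[1] - t[0])
        sv = _cyclic_sv_ml(t, q, cycle)
    return FlowCurve(
        time_ms=t,
        flow_ml_s=q,
        stroke_volume_ml=float(sv),
        peak_flow_ml_s=float(q.max()),
        coverage=coverage,
        covered_ms=covered,
        vessel_label=meta.get("vessel_label", "other"),
    )


def write_contour(contour: VesselContour, path) -> None:
    """Contour CSV with columns frame, vertex_index, u_mm, v_mm.

    A static contour is written as frame -1.
    """
    rows = []
    if contour.static or len(contour.polygons) == 1:
        frames = [(-1, contour.polygons[0])]
    else:
        frames = list(enumerate(contour.polygons))
    for f, poly in frames:
        for i, (u, v) in enumerate(poly):
            rows.append({"frame": f, "vertex_index": i, "u_mm": u, "v_mm": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contour(path, vessel_label: str = "other") -> VesselContour:
    df = pd.read_csv(path)
    for col in ("frame", "vertex_index", "u_mm", "v_mm"):
        if col not in df.columns:
            raise FormatError(f"contour CSV {path} lacks column {col!r}")
    polys = []
    static = (df["frame"] == -1).all()
    for _, grp in df.sort_values(["frame", "vertex_index"]).groupby("frame"):
        polys.append(grp[["u_mm", "v_mm"]].to_numpy(dtype=float))
    return VesselContour(polygons=polys, vessel_label=vessel_label, static=bool(static))


def write_pathlines(paths: PathlineSet, path) -> None:
    """Pathline CSV: particle_id, emitter_id, time_ms, x, y, z, inside_pool."""
    P, K, _ = paths.positions.shape
    pid = np.repeat(np.arange(P), K)
    eid = np.repeat(paths.emitter_ids, K)
    t = np.tile(paths.record_times_ms, P)
    xyz = paths.positions.reshape(P * K, 3)
    inside = (
        paths.inside_pool.reshape(P * K)
        if paths.inside_pool is not None
        else np.full(P * K, np.nan)
    )
    df = pd.DataFrame(
        {
            "particle_id": pid,
            "emitter_id": eid,
            "time_ms": t,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "inside_pool": inside,
        }
    )
    df = df[~np.isnan(df["x"])]  # rows before release carry no position
    df.to_csv(path, index=False)
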