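"""Readers and writers for the pipeline's on-disk formats.

CSV files are comma-separated UTF-8 with a header row and '.' decimals; all
coordinates are in μm.  Image stacks are multi-page TIFF, one file per
channel.  Deformation fields are stored as a dense ``.npy`` array plus a
JSON sidecar describing the control-grid geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracking import DeformationField
from .wss import ParticleTracks, ShearTrace, VolumeTrace, WallGeometry

__all__ = [
    "write_stack", "read_stack",
    "write_tracks", "read_tracks",
    "write_contours", "read_contours",
    "write_volume_trace", "read_volume_trace",
    "write_shear_trace", "read_shear_trace",
    "write_rois", "read_rois",
    "write_deformation_field", "read_deformation_field",
]


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_tracks(path, tracks: ParticleTracks) -> None:
    df = tracks.data.copy()
    df.attrs = {}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# frame_interval_s={tracks.frame_interval!r}\n")
        df.to_csv(fh, index=False)


def read_tracks(path) -> ParticleTracks:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# frame_interval_s="):
            raise ValueError("tracks CSV missing frame_interval_s header")
        dt = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return ParticleTracks(df, frame_interval=dt)


def write_contours(path, wall: WallGeometry) -> None:
    rows = []
    for i, (t, frame) in enumerate(zip(wall.times, wall.contours)):
        for c, poly in enumerate(frame):
            for v, (x, y) in enumerate(poly):
                rows.append((i, t, c, v, x, y))
    pd.DataFrame(rows, columns=["frame", "time_s", "contour", "vertex_index",
                                "x_um", "y_um"]).to_csv(path, index=False)


def read_contours(path) -> WallGeometry:
    df = pd.read_csv(path)
    times = []
    contours = []
    for f, grp in df.groupby("frame", sort=True):
        times.append(grp["time_s"].iloc[0])
        frame = []
        for _, sub in grp.groupby("contour", sort=True):
            sub = sub.sort_values("vertex_index")
            frame.append(sub[["x_um", "y_um"]].to_numpy())
        contours.append(frame)
    return WallGeometry(times=np.asarray(times), contours=contours)


def write_volume_trace(path, trace: VolumeTrace) -> None:
    pd.DataFrame({"t_s": trace.times, "volume_nl": trace.volumes}
                 ).to_csv(path, index=False)


def read_volume_trace(path) -> VolumeTrace:
    df = pd.read_csv(path)
    return VolumeTrace(times=df["t_s"].to_numpy(),
                       volumes=df["volume_nl"].to_numpy())


def write_shear_trace(path, trace: ShearTrace) -> None:
    cols = {"t_s": trace.times,
            "shear_rate_s": trace.shear_rate,
            "shear_stress_pa": trace.shear_stress}
    if trace.smoothed_rate is not None:
        cols["smoothed_rate_s"] = trace.smoothed_rate
        cols["smoothed_stress_pa"] = trace.smoothed_stress
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# method={trace.method} viscosity_mpas={trace.viscosity!r}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_shear_trace(path) -> ShearTrace:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# method="):
            raise ValueError("shear trace CSV missing provenance header")
        parts = dict(p.split("=") for p in header[2:].split())
        df = pd.read_csv(fh)
    smoothed = df["smoothed_rate_s"].to_numpy() \
        if "smoothed_rate_s" in df.columns else None
    return ShearTrace(times=df["t_s"].to_numpy(),
                      shear_rate=df["shear_rate_s"].to_numpy(),
                      viscosity=float(parts["viscosity_mpas"]),
                      method=parts["method"],
                      smoothed_rate=smoothed)


def write_rois(path, rois: dict[str, np.ndarray]) -> None:
    payload = {k: np.asarray(v, dtype=float).tolist() for k, v in rois.items()}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_rois(path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {k: np.asarray(v, dtype=float) for k, v in payload.items()}


def write_deformation_field(path_npy, field: DeformationField) -> None:
    path_npy = Path(path_npy)
    np.save(path_npy, field.coeffs)
    meta = {"image_shape": list(field.image_shape),
            "grid_spacing_px": field.grid_spacing_px}
    path_npy.with_suffix(".json").write_text(json.dumps(meta),
                                             encoding="utf-8")


def read_deformation_field(path_npy) -> DeformationField:
    path_npy = Path(path_npy)
    coeffs = np.load(path_npy)
    meta = json.loads(path_npy.with_suffix(".json").read_text(encoding="utf-8"))
    return DeformationField(image_shape=tuple(meta["image_shape"]),
                            grid_spacing_px=meta["grid_spacing_px"],
                            coeffs=coeffs)
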