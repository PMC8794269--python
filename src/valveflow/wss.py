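"""Wall shear rate / wall shear stress estimation at the atrioventricular canal.

Two estimation regimes are implemented, mirroring the two blood-rheology
treatments:

* **two-phase** (wild type, red blood cells present): tracked cells passing
  close to the wall are treated as point samples of fluid velocity; assuming
  a linear velocity profile between the cell and the wall, the shear rate is
  ``|v_t| / d`` with ``v_t`` the wall-tangential velocity component and ``d``
  the cell-to-wall distance.  This is the first-order Taylor limit of the
  parabolic profile at the wall, so for cells within a small fraction of the
  lumen radius it approaches the true wall shear rate from below.

* **one-phase** (*gata1* mutants, plasma only): flow rate is obtained from
  the rate of change of ventricular volume, Q = -dV/dt, and the wall shear
  rate follows from a parabolic (Poiseuille) profile across the maximum
  inscribed circle of the canal cross-section,
  ``gamma_dot = 4 Q / (pi r^3)`` — a conservative (maximal) estimate.

Shear stress is always ``tau = mu * gamma_dot``.

Units: positions in μm, time in s, volume/flow in nl and nl/s, viscosity in
mPa·s, shear rate in 1/s, shear stress in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "WallGeometry",
    "ParticleTracks",
    "VolumeTrace",
    "ShearTrace",
    "TraceComparison",
    "poiseuille_wall_shear_rate",
    "near_wall_shear",
    "flow_rate_from_volume",
    "max_inscribed_circle",
    "parabolic_wall_shear",
    "postprocess_trace",
    "compare_traces",
    "volume_from_slices",
]

# unit bridges
_MPAS_TO_PAS = 1e-3          # mPa·s -> Pa·s
_NL_UM_SHEAR = 1e6           # 4 Q[nl/s] / (pi r[um]^3) -> s^-1 multiplier


def poiseuille_wall_shear_rate(q, r):
    """Wall shear rate 4Q/(pi r^3) of a parabolic profile, in coherent units
    (caller supplies Q and r in a consistent unit system)."""
    return 4.0 * np.asarray(q) / (math.pi * np.asarray(r) ** 3)


@dataclass
class WallGeometry:
    """Per-frame wall contours, optionally with lumen cross-section polygons.

    ``contours[i]`` is the list of wall polylines (each an (N, 2) float array
    of μm coordinates) at time ``times[i]``.  ``cross_sections[i]``, when
    present, is a simple closed polygon of the canal lumen.
    """

    times: np.ndarray
    contours: list[list[np.ndarray]]
    cross_sections: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.contours) != len(self.times):
            raise ValueError("one contour set per time point required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        norm = []
        for frame in self.contours:
            if isinstance(frame, np.ndarray):
                frame = [frame]
            frame = [np.asarray(p, dtype=float) for p in frame]
            for p in frame:
                if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 2:
                    raise ValueError("polylines need >= 2 vertices of (x, y)")
            norm.append(frame)
        self.contours = norm
        if self.cross_sections is not None:
            for poly in self.cross_sections:
                sp = Polygon(np.asarray(poly, dtype=float))
                if not sp.is_valid or sp.area <= 0:
                    raise ValueError("cross-section polygons must be simple "
                                     "with positive area")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class ParticleTracks:
    """Tracer observations: a table with columns ``frame``, ``particle_id``,
    ``x_um``, ``y_um`` (optionally ``vx_um_s``/``vy_um_s`` precomputed) plus
    the frame interval in seconds."""

    data: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        required = {"frame", "particle_id", "x_um", "y_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"tracks table missing columns {sorted(missing)}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def velocities(self) -> pd.DataFrame:
        """Forward-difference velocities for consecutive-frame observations of
        the same particle, assigned to the earlier frame.  Non-consecutive
        observations yield no velocity sample."""
        if {"vx_um_s", "vy_um_s"} <= set(self.data.columns):
            out = self.data.dropna(subset=["vx_um_s", "vy_um_s"]).copy()
            return out[["frame", "particle_id", "x_um", "y_um",
                        "vx_um_s", "vy_um_s"]]
        df = self.data.sort_values(["particle_id", "frame"])
        g = df.groupby("particle_id", sort=False)
        dframe = g["frame"].diff().shift(-1)
        vx = g["x_um"].diff().shift(-1) / (dframe * self.frame_interval)
        vy = g["y_um"].diff().shift(-1) / (dframe * self.frame_interval)
        out = df.assign(vx_um_s=vx, vy_um_s=vy)
        out = out[dframe == 1]
        if not np.all(np.isfinite(out[["vx_um_s", "vy_um_s"]].to_numpy())):
            raise ValueError("non-finite velocity encountered")
        return out[["frame", "particle_id", "x_um", "y_um",
                    "vx_um_s", "vy_um_s"]]

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].max()) + 1


@dataclass
class VolumeTrace:
    """Ventricular volume over time (s, nl)."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class ShearTrace:
    """Per-frame shear rate (1/s) and shear stress (Pa) with provenance.

    Missing frames (e.g. no near-wall particle) carry NaN, never zero.
    ``tau = mu * gamma_dot`` holds at every sample by construction.
    Aggregates are computed on the smoothed series when one is present.
    """

    times: np.ndarray
    shear_rate: np.ndarray
    viscosity: float                      # mPa·s
    method: str                           # "two_phase" | "one_phase" | ...
    shear_rate_mean: np.ndarray | None = None   # secondary per-frame statistic
    smoothed_rate: np.ndarray | None = None
    shear_stress: np.ndarray = field(init=False)
    smoothed_stress: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.shear_rate = np.asarray(self.shear_rate, dtype=float)
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        self.shear_stress = self.viscosity * _MPAS_TO_PAS * self.shear_rate
        if self.smoothed_rate is not None:
            self.smoothed_rate = np.asarray(self.smoothed_rate, dtype=float)
            self.smoothed_stress = (self.viscosity * _MPAS_TO_PAS
                                    * self.smoothed_rate)

    def _active_rate(self) -> np.ndarray:
        return self.smoothed_rate if self.smoothed_rate is not None \
            else self.shear_rate

    @property
    def max_rate(self) -> float:
        return float(np.nanmax(self._active_rate()))

    @property
    def p95_rate(self) -> float:
        return float(np.nanpercentile(self._active_rate(), 95))

    @property
    def max_stress(self) -> float:
        return self.viscosity * _MPAS_TO_PAS * self.max_rate

    @property
    def p95_stress(self) -> float:
        return self.viscosity * _MPAS_TO_PAS * self.p95_rate


def _tangent_at(line: LineString, s: float) -> np.ndarray:
    h = max(1e-6, 1e-4 * line.length)
    a = line.interpolate(max(0.0, s - h))
    b = line.interpolate(min(line.length, s + h))
    t = np.array([b.x - a.x, b.y - a.y])
    n = np.linalg.norm(t)
    if n == 0:
        raise ValueError("degenerate wall polyline (zero tangent)")
    return t / n


def near_wall_shear(
    tracks: ParticleTracks,
    wall: WallGeometry,
    viscosity: float,
    near_wall_cutoff: float,
    projection: str = "tangential",
    wall_relative: bool = True,
) -> ShearTrace:
    """Two-phase shear estimate from near-wall tracked particles.

    For every velocity sample within ``near_wall_cutoff`` μm of the wall,
    the shear rate is the wall-tangential speed divided by the distance to
    the nearest wall point (linear-profile assumption).  The per-frame value
    is the maximum over qualifying particles; the per-frame mean is emitted
    alongside.  With ``wall_relative=True`` (default) the particle velocity
    is taken relative to the local wall velocity, so wall motion during the
    cycle is not mistaken for flow.

    Raises if no particle ever qualifies, or a particle sits exactly on the
    wall (d = 0).
    """
    if near_wall_cutoff <= 0:
        raise ValueError("near_wall_cutoff must be positive")
    if projection not in ("tangential", "magnitude"):
        raise ValueError("projection must be 'tangential' or 'magnitude'")
    vel = tracks.velocities()
    n_frames = wall.n_frames
    lines = [[LineString(p) for p in frame] for frame in wall.contours]

    rate_max = np.full(n_frames, np.nan)
    rate_mean = np.full(n_frames, np.nan)
    for f, grp in vel.groupby("frame"):
        f = int(f)
        if f < 0 or f >= n_frames:
            raise ValueError(f"track frame {f} outside wall geometry range")
        rates = []
        for row in grp.itertuples(index=False):
            pt = Point(row.x_um, row.y_um)
            dists = [ln.distance(pt) for ln in lines[f]]
            k = int(np.argmin(dists))
            d = dists[k]
            if d == 0:
                raise ValueError("particle located exactly on the wall")
            if d > near_wall_cutoff:
                continue
            line = lines[f][k]
            s = line.project(pt)
            v = np.array([row.vx_um_s, row.vy_um_s])
            if wall_relative and f + 1 < n_frames and k < len(lines[f + 1]):
                nxt = lines[f + 1][k]
                frac = s / line.length if line.length > 0 else 0.0
                a = line.interpolate(s)
                b = nxt.interpolate(frac * nxt.length)
                v = v - np.array([b.x - a.x, b.y - a.y]) / tracks.frame_interval
            if projection == "tangential":
                vt = abs(float(np.dot(v, _tangent_at(line, s))))
            else:
                vt = float(np.linalg.norm(v))
            rates.append(vt / d)
        if rates:
            rate_max[f] = max(rates)
            rate_mean[f] = float(np.mean(rates))
    if np.all(np.isnan(rate_max)):
        raise ValueError("no particle ever passed within the near-wall cutoff")
    return ShearTrace(wall.times, rate_max, viscosity, "two_phase",
                      shear_rate_mean=rate_mean)


def flow_rate_from_volume(trace: VolumeTrace) -> tuple[np.ndarray, np.ndarray]:
    """Flow rate Q(t) = -dV/dt (nl/s) by second-order central differences
    (one-sided second-order stencils at the ends).  Positive Q is outflow
    from the ventricle."""
    if trace.times.size < 3:
        raise ValueError("need at least 3 volume samples")
    q = -np.gradient(trace.volumes, trace.times, edge_order=2)
    return trace.times.copy(), q


def _signed_distance(poly: Polygon, xy: np.ndarray) -> np.ndarray:
    pts = shapely.points(xy[:, 0], xy[:, 1])
    d = shapely.distance(pts, poly.boundary)
    inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    return np.where(inside, d, -d)


def max_inscribed_circle(
    polygon, resolution: float
) -> tuple[tuple[float, float], float]:
    """Centre and radius of the maximum inscribed circle of a simple polygon.

    Grid search at the stated resolution over the polygon interior followed
    by Nelder–Mead refinement of the distance-to-boundary objective; the
    returned radius is within ``resolution / 2`` of the true inradius (and
    usually far closer after refinement).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    poly = polygon if isinstance(polygon, Polygon) \
        else Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("degenerate (zero-area) polygon")
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    if xs.size == 0 or ys.size == 0:
        xs, ys = np.array([(minx + maxx) / 2]), np.array([(miny + maxy) / 2])
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    sd = _signed_distance(poly, grid)
    best = grid[int(np.argmax(sd))]

    res = minimize(
        lambda p: -_signed_distance(poly, p.reshape(1, 2))[0],
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500},
    )
    center = (float(res.x[0]), float(res.x[1]))
    radius = float(-res.fun)
    if radius <= 0:
        raise ValueError("failed to locate an interior point")
    return center, radius


def parabolic_wall_shear(
    times: np.ndarray,
    flow: np.ndarray,
    radius,
    viscosity: float,
) -> ShearTrace:
    """One-phase shear estimate: parabolic profile across the maximum
    inscribed circle, ``gamma_dot(t) = 4 |Q(t)| / (pi r(t)^3)``.

    ``flow`` in nl/s, ``radius`` (scalar or per-frame) in μm, ``viscosity``
    in mPa·s; output in 1/s and Pa.
    """
    times = np.asarray(times, dtype=float)
    flow = np.asarray(flow, dtype=float)
    r = np.broadcast_to(np.asarray(radius, dtype=float), flow.shape)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    rate = poiseuille_wall_shear_rate(np.abs(flow), r) * _NL_UM_SHEAR
    return ShearTrace(times, rate, viscosity, "one_phase")


def _circular_nanmean(x: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth == 0:
        return x.copy()
    w = 2 * halfwidth + 1
    xp = np.concatenate([x[-halfwidth:], x, x[:halfwidth]])
    vals = np.where(np.isnan(xp), 0.0, xp)
    cnt = (~np.isnan(xp)).astype(float)
    kern = np.ones(w)
    num = np.convolve(vals, kern, mode="valid")
    den = np.convolve(cnt, kern, mode="valid")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def postprocess_trace(
    trace: ShearTrace,
    align_at: float | None = None,
    envelope_halfwidth: int = 2,
    event_time: float | None = None,
) -> ShearTrace:
    """Align and smooth a periodic shear trace.

    If both ``align_at`` and ``event_time`` are given, the trace is shifted
    circularly so the sample nearest ``event_time`` (e.g. the widest-lumen
    frame) lands at ``align_at``.  Smoothing is a centred moving mean over
    ``2 * envelope_halfwidth + 1`` frames with periodic boundary; aggregates
    of the returned trace are taken over the smoothed series.
    """
    if envelope_halfwidth < 0:
        raise ValueError("envelope_halfwidth must be >= 0")
    rate = trace.shear_rate.copy()
    mean = None if trace.shear_rate_mean is None else trace.shear_rate_mean.copy()
    if align_at is not None and event_time is not None:
        dt = float(np.median(np.diff(trace.times)))
        shift = int(round((align_at - event_time) / dt))
        rate = np.roll(rate, shift)
        if mean is not None:
            mean = np.roll(mean, shift)
    smoothed = _circular_nanmean(rate, envelope_halfwidth)
    return ShearTrace(trace.times.copy(), rate, trace.viscosity, trace.method,
                      shear_rate_mean=mean, smoothed_rate=smoothed)


@dataclass(frozen=True)
class TraceComparison:
    """Fold-change summary between two shear traces on a common cycle base."""

    max_stress_ratio: float
    p95_stress_ratio: float
    max_rate_ratio: float
    pointwise_stress_ratio: np.ndarray


def compare_traces(a: ShearTrace, b: ShearTrace) -> TraceComparison:
    """Ratios a/b of trace maxima, 95th percentiles, and pointwise stress.

    Zero or missing denominators yield NaN in the pointwise series; aggregate
    ratios are NaN when the denominator aggregate is zero.
    """
    def _ratio(x: float, y: float) -> float:
        return float(x / y) if y not in (0.0,) and np.isfinite(y) else float("nan")

    sa = a.smoothed_stress if a.smoothed_stress is not None else a.shear_stress
    sb = b.smoothed_stress if b.smoothed_stress is not None else b.shear_stress
    n = min(sa.size, sb.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        pw = sa[:n] / sb[:n]
    pw = np.where(np.isfinite(pw), pw, np.nan)
    return TraceComparison(
        max_stress_ratio=_ratio(a.max_stress, b.max_stress),
        p95_stress_ratio=_ratio(a.p95_stress, b.p95_stress),
        max_rate_ratio=_ratio(a.max_rate, b.max_rate),
        pointwise_stress_ratio=pw,
    )


def volume_from_slices(slice_polygons: Sequence[np.ndarray],
                       slice_spacing_um: float) -> float:
    """Ventricular volume (nl) from a z-stack of lumen polygons by disk
    summation: sum of polygon areas (μm²) times slice spacing (μm)."""
    if slice_spacing_um <= 0:
        raise ValueError("slice_spacing_um must be positive")
    total_um3 = sum(Polygon(np.asarray(p, dtype=float)).area
                    for p in slice_polygons) * slice_spacing_um
    return total_um3 * 1e-6  # μm³ -> nl (1 nl = 1e6 μm³)
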