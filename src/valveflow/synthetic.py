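"""Ground-truth synthetic fixtures for every analysis stage.

Each generator is a pure function of its parameters and a single integer
seed: identical inputs give bit-identical outputs.  The generators emulate
the statistical structure the estimators assume — a pulsatile tube with
parabolic luminal flow advecting finite-size tracers, a periodic ventricular
volume trace, spot images of Gaussian dots over a uniform background, and
two-channel membrane images with controllable apical/basal and interface
contrasts — without attempting photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .wss import ParticleTracks, VolumeTrace, WallGeometry, poiseuille_wall_shear_rate

__all__ = [
    "TubeFlowScenario",
    "TubeMovie",
    "SpotImageSpec",
    "SpotImage",
    "CellRowSpec",
    "PolarityImage",
    "generate_tube_movie",
    "generate_volume_trace",
    "generate_spot_image",
    "generate_polarity_image",
]

_V_UM_S = 1e6  # 2 Q[nl/s] / (pi R[um]^2) -> μm/s multiplier


# ---------------------------------------------------------------------------
# pulsatile tube with tracers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeFlowScenario:
    """A contracting 2D tube with parabolic luminal flow and advected tracers.

    The luminal radius is ``radius_fn(t)`` (μm; a constant float is accepted),
    the centreline a straight segment between two μm points, and the flow
    ``Q(t) = peak_flow * cos(2 pi t / period)`` nl/s unless ``flow_fn``
    overrides it.  Tracers are advected with the fluid velocity at their
    centre,

        v(r, t) = 2 Q(t) / (pi R(t)^2) * (1 - r^2 / R(t)^2),

    and the analytic wall shear rate ``4 Q / (pi R^3)`` is part of the
    emitted ground truth.
    """

    radius_fn: Callable[[float], float] | float = 25.0
    centerline: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 0.0), (400.0, 0.0))
    peak_flow: float = 1.0            # nl/s
    period: float = 0.5               # s
    frame_interval: float = 0.005     # s
    n_frames: int = 100
    viscosity: float = 1.5            # mPa·s
    tracer_count: int = 100
    tracer_radius: float = 2.0        # μm
    noise_sd: float = 2.0             # intensity units
    seed: int = 0
    um_per_px: float = 1.0
    background: float = 10.0
    tracer_amplitude: float = 120.0
    wall_amplitude: float = 40.0
    flow_fn: Callable[[float], float] | None = None

    def radius(self, t: float) -> float:
        r = self.radius_fn(t) if callable(self.radius_fn) else float(self.radius_fn)
        if r <= 0:
            raise ValueError(f"radius_fn({t}) = {r} must be positive")
        return r

    def flow(self, t: float) -> float:
        if self.flow_fn is not None:
            return float(self.flow_fn(t))
        return self.peak_flow * math.cos(2.0 * math.pi * t / self.period)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class TubeMovie:
    """Output bundle of :func:`generate_tube_movie`."""

    stack: np.ndarray                 # (n_frames, H, W) float32
    wall: WallGeometry
    tracks: ParticleTracks            # ground-truth positions (and velocities)
    volume_trace: VolumeTrace
    ground_truth: dict                # times, flow, radius, wall_shear_rate, ...
    um_per_px: float
    image_origin_um: np.ndarray | None = None  # world μm of pixel (0, 0)


def _axial_velocity(q: float, big_r: float, r_off: np.ndarray) -> np.ndarray:
    return (2.0 * q / (math.pi * big_r ** 2) * _V_UM_S
            * (1.0 - (r_off / big_r) ** 2))


def generate_tube_movie(scenario: TubeFlowScenario, n_substeps: int = 8,
                        render: bool = True) -> TubeMovie:
    """Simulate the tube scenario and render a tracer movie.

    Tracers are seeded uniformly in axial position and radial offset (staying
    ``tracer_radius`` clear of the wall at its tightest) and advected by the
    parabolic profile with ``n_substeps`` midpoint sub-steps per frame.  The
    tracer count is conserved: a tracer leaving one axial end re-enters at
    the other (its track id changes at the wrap, since a real tracker would
    lose the identity).  Frames are the uniform background plus Gaussian
    blobs for tracers, a bright ridge for each wall, and additive Gaussian
    noise.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    times = np.arange(sc.n_frames) * sc.frame_interval
    radii = np.array([sc.radius(t) for t in times])
    flows = np.array([sc.flow(t) for t in times])
    r_min = radii.min()
    if sc.tracer_radius >= r_min:
        raise ValueError(
            f"tracer_radius {sc.tracer_radius} μm does not fit the minimum "
            f"lumen radius {r_min} μm")

    p0 = np.asarray(sc.centerline[0], dtype=float)
    p1 = np.asarray(sc.centerline[1], dtype=float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("degenerate centerline")
    u_hat = axis / length
    n_hat = np.array([-u_hat[1], u_hat[0]])

    # seed tracers: axial position s in [0, L), signed radial offset
    s = rng.uniform(0.0, length, sc.tracer_count)
    r_off = rng.uniform(-(r_min - sc.tracer_radius),
                        r_min - sc.tracer_radius, sc.tracer_count)

    next_id = sc.tracer_count
    ids = np.arange(sc.tracer_count)
    rows = []
    true_v = np.zeros((sc.n_frames, sc.tracer_count))
    pos_s = np.zeros((sc.n_frames, sc.tracer_count))
    for f in range(sc.n_frames):
        t = times[f]
        pos_s[f] = s
        true_v[f] = _axial_velocity(flows[f], radii[f], r_off)
        for i in range(sc.tracer_count):
            xy = p0 + s[i] * u_hat + r_off[i] * n_hat
            rows.append((f, int(ids[i]), xy[0], xy[1]))
        if f < sc.n_frames - 1:
            dt = sc.frame_interval / n_substeps
            for k in range(n_substeps):
                tm = t + (k + 0.5) * dt
                v = _axial_velocity(sc.flow(tm), sc.radius(tm), r_off)
                s = s + v * dt
            wrapped = (s < 0) | (s >= length)
            if np.any(wrapped):
                s = np.mod(s, length)
                nw = int(wrapped.sum())
                ids = ids.copy()
                ids[wrapped] = np.arange(next_id, next_id + nw)
                next_id += nw

    tracks = ParticleTracks(
        pd.DataFrame(rows, columns=["frame", "particle_id", "x_um", "y_um"]),
        frame_interval=sc.frame_interval,
    )

    # wall contours: two polylines offset +/-R(t) from the centreline
    contours = []
    cross_sections = []
    n_axial = max(2, int(length))
    ax_samples = np.linspace(0.0, length, n_axial)
    theta = np.linspace(0.0, 2.0 * math.pi, 129)[:-1]
    mid = p0 + 0.5 * length * u_hat
    for f in range(sc.n_frames):
        big_r = radii[f]
        top = p0[None, :] + ax_samples[:, None] * u_hat + big_r * n_hat
        bot = p0[None, :] + ax_samples[:, None] * u_hat - big_r * n_hat
        contours.append([top, bot])
        circ = mid[None, :] + big_r * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        cross_sections.append(circ)
    wall = WallGeometry(times=times, contours=contours,
                        cross_sections=cross_sections)

    # volume trace consistent with -dV/dt = Q(t), integrated numerically on a
    # fine grid (analytic for the default cosine flow, but flow_fn is free)
    fine = np.linspace(0.0, times[-1], max(2, 50 * sc.n_frames))
    qf = np.array([sc.flow(t) for t in fine])
    cum = np.concatenate([[0.0], np.cumsum((qf[1:] + qf[:-1]) / 2.0
                                           * np.diff(fine))])
    v_rel = -np.interp(times, fine, cum)
    v0 = 1.0 - v_rel.min() + 2.0 * abs(sc.peak_flow) * sc.period / (2 * math.pi)
    volume_trace = VolumeTrace(times=times, volumes=v0 + v_rel)

    wall_shear = poiseuille_wall_shear_rate(np.abs(flows), radii) * 1e6

    stack = None
    origin = None
    if render:
        stack, origin = _render_tube(sc, times, radii, pos_s, r_off, p0,
                                     u_hat, n_hat, length, rng)

    gt = {
        "times": times,
        "flow_nl_s": flows,
        "radius_um": radii,
        "wall_shear_rate_s": wall_shear,
        "wall_shear_stress_pa": sc.viscosity * 1e-3 * wall_shear,
        "tracer_axial_um": pos_s,
        "tracer_radial_um": r_off,
        "tracer_velocity_um_s": true_v,
        "seed": sc.seed,
        "image_origin_um": origin,
    }
    return TubeMovie(stack=stack, wall=wall, tracks=tracks,
                     volume_trace=volume_trace, ground_truth=gt,
                     um_per_px=sc.um_per_px, image_origin_um=origin)


def _splat_gaussians(img: np.ndarray, centers_px: np.ndarray,
                     amplitude: float, sigma_px: float) -> None:
    """Add 2D Gaussian blobs in place (patch radius 4 sigma)."""
    h, w = img.shape
    rad = max(2, int(math.ceil(4.0 * sigma_px)))
    for cx, cy in centers_px:
        x0, x1 = int(math.floor(cx)) - rad, int(math.floor(cx)) + rad + 1
        y0, y1 = int(math.floor(cy)) - rad, int(math.floor(cy)) + rad + 1
        xs0, xs1 = max(0, x0), min(w, x1)
        ys0, ys1 = max(0, y0), min(h, y1)
        if xs0 >= xs1 or ys0 >= ys1:
            continue
        yy, xx = np.mgrid[ys0:ys1, xs0:xs1]
        img[ys0:ys1, xs0:xs1] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px ** 2))


def _render_tube(sc, times, radii, pos_s, r_off, p0, u_hat, n_hat,
                 length, rng) -> np.ndarray:
    r_max = radii.max()
    margin = 3.0 * sc.tracer_radius + 5.0
    corners = []
    for ss in (0.0, length):
        for rr in (-(r_max + margin), r_max + margin):
            corners.append(p0 + ss * u_hat + rr * n_hat)
    corners = np.array(corners)
    lo = corners.min(axis=0) - margin
    hi = corners.max(axis=0) + margin
    w = int(math.ceil((hi[0] - lo[0]) / sc.um_per_px))
    h = int(math.ceil((hi[1] - lo[1]) / sc.um_per_px))
    sigma_px = sc.tracer_radius / sc.um_per_px
    stack = np.empty((sc.n_frames, h, w), dtype=np.float32)
    for f in range(sc.n_frames):
        img = np.full((h, w), sc.background, dtype=float)
        centers = (p0[None, :] + pos_s[f][:, None] * u_hat
                   + r_off[:, None] * n_hat)
        centers_px = (centers - lo[None, :]) / sc.um_per_px
        _splat_gaussians(img, centers_px, sc.tracer_amplitude, sigma_px)
        ridge = np.zeros((h, w))
        for sign in (+1.0, -1.0):
            a = (p0 + sign * radii[f] * n_hat - lo) / sc.um_per_px
            b = (p0 + length * u_hat + sign * radii[f] * n_hat
                 - lo) / sc.um_per_px
            _draw_segment(ridge, a, b, sc.wall_amplitude, 1.0)
        img += ridge
        if sc.noise_sd > 0:
            img = img + rng.normal(0.0, sc.noise_sd, img.shape)
        stack[f] = img.astype(np.float32)
    return stack, lo


# ---------------------------------------------------------------------------
# ventricular volume trace
# ---------------------------------------------------------------------------

def generate_volume_trace(
    v0: float, amplitude: float, period: float, dt: float, n: int,
    phase: float = 0.0,
) -> tuple[VolumeTrace, np.ndarray]:
    """Periodic ventricular volume ``V(t) = V0 + A sin(2 pi t / period +
    phase)`` sampled every ``dt`` seconds, together with the closed-form
    ground-truth flow ``Q(t) = -dV/dt = -A w cos(w t + phase)`` (nl/s)."""
    if abs(amplitude) >= v0:
        raise ValueError("amplitude must be smaller than V0 (volumes > 0)")
    if dt <= 0 or period <= 0 or n < 2:
        raise ValueError("dt, period must be positive and n >= 2")
    t = np.arange(n) * dt
    w = 2.0 * math.pi / period
    v = v0 + amplitude * np.sin(w * t + phase)
    q_true = -amplitude * w * np.cos(w * t + phase)
    return VolumeTrace(times=t, volumes=v), q_true


# ---------------------------------------------------------------------------
# spot (smFISH-style) images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotImageSpec:
    """Gaussian dots over a uniform background, organised by labeled ROI.

    ``roi_polygons`` maps region label -> (N, 2) polygon in pixel
    coordinates; ``dot_count_per_roi`` maps label -> planted dot count.
    Dots are kept ``3 * dot_sigma`` clear of the ROI boundary (fully inside)
    and ``min_separation`` (default ``4 * dot_sigma``) apart so that they are
    isolated, as the calibration procedure requires.  ``roi_offsets`` adds a
    constant inside an ROI (a negative value makes it dimmer than the
    background).
    """

    image_shape: tuple[int, int] = (240, 360)
    background_level: float = 50.0
    dot_count_per_roi: Mapping[str, int] = field(default_factory=dict)
    dot_amplitude: float = 80.0
    dot_sigma: float = 2.0
    roi_polygons: Mapping[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 8.0
    seed: int = 0
    min_separation: float | None = None
    roi_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        for label in self.dot_count_per_roi:
            if label not in self.roi_polygons:
                raise ValueError(f"dot counts given for unknown ROI {label!r}")


@dataclass
class SpotImage:
    """Output of :func:`generate_spot_image`: the image, its labeled ROIs and
    a ledger of every planted dot (centre, analytic integrated intensity
    above background ``amplitude * 2 pi sigma^2``, and effective area
    ``pi (3 sigma)^2``)."""

    image: np.ndarray
    roi_polygons: dict[str, np.ndarray]
    ledger: pd.DataFrame

    def dots_in(self, label: str) -> pd.DataFrame:
        return self.ledger[self.ledger["roi"] == label]


def _sample_points_in_polygon(poly: Polygon, n: int, margin: float,
                              min_sep: float, rng: np.random.Generator,
                              max_tries: int = 20000) -> np.ndarray:
    inner = poly.buffer(-margin)
    if inner.is_empty:
        raise ValueError("ROI too small for the requested dot margin")
    minx, miny, maxx, maxy = inner.bounds
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} isolated dots after {max_tries} tries; "
                "enlarge the ROI or reduce min_separation")
        cand = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if not shapely.contains_xy(inner, cand[0], cand[1]):
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_sep:
            continue
        pts.append(cand)
    return np.array(pts) if pts else np.empty((0, 2))


def generate_spot_image(spec: SpotImageSpec) -> SpotImage:
    """Render the spot image described by ``spec``.

    Identical spec (including seed) gives identical dot coordinates and
    pixels.  Placement failures (too many dots for the ROI at the isolation
    distance) raise rather than silently overlapping dots.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    img = np.full((h, w), float(spec.background_level))
    min_sep = spec.min_separation if spec.min_separation is not None \
        else 4.0 * spec.dot_sigma
    margin = 3.0 * spec.dot_sigma
    records = []
    polys = {k: np.asarray(v, dtype=float) for k, v in spec.roi_polygons.items()}

    for label, poly_xy in polys.items():
        offset = spec.roi_offsets.get(label, 0.0)
        if offset:
            yy, xx = np.mgrid[0:h, 0:w]
            inside = shapely.contains_xy(
                Polygon(poly_xy), xx.ravel() + 1e-9, yy.ravel() + 1e-9)
            img.ravel()[inside] += offset
        count = spec.dot_count_per_roi.get(label, 0)
        if count == 0:
            continue
        centers = _sample_points_in_polygon(
            Polygon(poly_xy), count, margin, min_sep, rng)
        _splat_gaussians(img, centers, spec.dot_amplitude, spec.dot_sigma)
        for cx, cy in centers:
            records.append({
                "roi": label,
                "x_px": cx,
                "y_px": cy,
                "integrated_intensity": spec.dot_amplitude
                * 2.0 * math.pi * spec.dot_sigma ** 2,
                "area_px2": math.pi * (3.0 * spec.dot_sigma) ** 2,
            })
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    ledger = pd.DataFrame(
        records, columns=["roi", "x_px", "y_px",
                          "integrated_intensity", "area_px2"])
    return SpotImage(image=img, roi_polygons=polys, ledger=ledger)


# ---------------------------------------------------------------------------
# two-channel polarity images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRowSpec:
    """Layout of a single row of rectangular cells for polarity fixtures.

    The apical membrane is the top edge of each cell, the basal membrane the
    bottom edge, and lateral membranes (cell–cell interfaces) the shared
    vertical edges, which alternate between two labels so that interface
    contrast fixtures can be built."""

    n_cells: int = 6
    cell_width: float = 30.0      # px
    cell_height: float = 24.0     # px
    origin: tuple[float, float] = (20.0, 20.0)
    membrane_sigma: float = 1.5   # px, Gaussian cross-profile of membranes
    interface_labels: tuple[str, str] = ("luminal", "abluminal")


@dataclass
class PolarityImage:
    """Two-channel image (2, H, W; channel 0 = green, 1 = red) with membrane
    segment annotations (lists of (2, 2) polylines in px)."""

    image: np.ndarray
    apical_segments: list[np.ndarray]
    basal_segments: list[np.ndarray]
    lateral_segments: dict[str, list[np.ndarray]]


def _draw_segment(img: np.ndarray, a: np.ndarray, b: np.ndarray,
                  intensity: float, sigma: float) -> None:
    """Max-composite a line segment with Gaussian cross-profile: the
    centreline intensity equals ``intensity`` exactly and crossing membranes
    do not double up."""
    h, w = img.shape
    pad = int(math.ceil(4 * sigma)) + 1
    x0 = max(0, int(min(a[0], b[0])) - pad)
    x1 = min(w, int(max(a[0], b[0])) + pad + 1)
    y0 = max(0, int(min(a[1], b[1])) - pad)
    y1 = min(h, int(max(a[1], b[1])) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ab = b - a
    ll = float(ab @ ab)
    if ll == 0:
        d2 = (xx - a[0]) ** 2 + (yy - a[1]) ** 2
    else:
        t = np.clip(((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / ll, 0.0, 1.0)
        d2 = (xx - (a[0] + t * ab[0])) ** 2 + (yy - (a[1] + t * ab[1])) ** 2
    prof = intensity * np.exp(-d2 / (2.0 * sigma ** 2))
    np.maximum(img[y0:y1, x0:x1], prof, out=img[y0:y1, x0:x1])


def generate_polarity_image(
    apical_green: float,
    basal_green: float,
    apical_red: float,
    basal_red: float,
    geometry: CellRowSpec = CellRowSpec(),
    lateral_green: Mapping[str, float] | None = None,
    lateral_red: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PolarityImage:
    """Render a row of cells with stated membrane intensities per channel.

    With all four intensities equal the downstream apical/basal
    ratio-of-ratios is exactly 1; doubling ``apical_green`` forces a
    noise-free ratio of 2.  Lateral (cell–cell interface) intensities
    default to the mean of apical and basal for each channel and can be set
    per interface label.  Annotated segments are shrunk by ``2 sigma`` at
    each end so that samples along them do not touch membrane junctions.
    """
    for v in (apical_green, basal_green, apical_red, basal_red):
        if v < 0:
            raise ValueError("intensities must be >= 0")
    g = geometry
    ox, oy = g.origin
    h = int(oy + g.cell_height + oy)
    w = int(ox + g.n_cells * g.cell_width + ox)
    rng = np.random.default_rng(seed)
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    lat_g = dict(lateral_green or {})
    lat_r = dict(lateral_red or {})
    for lbl in g.interface_labels:
        lat_g.setdefault(lbl, 0.5 * (apical_green + basal_green))
        lat_r.setdefault(lbl, 0.5 * (apical_red + basal_red))

    shrink = 2.0 * g.membrane_sigma
    apical, basal = [], []
    lateral: dict[str, list[np.ndarray]] = {lbl: [] for lbl in g.interface_labels}
    for i in range(g.n_cells):
        x0 = ox + i * g.cell_width
        x1 = x0 + g.cell_width
        top_a, top_b = np.array([x0, oy]), np.array([x1, oy])
        bot_a = np.array([x0, oy + g.cell_height])
        bot_b = np.array([x1, oy + g.cell_height])
        _draw_segment(green, top_a, top_b, apical_green, g.membrane_sigma)
        _draw_segment(red, top_a, top_b, apical_red, g.membrane_sigma)
        _draw_segment(green, bot_a, bot_b, basal_green, g.membrane_sigma)
        _draw_segment(red, bot_a, bot_b, basal_red, g.membrane_sigma)
        apical.append(np.array([[x0 + shrink, oy], [x1 - shrink, oy]]))
        basal.append(np.array([[x0 + shrink, oy + g.cell_height],
                               [x1 - shrink, oy + g.cell_height]]))
        if i > 0:
            lbl = g.interface_labels[i % len(g.interface_labels)]
            la = np.array([x0, oy])
            lb = np.array([x0, oy + g.cell_height])
            _draw_segment(green, la, lb, lat_g[lbl], g.membrane_sigma)
            _draw_segment(red, la, lb, lat_r[lbl], g.membrane_sigma)
            lateral[lbl].append(np.array([[x0, oy + shrink],
                                          [x0, oy + g.cell_height - shrink]]))
    img = np.stack([green, red])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return PolarityImage(image=img, apical_segments=apical,
                         basal_segments=basal, lateral_segments=lateral)
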