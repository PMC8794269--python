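"""Tracer segmentation and motion estimation by free-form registration.

Frame-to-frame motion is modelled as a free-form deformation: displacement
vectors live on a regular control grid (default spacing 5.6 μm) and are
interpolated to every pixel with cubic B-splines (the control values are the
B-spline coefficients, so the zero field is exactly the identity warp).
Pairwise registration minimises the mean squared intensity difference
between the fixed frame and the warped moving frame with L-BFGS-B and an
analytic gradient, over a 3-level multi-resolution pyramid.  Consecutive
registrations are warm-started with half the previous deformation to smooth
velocity changes.  Bright tracers are segmented by intensity thresholding
and connected components; velocities are the interpolated displacement at
each centroid divided by the frame interval, and identities are linked by
warped-position nearest neighbour within a gating radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .wss import ParticleTracks

__all__ = [
    "DeformationField",
    "RegistrationResult",
    "segment_particles",
    "register_pair",
    "track_movie",
]


def _bspline3(s: np.ndarray) -> np.ndarray:
    a = np.abs(s)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    out[m1] = (4.0 - 6.0 * a[m1] ** 2 + 3.0 * a[m1] ** 3) / 6.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m2] = (2.0 - a[m2]) ** 3 / 6.0
    return out


def _n_controls(size: int, spacing: float) -> int:
    # control k sits at (k - 1) * spacing; cubic support needs one point
    # before the domain and two beyond it
    return int(math.floor((size - 1) / spacing)) + 4


def _axis_weights(coords: np.ndarray, spacing: float, ncp: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """For each coordinate, the 4 control indices and B-spline weights."""
    t = coords / spacing + 1.0
    i0 = np.floor(t).astype(int)
    ks = i0[:, None] + np.arange(-1, 3)[None, :]
    wts = _bspline3(t[:, None] - ks)
    ks = np.clip(ks, 0, ncp - 1)   # clipped indices only ever get zero weight
    return ks, wts


@dataclass
class DeformationField:
    """Cubic B-spline free-form deformation over an image domain.

    ``coeffs`` has shape (ncy, ncx, 2) and holds the (ux, uy) control values
    in full-resolution pixels; the dense displacement at pixel (x, y) is the
    separable cubic B-spline interpolation of the control grid.
    """

    image_shape: tuple[int, int]
    grid_spacing_px: float
    coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid_spacing_px <= 0:
            raise ValueError("grid spacing must be positive")
        h, w = self.image_shape
        ncy = _n_controls(h, self.grid_spacing_px)
        ncx = _n_controls(w, self.grid_spacing_px)
        if self.coeffs is None:
            self.coeffs = np.zeros((ncy, ncx, 2))
        elif self.coeffs.shape != (ncy, ncx, 2):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match grid "
                f"({ncy}, {ncx}, 2) for image {self.image_shape}")

    @classmethod
    def zero(cls, image_shape: tuple[int, int],
             grid_spacing_px: float) -> "DeformationField":
        return cls(image_shape=image_shape, grid_spacing_px=grid_spacing_px)

    def scaled(self, factor: float) -> "DeformationField":
        return DeformationField(self.image_shape, self.grid_spacing_px,
                                self.coeffs * factor)

    def displacement_at(self, points_xy: np.ndarray) -> np.ndarray:
        """Displacement (ux, uy) in px at arbitrary (x, y) pixel positions."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        ncy, ncx, _ = self.coeffs.shape
        kx, wx = _axis_weights(pts[:, 0], self.grid_spacing_px, ncx)
        ky, wy = _axis_weights(pts[:, 1], self.grid_spacing_px, ncy)
        out = np.zeros((pts.shape[0], 2))
        for a in range(4):
            for b in range(4):
                wgt = (wy[:, a] * wx[:, b])[:, None]
                out += wgt * self.coeffs[ky[:, a], kx[:, b], :]
        return out

    def dense(self) -> np.ndarray:
        """Dense (H, W, 2) displacement field at every pixel."""
        h, w = self.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        return self.displacement_at(pts).reshape(h, w, 2)


def _interp_matrix(coords_y: np.ndarray, coords_x: np.ndarray,
                   spacing: float, ncy: int, ncx: int) -> sparse.csr_matrix:
    """Sparse matrix mapping flattened control values (ncy*ncx) to the
    displacement at the grid of full-resolution coordinates (len_y*len_x)."""
    kx, wx = _axis_weights(coords_x, spacing, ncx)
    ky, wy = _axis_weights(coords_y, spacing, ncy)
    ny, nx = coords_y.size, coords_x.size
    rows = np.repeat(np.arange(ny * nx), 16)
    kcol = (ky[:, None, :, None] * ncx + kx[None, :, None, :])
    kcol = np.broadcast_to(kcol, (ny, nx, 4, 4)).ravel()
    data = (wy[:, None, :, None] * wx[None, :, None, :])
    data = np.broadcast_to(data, (ny, nx, 4, 4)).ravel()
    mat = sparse.coo_matrix((data, (rows, kcol)),
                            shape=(ny * nx, ncy * ncx))
    return mat.tocsr()


@dataclass
class RegistrationResult:
    """Outcome of a pairwise registration."""

    field: DeformationField
    converged: bool
    objective_init: float
    objective_final: float
    level_objectives: list[float]


def _downsample(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img.astype(float)
    return gaussian_filter(img.astype(float), sigma=f / 2.0)[::f, ::f]


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    grid_spacing_um: float = 5.6,
    um_per_px: float = 1.0,
    init: DeformationField | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    max_iter: tuple[int, ...] = (40, 40, 60),
    tol: float = 1e-7,
    smooth_weight: float = 0.0,
) -> RegistrationResult:
    """Estimate the free-form displacement u with M(x + u(x)) ≈ F(x).

    The returned field maps material points of the fixed frame to their
    position in the moving frame, so for consecutive movie frames it is the
    forward displacement over one frame interval.  The objective (MSE, plus
    an optional first-difference smoothness penalty on the control grid) at
    the solution never exceeds the objective at the initialization: if the
    pyramid fails to improve on the initial field, the initial field is
    returned with ``converged=False``.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving frames must share a shape")
    spacing_px = grid_spacing_um / um_per_px
    h, w = fixed.shape
    fld = DeformationField.zero((h, w), spacing_px) if init is None \
        else DeformationField((h, w), spacing_px, init.coeffs.copy())
    ncy, ncx, _ = fld.coeffs.shape
    c0 = fld.coeffs.reshape(-1, 2).copy()

    def _penalty_and_grad(c: np.ndarray) -> tuple[float, np.ndarray]:
        if smooth_weight == 0.0:
            return 0.0, np.zeros_like(c)
        cc = c.reshape(ncy, ncx, 2)
        dy = np.diff(cc, axis=0)
        dx = np.diff(cc, axis=1)
        pen = smooth_weight * (np.sum(dy ** 2) + np.sum(dx ** 2))
        g = np.zeros_like(cc)
        g[:-1] -= 2 * smooth_weight * dy
        g[1:] += 2 * smooth_weight * dy
        g[:, :-1] -= 2 * smooth_weight * dx
        g[:, 1:] += 2 * smooth_weight * dx
        return pen, g.reshape(-1, 2)

    def _level_problem(f: int):
        fl = _downsample(fixed, f)
        ml = _downsample(moving, f)
        hl, wl = fl.shape
        wmat = _interp_matrix(np.arange(hl) * f, np.arange(wl) * f,
                              spacing_px, ncy, ncx)
        gy, gx = np.gradient(ml)
        base_y, base_x = np.mgrid[0:hl, 0:wl]
        base_y = base_y.ravel().astype(float)
        base_x = base_x.ravel().astype(float)
        fvec = fl.ravel()
        npix = fvec.size

        def objective(cflat: np.ndarray):
            c = cflat.reshape(-1, 2)
            u = wmat @ c                       # full-res px
            cy = base_y + u[:, 1] / f
            cx = base_x + u[:, 0] / f
            coords = np.vstack([cy, cx])
            warped = map_coordinates(ml, coords, order=1, mode="nearest")
            r = warped - fvec
            e = float(np.mean(r ** 2))
            gmy = map_coordinates(gy, coords, order=1, mode="nearest")
            gmx = map_coordinates(gx, coords, order=1, mode="nearest")
            gc = np.empty_like(c)
            gc[:, 0] = (2.0 / npix) * (wmat.T @ (r * gmx)) / f
            gc[:, 1] = (2.0 / npix) * (wmat.T @ (r * gmy)) / f
            pen, gpen = _penalty_and_grad(c)
            return e + pen, (gc + gpen).ravel()

        return objective

    obj_fine = _level_problem(1)
    e_init, _ = obj_fine(c0.ravel())

    c = c0.copy()
    level_objs: list[float] = []
    converged = True
    for f, it in zip(levels, max_iter):
        objective = obj_fine if f == 1 else _level_problem(f)
        res = minimize(objective, c.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": it, "ftol": tol, "gtol": 1e-9})
        c = res.x.reshape(-1, 2)
        if not res.success and res.status != 1:  # status 1 = maxiter reached
            converged = False
        level_objs.append(obj_fine(c.ravel())[0])

    e_final = level_objs[-1]
    if e_final > e_init:   # guarantee: never worse than the initialization
        c, e_final, converged = c0, e_init, False
    out = DeformationField((h, w), spacing_px, c.reshape(ncy, ncx, 2))
    return RegistrationResult(field=out, converged=converged,
                              objective_init=e_init, objective_final=e_final,
                              level_objectives=level_objs)


def segment_particles(
    image: np.ndarray,
    threshold: float,
    min_area_px: int = 4,
    um_per_px: float = 1.0,
) -> pd.DataFrame:
    """Connected components of ``image > threshold`` as particle detections.

    Components smaller than ``min_area_px`` pixels are discarded (rejects
    single-pixel noise).  Returns a table with centroid ``x_um``/``y_um``,
    ``x_px``/``y_px`` and ``area_px2``; an empty table is a valid result.
    """
    mask = np.asarray(image) > threshold
    lab = cc_label(mask)
    rows = []
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        rows.append({"x_px": cx, "y_px": cy,
                     "x_um": cx * um_per_px, "y_um": cy * um_per_px,
                     "area_px2": float(rp.area)})
    return pd.DataFrame(rows, columns=["x_px", "y_px", "x_um", "y_um",
                                       "area_px2"])


def track_movie(
    stack: np.ndarray,
    threshold: float,
    grid_spacing_um: float = 5.6,
    um_per_px: float = 1.0,
    frame_interval: float = 1.0,
    gating_radius_um: float | None = None,
    min_area_px: int = 4,
    **register_kwargs,
) -> ParticleTracks:
    """Segment and track particles through an image stack.

    Each consecutive pair is registered with a warm start of half the
    previous deformation field; a particle's velocity is the interpolated
    displacement at its centroid divided by the frame interval.  Identities
    are linked by nearest neighbour between warped centroids and the next
    frame's detections within ``gating_radius_um`` (default 2x grid
    spacing); gating failures terminate tracks and spawn new ids.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames >= 2, H, W)")
    n = stack.shape[0]
    gate_px = (2.0 * grid_spacing_um if gating_radius_um is None
               else gating_radius_um) / um_per_px

    detections = [segment_particles(stack[i], threshold, min_area_px,
                                    um_per_px) for i in range(n)]
    next_id = 0
    ids = list(range(len(detections[0])))
    next_id = len(ids)
    prev_field: DeformationField | None = None
    rows = []
    for i in range(n - 1):
        init = prev_field.scaled(0.5) if prev_field is not None else None
        reg = register_pair(stack[i], stack[i + 1],
                            grid_spacing_um=grid_spacing_um,
                            um_per_px=um_per_px, init=init, **register_kwargs)
        prev_field = reg.field
        det = detections[i]
        pts = det[["x_px", "y_px"]].to_numpy() if len(det) else \
            np.empty((0, 2))
        u = reg.field.displacement_at(pts) if len(pts) else np.empty((0, 2))
        vel = u * um_per_px / frame_interval
        for j in range(len(det)):
            rows.append((i, ids[j], det["x_um"].iloc[j], det["y_um"].iloc[j],
                         vel[j, 0], vel[j, 1]))
        # link: warped position vs next detections
        nxt = detections[i + 1]
        new_ids = [-1] * len(nxt)
        if len(nxt) and len(pts):
            warped = pts + u
            tree = cKDTree(nxt[["x_px", "y_px"]].to_numpy())
            dist, idx = tree.query(warped, distance_upper_bound=gate_px)
            used = set()
            order = np.argsort(dist)
            for j in order:
                if not np.isfinite(dist[j]):
                    continue
                k = int(idx[j])
                if k in used:
                    continue
                used.add(k)
                new_ids[k] = ids[j]
        for k in range(len(nxt)):
            if new_ids[k] == -1:
                new_ids[k] = next_id
                next_id += 1
        ids = new_ids
    det = detections[n - 1]
    for j in range(len(det)):
        rows.append((n - 1, ids[j], det["x_um"].iloc[j], det["y_um"].iloc[j],
                     np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["frame", "particle_id", "x_um", "y_um",
                                     "vx_um_s", "vy_um_s"])
    return ParticleTracks(df, frame_interval=frame_interval)
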