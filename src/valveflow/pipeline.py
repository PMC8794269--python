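"""End-to-end demo pipeline on seeded synthetic scenarios.

``run_demo`` generates a Poiseuille tube scenario with known ground truth,
estimates wall shear stress through both regimes (two-phase from tracked
particles, one-phase from the ventricular volume trace and the maximum
inscribed circle), runs the dot-density and polarity quantifications on
seeded fixtures, and reports every estimate next to its analytic truth in a
machine-readable dictionary.  All randomness derives from the single seed in
the configuration, so a rerun regenerates the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rnascope, synthetic, tracking, viscosity, wss

__all__ = ["PipelineConfig", "StageError", "run_demo"]


@dataclass
class PipelineConfig:
    """Resolved parameters of a demo run; serializes losslessly to JSON."""

    seed: int = 0
    um_per_px: float = 1.0
    # tube scenario for the WSS cross-validation (ground-truth tracks)
    tube_radius_um: float = 25.0
    tube_length_um: float = 400.0
    peak_flow_nl_s: float = 1.0
    period_s: float = 0.5
    n_frames: int = 120
    tracer_count: int = 150
    near_wall_cutoff_frac: float = 0.15
    envelope_halfwidth: int = 2
    viscosity_mpas: float = 1.5
    # smaller rendered scenario for registration-based tracking
    track_n_frames: int = 12
    track_peak_flow_nl_s: float = 0.15
    track_radius_um: float = 20.0
    track_length_um: float = 160.0
    grid_spacing_um: float = 5.6
    segment_threshold: float = 60.0
    # quantification fixtures
    spot_counts: tuple[int, ...] = (0, 12, 30, 90)
    polarity_contrast: float = 2.0
    polarity_noise_sd: float = 1.0
    output_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        if "spot_counts" in payload:
            payload["spot_counts"] = tuple(payload["spot_counts"])
        return cls(**payload)


class StageError(RuntimeError):
    """A demo stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _rel_err(est: float, true: float) -> float:
    return abs(est - true) / abs(true)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:   # noqa: BLE001 - named-stage reporting
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("wss_cross_validation")
def _wss_stage(cfg: PipelineConfig) -> dict:
    sc = synthetic.TubeFlowScenario(
        radius_fn=cfg.tube_radius_um,
        centerline=((0.0, 0.0), (cfg.tube_length_um, 0.0)),
        peak_flow=cfg.peak_flow_nl_s,
        period=cfg.period_s,
        frame_interval=cfg.period_s / 100.0,
        n_frames=cfg.n_frames,
        viscosity=cfg.viscosity_mpas,
        tracer_count=cfg.tracer_count,
        tracer_radius=1.0,
        seed=cfg.seed,
    )
    movie = synthetic.generate_tube_movie(sc, render=False)
    gt = movie.ground_truth
    true_max = float(np.max(gt["wall_shear_rate_s"]))
    true_p95 = float(np.percentile(gt["wall_shear_rate_s"], 95))

    cutoff = cfg.near_wall_cutoff_frac * cfg.tube_radius_um
    two = wss.near_wall_shear(movie.tracks, movie.wall, cfg.viscosity_mpas,
                              near_wall_cutoff=cutoff)
    times, q = wss.flow_rate_from_volume(movie.volume_trace)
    (_, _), r_in = wss.max_inscribed_circle(
        movie.wall.cross_sections[0], resolution=0.5)
    one = wss.parabolic_wall_shear(times, q, r_in, cfg.viscosity_mpas)
    agree = wss.compare_traces(two, one)
    return {
        "analytic_max_shear_rate_s": true_max,
        "analytic_p95_shear_rate_s": true_p95,
        "two_phase_max_shear_rate_s": two.max_rate,
        "one_phase_max_shear_rate_s": one.max_rate,
        "two_phase_max_rel_err": _rel_err(two.max_rate, true_max),
        "one_phase_max_rel_err": _rel_err(one.max_rate, true_max),
        "two_phase_p95_rel_err": _rel_err(two.p95_rate, true_p95),
        "one_phase_p95_rel_err": _rel_err(one.p95_rate, true_p95),
        "regime_agreement_rel_err": abs(agree.max_rate_ratio - 1.0),
        "max_stress_pa_one_phase": one.max_stress,
        "inscribed_radius_um": r_in,
    }


@_stage("tracking")
def _tracking_stage(cfg: PipelineConfig) -> dict:
    sc = synthetic.TubeFlowScenario(
        radius_fn=cfg.track_radius_um,
        centerline=((0.0, 0.0), (cfg.track_length_um, 0.0)),
        peak_flow=cfg.track_peak_flow_nl_s,
        period=cfg.period_s,
        frame_interval=0.01,
        n_frames=cfg.track_n_frames,
        viscosity=cfg.viscosity_mpas,
        tracer_count=12,
        tracer_radius=2.0,
        noise_sd=1.0,
        seed=cfg.seed + 1,
    )
    movie = synthetic.generate_tube_movie(sc)
    est = tracking.track_movie(movie.stack, threshold=cfg.segment_threshold,
                               grid_spacing_um=cfg.grid_spacing_um,
                               um_per_px=sc.um_per_px,
                               frame_interval=sc.frame_interval)
    vel = est.velocities()
    gt = movie.ground_truth
    # match estimates to ground truth by position, away from the wall
    errs = []
    origin = movie.image_origin_um
    p0 = np.array(sc.centerline[0])
    for row in vel.itertuples(index=False):
        f = int(row.frame)
        x_w = row.x_um + origin[0]
        y_w = row.y_um + origin[1]
        r_off = y_w - p0[1]
        if abs(r_off) > 0.7 * cfg.track_radius_um:
            continue
        i = int(np.argmin(
            np.abs(gt["tracer_axial_um"][f] - (x_w - p0[0]))
            + np.abs(gt["tracer_radial_um"] - r_off)))
        v_true = gt["tracer_velocity_um_s"][f][i]
        if abs(v_true) < 20.0:
            continue
        errs.append(abs(row.vx_um_s - v_true) / abs(v_true))
    if not errs:
        raise ValueError("no track matched the ground truth")
    return {
        "n_velocity_samples": len(errs),
        "median_velocity_rel_err": float(np.median(errs)),
    }


@_stage("dot_quantification")
def _dots_stage(cfg: PipelineConfig) -> dict:
    spec = default_spot_spec(cfg.spot_counts, seed=cfg.seed + 2)
    spot = synthetic.generate_spot_image(spec)
    result = quantify_spot_image(spot, spec)
    errors = {lbl: abs(result[lbl].count - spec.dot_count_per_roi.get(lbl, 0))
              for lbl in spec.roi_polygons if lbl != "background"}
    return {
        "planted_counts": {k: spec.dot_count_per_roi.get(k, 0)
                           for k in errors},
        "recovered_counts": {k: result[k].count for k in errors},
        "abs_count_errors": errors,
    }


@_stage("polarity_quantification")
def _polarity_stage(cfg: PipelineConfig) -> dict:
    from . import ratiometry
    c = 40.0
    img = synthetic.generate_polarity_image(
        apical_green=cfg.polarity_contrast * c, basal_green=c,
        apical_red=c, basal_red=c,
        noise_sd=cfg.polarity_noise_sd, seed=cfg.seed + 3)
    pol = ratiometry.polarity_ratio(img.image, img.apical_segments,
                                    img.basal_segments)
    contrast = {"luminal": 2.0 * c, "abluminal": c}
    img2 = synthetic.generate_polarity_image(
        c, c, c, c, lateral_green=contrast,
        noise_sd=cfg.polarity_noise_sd, seed=cfg.seed + 4)
    measures = [
        ratiometry.measure_interface(img2.image[0], seg, f"{lbl}_{i}", lbl)
        for lbl, segs in img2.lateral_segments.items()
        for i, seg in enumerate(segs)]
    iratio = ratiometry.interface_ratio(measures, "luminal", "abluminal")
    return {
        "planted_polarity_ratio": cfg.polarity_contrast,
        "recovered_polarity_ratio": pol.ratio,
        "polarity_rel_err": _rel_err(pol.ratio, cfg.polarity_contrast),
        "planted_interface_ratio": 2.0,
        "recovered_interface_ratio": iratio,
        "interface_rel_err": _rel_err(iratio, 2.0),
    }


@_stage("viscosity_model")
def _viscosity_stage(cfg: PipelineConfig) -> dict:
    d_f = viscosity.equivalent_molecule_diameter(viscosity.PLASMA)
    phi, dilution = viscosity.injection_volume_fraction(
        stock_fraction=0.05, injected_volume=4.6, blood_volume=60.0)
    spec = viscosity.NanofluidSpec(fluid=viscosity.PLASMA, d_p=95e-9, phi=phi)
    mu_eff = viscosity.effective_viscosity(spec)
    return {
        "plasma_molecule_diameter_m": d_f,
        "dilution_factor": dilution,
        "phi_in_blood": phi,
        "mu_eff_mpas": mu_eff,
        "viscosity_ratio": mu_eff / viscosity.PLASMA.mu_f,
    }


def default_spot_spec(counts=(0, 12, 30, 90), seed: int = 0,
                      dim_offset: float | None = None
                      ) -> synthetic.SpotImageSpec:
    """Standard four-region spot fixture: 110x110 px regions in a 2x2 block
    plus a 120x120 background ROI; optionally one extra below-background
    region (``dim_offset`` < 0)."""
    def rect(x, y, w, h):
        return np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]],
                        dtype=float)

    rois = {"background": rect(245, 5, 120, 120)}
    dot_counts = {}
    for i, cnt in enumerate(counts):
        lbl = f"region_{i}"
        rois[lbl] = rect(5 + (i % 2) * 118, 5 + (i // 2) * 118, 110, 110)
        dot_counts[lbl] = int(cnt)
    offsets = {}
    if dim_offset is not None:
        rois["dim"] = rect(245, 130, 110, 100)
        offsets["dim"] = dim_offset
    return synthetic.SpotImageSpec(
        image_shape=(245, 370), background_level=50.0,
        dot_count_per_roi=dot_counts, dot_amplitude=80.0, dot_sigma=2.0,
        roi_polygons=rois, noise_sd=8.0, seed=seed, roi_offsets=offsets)


def quantify_spot_image(spot: synthetic.SpotImage,
                        spec: synthetic.SpotImageSpec,
                        n_reference_dots: int = 20
                        ) -> dict[str, rnascope.DotQuantResult]:
    """Run the full dot statistic on a synthetic spot image: background from
    the ``background`` ROI, calibration from up to ``n_reference_dots``
    ledger dots, counts for every other ROI."""
    bg_roi = rnascope.measure_roi(spot.image, spot.roi_polygons["background"],
                                  label="background")
    ref = spot.ledger.head(n_reference_dots)
    if len(ref) == 0:
        raise ValueError("ledger holds no reference dots for calibration")
    bg = rnascope.background_level(bg_roi)
    cal_dots = [(row.integrated_intensity + bg * row.area_px2, row.area_px2)
                for row in ref.itertuples(index=False)]
    cal = rnascope.DotCalibration(dots=cal_dots, background_roi=bg_roi)
    dot_mean = rnascope.mean_dot_intensity(cal)
    out = {}
    for lbl, poly in spot.roi_polygons.items():
        if lbl == "background":
            continue
        roi = rnascope.measure_roi(spot.image, poly, label=lbl)
        count, density = rnascope.dots_in_roi(roi, bg, dot_mean)
        out[lbl] = rnascope.DotQuantResult(
            label=lbl, count=count, density=density, area=roi.area,
            background=bg, dot_mean=dot_mean)
    return out


def run_demo(config: PipelineConfig | None = None) -> dict:
    """Run every stage on seeded fixtures and return the error report.

    When ``config.output_dir`` is set, the resolved configuration and the
    report are written there as JSON.
    """
    cfg = config or PipelineConfig()
    report = {
        "config": dataclasses.asdict(cfg),
        "wss": _wss_stage(cfg),
        "tracking": _tracking_stage(cfg),
        "dots": _dots_stage(cfg),
        "polarity": _polarity_stage(cfg),
        "viscosity": _viscosity_stage(cfg),
    }
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(cfg.to_json(), encoding="utf-8")
        (out / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default),
            encoding="utf-8")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
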