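"""Junction-intensity ratios and apical/basal polarity ratiometry.

Two formula-defined quantifications of membrane fluorescence:

* **interface ratio** — cell–cell interfaces are grouped into two labeled
  sets (e.g. luminal vs abluminal); the ratio is the across-interface
  average of a per-interface statistic (mean or max intensity) in the
  numerator set divided by the same average in the denominator set.

* **polarity ratio** — with a protein channel (green) and a membrane
  reference channel (red), the per-embryo value is the ratio-of-ratios

      (sum_z apical_green / sum_z apical_red)
    / (sum_z basal_green  / sum_z basal_red),

  where each term is a per-slice channel mean sampled along annotated
  membrane segments.  Values above 1 indicate apical enrichment of the
  protein relative to the membrane marker; the construction is invariant to
  independent global rescaling of either channel.

Departures of such ratios from the theoretical value 1 are assessed with a
one-sample Wilcoxon signed-rank test (the coherent one-sample analogue of a
rank test against a constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates

__all__ = [
    "InterfaceMeasurement",
    "PolarityMeasurement",
    "RankTestResult",
    "sample_along_polyline",
    "measure_interface",
    "interface_ratio",
    "polarity_ratio",
    "one_sample_rank_test",
]


@dataclass(frozen=True)
class InterfaceMeasurement:
    """Summary intensities of one cell–cell interface."""

    interface_id: str
    label: str
    mean_intensity: float
    max_intensity: float

    def __post_init__(self) -> None:
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be >= 0")
        if self.max_intensity < self.mean_intensity:
            raise ValueError("max_intensity must be >= mean_intensity")


@dataclass
class PolarityMeasurement:
    """Per-slice channel means along apical and basal segments, plus the
    embryo-level ratio-of-ratios."""

    per_slice: pd.DataFrame   # slice, apical_green, apical_red, basal_green, basal_red
    ratio: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def sample_along_polyline(image: np.ndarray, polyline: np.ndarray,
                          spacing: float = 1.0) -> np.ndarray:
    """Bilinear intensity samples at fixed arc-length spacing (px) along a
    polyline of (x, y) pixel coordinates."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (N>=2, 2) array of (x, y)")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total == 0:
        raise ValueError("degenerate (zero-length) segment")
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(2, int(np.floor(total / spacing)) + 1)
    s = np.linspace(0.0, total, n)
    xs = np.interp(s, arc, pts[:, 0])
    ys = np.interp(s, arc, pts[:, 1])
    return map_coordinates(np.asarray(image, dtype=float),
                           np.vstack([ys, xs]), order=1, mode="nearest")


def measure_interface(image: np.ndarray, polyline: np.ndarray,
                      interface_id: str, label: str,
                      spacing: float = 1.0) -> InterfaceMeasurement:
    """Mean and max intensity sampled along one interface polyline."""
    vals = sample_along_polyline(image, polyline, spacing)
    return InterfaceMeasurement(interface_id=interface_id, label=label,
                                mean_intensity=float(vals.mean()),
                                max_intensity=float(vals.max()))


def interface_ratio(
    measurements: Sequence[InterfaceMeasurement],
    numerator_label: str,
    denominator_label: str,
    statistic: str = "mean",
) -> float:
    """Ratio of across-interface averages of the chosen per-interface
    statistic (``"mean"`` or ``"max"``)."""
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    key = "mean_intensity" if statistic == "mean" else "max_intensity"
    num = [getattr(m, key) for m in measurements if m.label == numerator_label]
    den = [getattr(m, key) for m in measurements if m.label == denominator_label]
    if not num or not den:
        raise ValueError("both label sets must be non-empty")
    denominator = float(np.mean(den))
    if denominator == 0:
        raise ValueError("denominator interfaces have zero mean intensity")
    return float(np.mean(num)) / denominator


def polarity_ratio(
    slices: Sequence[np.ndarray] | np.ndarray,
    apical_segments: Sequence[Sequence[np.ndarray]] | Sequence[np.ndarray],
    basal_segments: Sequence[Sequence[np.ndarray]] | Sequence[np.ndarray],
    spacing: float = 1.0,
) -> PolarityMeasurement:
    """Apical/basal green-over-red ratio-of-ratios across z-slices.

    ``slices`` is one (2, H, W) two-channel image or a sequence of them
    (channel 0 = green, 1 = red); segments are per-slice lists of (N, 2)
    polylines (a flat list is accepted for a single slice).  Per-slice
    channel means along the segments are summed over slices before the
    ratios are formed, and the per-slice table is returned so either pooling
    convention can be recovered.
    """
    if isinstance(slices, np.ndarray) and slices.ndim == 3:
        slices = [slices]
        if apical_segments and isinstance(apical_segments[0], np.ndarray):
            apical_segments = [apical_segments]
        if basal_segments and isinstance(basal_segments[0], np.ndarray):
            basal_segments = [basal_segments]
    if not (len(slices) == len(apical_segments) == len(basal_segments)):
        raise ValueError("one segment list per slice required")

    rows = []
    for z, (img, apicals, basals) in enumerate(
            zip(slices, apical_segments, basal_segments)):
        img = np.asarray(img, dtype=float)
        if img.ndim != 3 or img.shape[0] != 2:
            raise ValueError("each slice must be a (2, H, W) two-channel image")
        if len(apicals) == 0 or len(basals) == 0:
            raise ValueError("each slice needs apical and basal segments")

        def _mean(channel: np.ndarray, segs) -> float:
            vals = np.concatenate(
                [sample_along_polyline(channel, s, spacing) for s in segs])
            return float(vals.mean())

        rows.append({
            "slice": z,
            "apical_green": _mean(img[0], apicals),
            "apical_red": _mean(img[1], apicals),
            "basal_green": _mean(img[0], basals),
            "basal_red": _mean(img[1], basals),
        })
    table = pd.DataFrame(rows)
    ar = table["apical_red"].sum()
    br = table["basal_red"].sum()
    bg = table["basal_green"].sum()
    if ar <= 0 or br <= 0:
        raise ValueError("zero red (membrane) signal on the apical or basal side")
    if bg == 0:
        raise ValueError("zero basal green signal: ratio undefined")
    ratio = (table["apical_green"].sum() / ar) / (bg / br)
    return PolarityMeasurement(per_slice=table, ratio=float(ratio))


def one_sample_rank_test(values: Sequence[float],
                         null_value: float = 1.0) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test of ``values`` against a constant.

    Exact null distribution for n <= 25 (when no ties or zero differences),
    normal approximation otherwise.  All values equal to the null is
    degenerate and reported as p = 1 with a flag.  Requires n >= 5.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 5:
        raise ValueError(f"need at least 5 values, got {vals.size}")
    diffs = vals - null_value
    if np.all(diffs == 0):
        return RankTestResult(statistic=0.0, p_value=1.0, n=int(vals.size),
                              degenerate=True)
    nz = diffs[diffs != 0]
    exact_ok = (vals.size <= 25 and nz.size == vals.size
                and np.unique(np.abs(nz)).size == nz.size)
    res = stats.wilcoxon(diffs, alternative="two-sided",
                         method="exact" if exact_ok else "approx")
    return RankTestResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue), n=int(vals.size))
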