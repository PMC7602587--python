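"""Epithelial thickness and vessel-density quantification.

Thickness: OCT measures depth in optical path length (OPL), so a pixel
count converts to geometric tissue length as ``pixels * l / n`` with the
axial pixel pitch ``l = 5 um`` (in air) and the epithelial refractive
index ``n = 1.37``.  Thickness is sampled at five evenly distributed
lateral positions per B-scan; the mean over the 5 x 5 samples of a series
is the subject-level value at that measurement point.

Vessel density: the summed luminal cross-sectional area of larger vessels
divided by the avascular epithelial area of the same B-scan, rated
``low`` (< 0.10), ``moderate`` (0.10-0.30, both endpoints included) or
``high`` (> 0.30).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon

from .geometry import BScanSeries, ScanGeometry
from .segmentation import LayerSegmentation

__all__ = [
    "ThicknessResult", "VascularizationResult",
    "opl_to_geometric", "sample_positions", "measure_thickness",
    "vessel_density", "classify_vascularization",
    "LOW_MODERATE_CUT", "MODERATE_HIGH_CUT",
]

#: class boundaries of the vascularization rating; the moderate class is
#: the closed interval [0.10, 0.30]
LOW_MODERATE_CUT = 0.10
MODERATE_HIGH_CUT = 0.30


def opl_to_geometric(opl_pixels: float, axial_pixel: float = 5.0,
                     refractive_index: float = 1.37) -> float:
    """Geometric length (um) of an axial pixel count measured in OPL.

    Exact and linear: ``opl_pixels * axial_pixel / refractive_index``.
    """
    opl_pixels = np.asarray(opl_pixels, dtype=float)
    if np.any(opl_pixels < 0):
        raise ValueError("opl_pixels must be >= 0")
    if not axial_pixel > 0:
        raise ValueError("axial_pixel must be > 0")
    if not refractive_index >= 1:
        raise ValueError("refractive_index must be >= 1")
    out = opl_pixels * axial_pixel / refractive_index
    return float(out) if out.ndim == 0 else out


def sample_positions(n_columns: int, n_positions: int = 5) -> list[int]:
    """Evenly distributed sampling columns: centers of equal lateral bins.

    ``column_i = floor((i + 0.5) * n_columns / n_positions)`` — avoids the
    image-edge columns that an endpoint-inclusive spacing would hit.
    """
    if n_positions > n_columns:
        raise ValueError("n_positions must not exceed n_columns")
    return [int(np.floor((i + 0.5) * n_columns / n_positions))
            for i in range(n_positions)]


@dataclass
class ThicknessResult:
    """Series-level epithelial thickness with per-sample provenance."""

    per_position: list                  # (bscan_index, column, opl_pixels, geometric_um)
    per_bscan_mean: list                # um, NaN where a scan had no usable sample
    series_mean: float | None           # um; None when not assessable
    series_sd: float | None             # um, sample SD (ddof=1); 0.0 for n=1
    n_samples: int
    n_skipped: int                      # sampled columns without a located BM
    refractive_index: float
    axial_pixel: float

    @property
    def assessable(self) -> bool:
        return self.series_mean is not None


def measure_thickness(series: BScanSeries | None,
                      segmentations: Sequence[LayerSegmentation] | None = None,
                      *, annotations=None,
                      geometry: ScanGeometry | None = None,
                      refractive_index: float = 1.37,
                      n_positions: int = 5) -> ThicknessResult:
    """Epithelial thickness of one series, automatic or manual mode.

    Automatic mode supplies one :class:`LayerSegmentation` per B-scan and
    samples ``n_positions`` evenly distributed columns per scan, skipping
    (and counting) columns whose BM is absent.  Manual mode supplies an
    annotation set whose thickness lines carry the columns directly.  If no
    sampled column in the whole series has a measurable BM, the result is
    flagged not assessable (``series_mean is None``).
    """
    if geometry is None:
        if series is not None:
            geometry = series.geometry
        else:
            raise ValueError("geometry is required when no series is given")
    ax = geometry.axial_pixel
    samples: list[tuple[int, int, float, float]] = []
    skipped = 0
    if annotations is not None:
        lines_by_scan: dict[int, list] = {}
        for ln in annotations.thickness_lines:
            lines_by_scan.setdefault(ln.bscan, []).append(ln)
        n_scans = max(lines_by_scan, default=-1) + 1
        if series is not None:
            n_scans = max(n_scans, len(series))
        for i in range(n_scans):
            for ln in lines_by_scan.get(i, []):
                opl = float(ln.bm_row - ln.surface_row)
                samples.append((i, ln.column, opl,
                                opl_to_geometric(opl, ax, refractive_index)))
    else:
        if segmentations is None:
            raise ValueError("either segmentations or annotations are required")
        columns = sample_positions(geometry.n_columns, n_positions)
        n_scans = len(segmentations)
        for i, seg in enumerate(segmentations):
            for c in columns:
                if seg.located[c]:
                    opl = float(seg.bm_trace[c] - seg.surface_trace[c])
                    samples.append((i, c, opl, opl_to_geometric(opl, ax, refractive_index)))
                else:
                    skipped += 1

    per_bscan_mean = []
    for i in range(n_scans):
        vals = [s[3] for s in samples if s[0] == i]
        per_bscan_mean.append(float(np.mean(vals)) if vals else float("nan"))
    if not samples:
        return ThicknessResult([], per_bscan_mean, None, None, 0, skipped,
                               refractive_index, ax)
    geom = np.array([s[3] for s in samples])
    sd = float(np.std(geom, ddof=1)) if geom.size > 1 else 0.0
    return ThicknessResult(samples, per_bscan_mean, float(geom.mean()), sd,
                           len(samples), skipped, refractive_index, ax)


@dataclass
class VascularizationResult:
    """Vessel-density ratio of one B-scan and its three-class rating."""

    vessel_area_px: float
    epithelial_area_px: float
    ratio: float
    rating: str

    def __post_init__(self) -> None:
        if self.rating not in ("low", "moderate", "high"):
            raise ValueError(f"invalid rating {self.rating!r}")


def classify_vascularization(ratio: float) -> str:
    """Three-class rating of the vessel-density ratio.

    ``low`` below 0.10, ``moderate`` on the closed interval [0.10, 0.30],
    ``high`` above 0.30.  Monotone step function; negative ratios raise.
    """
    if ratio < 0:
        raise ValueError("vessel-density ratio must be >= 0")
    if ratio < LOW_MODERATE_CUT:
        return "low"
    if ratio <= MODERATE_HIGH_CUT:
        return "moderate"
    return "high"


def _rasterize_regions(regions, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for reg in regions:
        if hasattr(reg, "cy"):          # ellipse annotation
            rr, cc = _draw_ellipse(reg.cy, reg.cx, reg.axis_r, reg.axis_c,
                                   shape=shape, rotation=np.deg2rad(reg.angle_deg))
        else:                           # (row, col) polygon vertices
            verts = np.asarray(reg, dtype=float)
            rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = True
    return mask


def vessel_density(vessel_regions, epithelial_region,
                   shape: tuple[int, int] | None = None) -> VascularizationResult:
    """Vessel-density ratio: summed luminal area / epithelial area.

    ``vessel_regions`` may be a boolean mask, a list of ellipse annotations
    or a list of (row, col) polygons; shapes are rasterized before the area
    sum.  ``epithelial_region`` may be a boolean mask, a pixel count, or a
    (row, col) polygon.  Zero epithelial area raises ``ValueError``.
    """
    if isinstance(vessel_regions, np.ndarray) and vessel_regions.dtype == bool:
        vessel_px = float(vessel_regions.sum())
        shape = vessel_regions.shape
    else:
        if shape is None and isinstance(epithelial_region, np.ndarray):
            shape = epithelial_region.shape
        if shape is None:
            raise ValueError("shape is required to rasterize vessel regions")
        vessel_px = float(_rasterize_regions(vessel_regions, shape).sum())

    if isinstance(epithelial_region, np.ndarray):
        epith_px = float(epithelial_region.sum())
    elif np.isscalar(epithelial_region):
        epith_px = float(epithelial_region)
    else:
        if shape is None:
            raise ValueError("shape is required to rasterize the epithelial polygon")
        verts = np.asarray(epithelial_region, dtype=float)
        rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        epith_px = float(len(rr))
    if epith_px <= 0:
        raise ValueError("epithelial area must be > 0")
    ratio = vessel_px / epith_px
    return VascularizationResult(vessel_px, epith_px, ratio,
                                 classify_vascularization(ratio))
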