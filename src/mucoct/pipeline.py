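"""Shared per-series analysis path for the auto / manual / truth modes.

All three modes funnel into the same downstream computations (thickness,
vessel density, seven-criterion score), differing only in where layer
boundaries and vessel regions come from:

* ``auto``   — detectors (segmentation + scoring modules); vessel regions
  must still be supplied (annotations or phantom truth): automatic vessel
  segmentation is out of scope.
* ``manual`` — annotation thickness lines / vessel ellipses.
* ``truth``  — phantom ground truth (the oracle path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregate import SubjectSeriesResult
from .geometry import BScanSeries
from .quantify import measure_thickness, vessel_density
from .scoring import ScoringConfig, score_bscan, score_from_truth
from .segmentation import (BM_FOUND, BM_UNSHARP, BM_ABSENT, LayerSegmentation,
                           SegmentationConfig, segment_bscan)

__all__ = ["SeriesAnalysis", "truth_segmentation", "analyze_series"]

MODES = ("auto", "manual", "truth")


def truth_segmentation(truth, seg_config: SegmentationConfig | None = None) -> LayerSegmentation:
    """A :class:`LayerSegmentation` read off a phantom's ground truth.

    Column statuses carry the labels the generating parameters imply: the
    epithelium/lamina contrast grades columns found vs unsharp, and a BM
    below the SNR-limited depth is absent everywhere.
    """
    cfg = seg_config or SegmentationConfig()
    prof = truth.params["profile"]
    refl, att = prof["reflectivity"], prof["attenuation"]
    contrast = (refl["mu_lp"] - refl["mu_ep"]) / refl["mu_ep"]
    n_cols = truth.surface_trace.size
    band_opl_um = float(np.median(truth.bm_trace - truth.surface_trace)) \
        * truth.geometry.axial_pixel
    ep_at_bm = refl["mu_ep"] * np.exp(-att["ep"] * band_opl_um)
    if ep_at_bm < cfg.snr_factor * prof["noise_floor"] \
            or band_opl_um > cfg.bm_max_depth_um:
        status = BM_ABSENT
    elif contrast >= cfg.c_hi:
        status = BM_FOUND
    else:
        status = BM_UNSHARP
    statuses = np.full(n_cols, status, dtype=object)
    bm = truth.bm_trace if status != BM_ABSENT else np.full(n_cols, -1, dtype=np.int64)
    return LayerSegmentation(
        surface_trace=truth.surface_trace.copy(), bm_trace=bm.copy(),
        bm_status=statuses, bm_contrast=np.full(n_cols, float(contrast)),
        shape=truth.geometry.shape)


@dataclass
class SeriesAnalysis:
    """Everything computed for one series."""

    segmentations: list
    thickness: object                 # ThicknessResult
    vascularizations: list            # per B-scan VascularizationResult or None
    criteria: list                    # per B-scan CriteriaScore

    @property
    def vessel_ratio(self) -> float | None:
        ratios = [v.ratio for v in self.vascularizations if v is not None]
        return float(np.mean(ratios)) if ratios else None

    def to_subject_result(self, metadata, image_count: int | None = None) -> SubjectSeriesResult:
        rows = [c.to_row() for c in self.criteria]
        return SubjectSeriesResult(
            subject_id=metadata.subject_id,
            measurement_point=metadata.measurement_point,
            sex=metadata.sex, age_group=metadata.age_group,
            thickness_series_mean=(self.thickness.series_mean
                                   if self.thickness.assessable else None),
            vessel_ratio=self.vessel_ratio,
            criteria_rows=rows,
            image_count=image_count if image_count is not None else len(self.criteria))


def analyze_series(series: BScanSeries, mode: str = "auto", *, truths=None,
                   annotations=None, refractive_index: float = 1.37,
                   seg_config: SegmentationConfig | None = None,
                   scoring_config: ScoringConfig | None = None) -> SeriesAnalysis:
    """Run segmentation, quantification and scoring on one series."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    seg_config = seg_config or SegmentationConfig()
    scoring_config = scoring_config or ScoringConfig()
    geometry = series.geometry

    if mode == "truth":
        if truths is None:
            raise ValueError("truth mode requires phantom truths")
        segs = [truth_segmentation(t, seg_config) for t in truths]
    else:
        segs = [segment_bscan(b, seg_config) for b in series]

    if mode == "manual":
        if annotations is None:
            raise ValueError("manual mode requires annotations")
        thickness = measure_thickness(series, annotations=annotations,
                                      geometry=geometry,
                                      refractive_index=refractive_index)
    else:
        thickness = measure_thickness(series, segs, geometry=geometry,
                                      refractive_index=refractive_index)

    vascularizations = []
    for i, seg in enumerate(segs):
        area = seg.epithelial_band_area_px()
        vessel_source = None
        if mode == "truth" or (mode == "auto" and truths is not None):
            vessel_source = truths[i].masks["vessel"]
            if mode == "truth":
                area = truths[i].epithelial_band_area_px()
        elif annotations is not None:
            marks = [e for e in annotations.vessel_regions if e.bscan == i]
            vessel_source = marks if marks else None
            poly = annotations.epithelial_polygon.get(str(i))
            if poly:
                area = poly  # rasterized inside vessel_density
        if vessel_source is None or area is None or \
                (np.isscalar(area) and area <= 0):
            vascularizations.append(None)
            continue
        vascularizations.append(
            vessel_density(vessel_source, area, shape=geometry.shape))

    criteria = []
    for i, (bscan, seg) in enumerate(zip(series, segs)):
        vasc = vascularizations[i]
        thick_ref = thickness if thickness.assessable else None
        if mode == "truth":
            score = score_from_truth(truths[i], geometry, scoring_config)
            if score.bm_assessment != "not_assessable":
                score.thickness = thick_ref
                score.vascularization = vasc
        else:
            score = score_bscan(bscan, seg, thick_ref, vasc, scoring_config)
        criteria.append(score)
    return SeriesAnalysis(segs, thickness, vascularizations, criteria)
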