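"""Stable on-disk formats: image stacks, sidecars, annotations, tables.

* B-scan series are multi-page grayscale TIFF stacks (written as float32
  linear intensity; 8- and 16-bit integer stacks are accepted on read)
  with a JSON metadata sidecar (versioned schema) next to the stack.
* Phantom truth is a parallel integer-label TIFF plus a JSON with traces,
  features and generating parameters.
* Manual annotations (thickness lines, vessel ellipses, polygons,
  criterion labels, component marks) are one JSON document; unknown
  fields round-trip untouched so both the manual and the automatic path
  share one downstream representation.
* Summary tables are CSV with documented, stable columns; percentages are
  printed to one decimal place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .geometry import BScanSeries, ScanGeometry
from .regions import AGE_GROUPS, SEXES, region_of

logger = logging.getLogger(__name__)

__all__ = [
    "StudyMetadata", "AnnotationSet", "ThicknessLine", "VesselEllipse",
    "ComponentMark", "CorruptStackError", "SidecarError",
    "GeometryMismatchError", "AnnotationBoundsError",
    "save_series", "load_series", "save_truth", "load_truth",
    "load_annotations", "save_annotations", "validate_annotations",
    "write_summary_tables", "fmt_pct",
]

SIDECAR_SCHEMA_VERSION = 1
ANNOTATION_SCHEMA_VERSION = 1

DEFAULT_REFRACTIVE_INDEX = 1.37


class CorruptStackError(RuntimeError):
    """The image stack cannot be read."""


class SidecarError(RuntimeError):
    """The metadata sidecar is missing or schema-invalid."""


class GeometryMismatchError(RuntimeError):
    """The stack's page count/size contradicts the sidecar geometry."""


class AnnotationBoundsError(ValueError):
    """Annotation coordinates fall outside the image bounds."""


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------

@dataclass
class StudyMetadata:
    """Provenance of one B-scan series."""

    subject_id: str
    measurement_point: str
    sex: str = "unspecified"
    age_group: str = "unspecified"
    geometry: ScanGeometry = None  # type: ignore[assignment]
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    seed: int | None = None
    quality_flag: str | None = None

    def __post_init__(self) -> None:
        if self.geometry is None:
            self.geometry = ScanGeometry()
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        self.region_id = region_of(self.measurement_point)

    def to_sidecar(self) -> dict:
        return {
            "schema_version": SIDECAR_SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "measurement_point": self.measurement_point,
            "sex": self.sex,
            "age_group": self.age_group,
            "geometry": self.geometry.to_dict(),
            "refractive_index": self.refractive_index,
            "seed": self.seed,
            "quality_flag": self.quality_flag,
        }


class _SidecarModel(BaseModel):
    model_config = ConfigDict(extra="allow")
    schema_version: int
    subject_id: str
    measurement_point: str
    sex: str = "unspecified"
    age_group: str = "unspecified"
    geometry: dict
    refractive_index: float | None = None
    seed: int | None = None
    quality_flag: str | None = None


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def save_series(series: BScanSeries, metadata: StudyMetadata, stack_path) -> Path:
    """Write a series as a float32 multi-page TIFF plus its JSON sidecar."""
    stack_path = Path(stack_path)
    tifffile.imwrite(stack_path, np.asarray(series.images, dtype=np.float32),
                     photometric="minisblack")
    _sidecar_path(stack_path).write_text(
        json.dumps(metadata.to_sidecar(), indent=1, sort_keys=True) + "\n")
    return stack_path


def load_series(stack_path) -> tuple[BScanSeries, StudyMetadata]:
    """Read a stack + sidecar pair.

    Missing ``refractive_index`` falls back to 1.37 (logged); a page
    count/size that contradicts the sidecar geometry raises
    :class:`GeometryMismatchError`.
    """
    stack_path = Path(stack_path)
    try:
        images = tifffile.imread(stack_path)
    except (OSError, ValueError) as exc:
        raise CorruptStackError(f"cannot read stack {stack_path}: {exc}") from exc
    if images.ndim == 2:
        images = images[None]
    sidecar = _sidecar_path(stack_path)
    if not sidecar.exists():
        raise SidecarError(f"missing sidecar {sidecar}")
    try:
        model = _SidecarModel.model_validate(json.loads(sidecar.read_text()))
    except (json.JSONDecodeError, ValidationError) as exc:
        raise SidecarError(f"invalid sidecar {sidecar}: {exc}") from exc
    geometry = ScanGeometry.from_dict(model.geometry)
    if images.shape[0] != geometry.series_length or images.shape[1:] != geometry.shape:
        raise GeometryMismatchError(
            f"stack shape {images.shape} contradicts sidecar geometry "
            f"({geometry.series_length} x {geometry.shape})")
    n = model.refractive_index
    if n is None:
        n = DEFAULT_REFRACTIVE_INDEX
        logger.info("sidecar %s lacks refractive_index; using default %.2f", sidecar, n)
    metadata = StudyMetadata(
        subject_id=model.subject_id, measurement_point=model.measurement_point,
        sex=model.sex, age_group=model.age_group, geometry=geometry,
        refractive_index=n, seed=model.seed, quality_flag=model.quality_flag)
    return BScanSeries(np.asarray(images, dtype=np.float64), geometry), metadata


# ---------------------------------------------------------------------------
# phantom truth
# ---------------------------------------------------------------------------

_MASK_BITS = {"lesion": 1, "vessel": 2, "gland": 4, "follicle": 8, "keratin": 16}


def save_truth(truths: list, stack_path) -> Path:
    """Write phantom truths as a bit-packed label TIFF + JSON of traces."""
    stack_path = Path(stack_path)
    pages = []
    records = []
    for t in truths:
        page = np.zeros(t.masks["vessel"].shape, dtype=np.uint8)
        for name, bit in _MASK_BITS.items():
            page |= t.masks[name].astype(np.uint8) * bit
        pages.append(page)
        records.append({
            "surface_trace": t.surface_trace.tolist(),
            "bm_trace": t.bm_trace.tolist(),
            "features": [vars(f) for f in t.features],
            "vessel_ratio_achieved": t.vessel_ratio_achieved,
            "vessel_status": t.vessel_status,
            "params": t.params,
        })
    tifffile.imwrite(stack_path, np.stack(pages), photometric="minisblack")
    _sidecar_path(stack_path).write_text(
        json.dumps({"schema_version": SIDECAR_SCHEMA_VERSION, "truths": records},
                   sort_keys=True) + "\n")
    return stack_path


def load_truth(stack_path) -> list:
    from .phantom import PhantomTruth, PlacedFeature
    stack_path = Path(stack_path)
    pages = tifffile.imread(stack_path)
    if pages.ndim == 2:
        pages = pages[None]
    doc = json.loads(_sidecar_path(stack_path).read_text())
    truths = []
    for page, rec in zip(pages, doc["truths"]):
        masks = {name: (page & bit) > 0 for name, bit in _MASK_BITS.items()}
        surface = np.asarray(rec["surface_trace"], dtype=np.int64)
        bm = np.asarray(rec["bm_trace"], dtype=np.int64)
        geometry = ScanGeometry.from_dict(rec["params"]["geometry"])
        n = rec["params"]["profile"]["refractive_index"]
        truths.append(PhantomTruth(
            surface_trace=surface, bm_trace=bm, masks=masks,
            true_thickness_geom=(bm - surface) * geometry.axial_pixel / n,
            features=[PlacedFeature(**f) for f in rec["features"]],
            params=rec["params"],
            vessel_ratio_achieved=rec["vessel_ratio_achieved"],
            vessel_status=rec["vessel_status"]))
    return truths


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

class ThicknessLine(BaseModel):
    """One vertical thickness measurement: surface to BM at a column."""
    model_config = ConfigDict(extra="allow")
    bscan: int = 0
    column: int
    surface_row: int
    bm_row: int

    @model_validator(mode="after")
    def _ordered(self):
        if self.bm_row < self.surface_row:
            raise ValueError(f"bm_row {self.bm_row} < surface_row {self.surface_row}")
        return self


class VesselEllipse(BaseModel):
    """Elliptic vascularization mark (pixel coordinates, semi-axes)."""
    model_config = ConfigDict(extra="allow")
    bscan: int = 0
    cx: float
    cy: float
    axis_c: float
    axis_r: float
    angle_deg: float = 0.0


class ComponentMark(BaseModel):
    model_config = ConfigDict(extra="allow")
    kind: str  # 'gland' | 'follicle'
    bscan: int = 0
    row: float = 0.0
    col: float = 0.0


class AnnotationSet(BaseModel):
    """Manual annotations of one series; JSON round-trip is lossless."""
    model_config = ConfigDict(extra="allow")
    schema_version: int = ANNOTATION_SCHEMA_VERSION
    thickness_lines: list[ThicknessLine] = []
    vessel_regions: list[VesselEllipse] = []
    epithelial_polygon: dict[str, list] = {}   # bscan index (str) -> [[row, col], ...]
    criterion_labels: dict[str, dict] = {}
    component_marks: list[ComponentMark] = []


def load_annotations(path) -> AnnotationSet:
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    return AnnotationSet.model_validate(data)


def save_annotations(annotations: AnnotationSet, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(annotations.model_dump(), sort_keys=True, indent=1) + "\n")
    return path


def validate_annotations(annotations: AnnotationSet, shape: tuple[int, int]) -> None:
    """Check all coordinates against the image bounds; raise with offenders."""
    n_rows, n_cols = shape
    offenders = []
    for i, ln in enumerate(annotations.thickness_lines):
        if not (0 <= ln.column < n_cols and 0 <= ln.surface_row < n_rows
                and 0 <= ln.bm_row < n_rows):
            offenders.append(f"thickness_lines[{i}]")
    for i, e in enumerate(annotations.vessel_regions):
        if not (0 <= e.cx < n_cols and 0 <= e.cy < n_rows):
            offenders.append(f"vessel_regions[{i}]")
    for key, poly in annotations.epithelial_polygon.items():
        for r, c in poly:
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                offenders.append(f"epithelial_polygon[{key}]")
                break
    if offenders:
        raise AnnotationBoundsError(
            "annotation coordinates out of bounds: " + ", ".join(offenders))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def fmt_pct(count: int, total: int) -> float:
    """Percentage to one decimal place (the reporting convention)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * count / total, 1)


THICKNESS_COLUMNS = [
    "region", "measurement_point", "stratum", "group", "n", "mean_um", "sd_um",
    "min_um", "q1_um", "median_um", "q3_um", "max_um", "n1_flag",
]
CRITERIA_COLUMNS = ["region", "criterion", "category", "count", "percent"]
VESSEL_COLUMNS = ["region", "n", "ratio_mean", "ratio_sd",
                  "pct_low", "pct_moderate", "pct_high"]


def write_summary_tables(summaries: list, out_dir) -> dict:
    """Write the three summary CSVs from :class:`~mucoct.aggregate.RegionSummary`
    objects and return a manifest of the files written.

    Tables: per-measurement-point thickness statistics (overall and by
    sex/age stratum), per-region criterion percentage distributions, and
    per-region vessel-density distributions.  Row order and number
    formatting are deterministic.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    thick_rows, crit_rows, vessel_rows = [], [], []
    for s in sorted(summaries, key=lambda s: s.region_id):
        for mp in sorted(s.per_mp, key=lambda m: int(m[2:])):
            for stratum, group, stats in s.per_mp[mp].iter_strata():
                thick_rows.append(dict(
                    region=s.region_id, measurement_point=mp, stratum=stratum,
                    group=group, n=stats.n,
                    mean_um=round(stats.mean, 1), sd_um=round(stats.sd, 1),
                    min_um=round(stats.minimum, 1), q1_um=round(stats.q1, 1),
                    median_um=round(stats.median, 1), q3_um=round(stats.q3, 1),
                    max_um=round(stats.maximum, 1),
                    n1_flag=int(stats.n == 1)))
        for criterion, dist in sorted(s.criterion_pct.items()):
            for category in sorted(dist):
                count, pct = dist[category]
                crit_rows.append(dict(region=s.region_id, criterion=criterion,
                                      category=category, count=count, percent=pct))
        v = s.vessel_stats
        if v is not None:
            vessel_rows.append(dict(
                region=s.region_id, n=v["n"], ratio_mean=round(v["mean"], 3),
                ratio_sd=round(v["sd"], 3), pct_low=v["pct"]["low"],
                pct_moderate=v["pct"]["moderate"], pct_high=v["pct"]["high"]))

    manifest = {}
    for name, rows, cols in (
            ("thickness_by_mp.csv", thick_rows, THICKNESS_COLUMNS),
            ("criteria_pct.csv", crit_rows, CRITERIA_COLUMNS),
            ("vessel_density.csv", vessel_rows, VESSEL_COLUMNS)):
        path = out_dir / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        manifest[name] = str(path)
    (out_dir / "manifest.json").write_text(
        json.dumps({"schema_version": SIDECAR_SCHEMA_VERSION, "tables": manifest},
                   sort_keys=True, indent=1) + "\n")
    manifest["manifest.json"] = str(out_dir / "manifest.json")
    return manifest
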