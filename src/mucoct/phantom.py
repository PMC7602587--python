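"""Synthetic OCT B-scan phantom of the healthy oral mucosa.

The phantom renders the canonical appearance of lining and masticatory
mucosa in intensity OCT: a weakly scattering (hyporeflective) epithelium
above a strongly scattering (hyperreflective) lamina propria, separated
by the basement membrane.  Every render returns full ground truth
(layer traces, labelled masks, generating parameters) so each analysis
stage downstream has an exact oracle.

Model
-----
``image = (reflectivity * cumulative_attenuation + noise_floor) * speckle``

* reflectivity: piecewise-constant per layer (epithelium, lamina propria,
  keratinized cap, hyporeflective inclusions);
* attenuation: per-layer exponential decay of the single-pass intensity
  with optical depth;
* speckle: fully developed, i.e. multiplicative unit-mean exponentially
  distributed intensity (the standard single-look model);
* noise floor: a small background level that shares the speckle statistics,
  so its mean and SD are estimable from the air region above the tissue.

Region presets encode the seven investigation areas: regional epithelial
thickness (mean +/- SD, geometric micrometres), vessel-density targets,
surface features (palatal ridges, tonsillar crypts, lesions), keratin for
the masticatory hard palate, and salivary-gland / lymphoid-follicle rates.

Coordinates: row 0 is shallowest, rows grow downward; traces are 0-based
row indices; the epithelial band is [surface_row, bm_row) per column.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .geometry import BScan, BScanSeries, ScanGeometry

__all__ = [
    "Reflectivity", "Attenuation", "SurfaceFeatureSpec", "TissueProfile",
    "PlacedFeature", "PhantomTruth", "REGION_PRESETS",
    "build_profile", "render_bscan", "render_series", "place_vessels",
    "to_display_uint8",
]

MASK_LABELS = ("lesion", "vessel", "gland", "follicle", "keratin")

#: lateral width of the cosine shoulder of surface features, um.  Features
#: are flat-topped so that their detectable lateral extent matches their
#: nominal diameter; the shoulder is wide enough that the surface slope
#: stays within the detector's smoothness bound (3 rows/column).
FEATURE_EDGE_UM = 30.0

#: margin (rows) that must remain below the basement membrane
_BOTTOM_MARGIN_ROWS = 8

#: inclusions (vessel lumina, glands, follicles) keep this clearance below
#: the BM: larger vessels sit in the deeper reticular lamina propria, and
#: the clearance keeps the membrane's intensity step unconfounded
_INCLUSION_CLEARANCE_ROWS = 16


@dataclass(frozen=True)
class Reflectivity:
    """Mean linear backscatter level per tissue class (arbitrary units)."""

    mu_ep: float = 0.25
    mu_lp: float = 0.75
    mu_keratin: float = 1.30
    mu_inclusion: float = 0.08
    mu_follicle_core: float = 0.30


@dataclass(frozen=True)
class Attenuation:
    """Single-pass intensity decay per micrometre of optical path."""

    ep: float = 0.0008
    lp: float = 0.0015


@dataclass(frozen=True)
class SurfaceFeatureSpec:
    """Statistical description of one kind of surface feature.

    kind: 'ridge' (convex, surface raised), 'crypt' (concave pit) or
    'lesion' (small concave notch with a local intensity dropout).
    diameter_um / amplitude_um: uniform sampling ranges.
    rate_per_mm: expected count per mm of lateral field (Poisson).
    """

    kind: str
    diameter_um: tuple[float, float]
    amplitude_um: tuple[float, float] = (50.0, 50.0)
    rate_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ridge", "crypt", "lesion"):
            raise ValueError(f"unknown surface feature kind {self.kind!r}")


@dataclass(frozen=True)
class TissueProfile:
    """Generating parameters of one investigation-area phantom."""

    region_id: str
    thickness_mean_geom: float
    thickness_sd_geom: float
    refractive_index: float = 1.37
    keratinized: bool = False
    surface_features: tuple[SurfaceFeatureSpec, ...] = ()
    vessel_density_target: float = 0.0
    gland_rate: float = 0.0       # per mm
    follicle_rate: float = 0.0    # per mm
    reflectivity: Reflectivity = field(default_factory=Reflectivity)
    attenuation: Attenuation = field(default_factory=Attenuation)
    noise_floor: float = 0.02
    speckle: bool = True
    surface_standoff_um: float = 150.0   # air gap above the tissue (OPL)
    surface_jitter_sd_rows: float = 3.0  # per-B-scan rigid offset SD
    thickness_by_sex: dict | None = None  # optional {'male': (mean, sd), ...}

    def __post_init__(self) -> None:
        r = self.reflectivity
        if not (r.mu_lp > r.mu_ep > r.mu_inclusion >= 0):
            raise ValueError("reflectivity must satisfy mu_lp > mu_ep > mu_inclusion >= 0")
        if self.keratinized and not r.mu_keratin > r.mu_lp:
            raise ValueError("keratinized profiles need mu_keratin > mu_lp")
        if self.vessel_density_target < 0:
            raise ValueError("vessel_density_target must be >= 0")
        if not self.thickness_mean_geom > 0:
            raise ValueError("thickness_mean_geom must be > 0")

    def to_dict(self) -> dict:
        d: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Reflectivity) or isinstance(v, Attenuation):
                v = vars(v).copy()
            elif isinstance(v, tuple) and v and isinstance(v[0], SurfaceFeatureSpec):
                v = [dict(kind=s.kind, diameter_um=list(s.diameter_um),
                          amplitude_um=list(s.amplitude_um),
                          rate_per_mm=s.rate_per_mm) for s in v]
            d[f.name] = v
        return d


@dataclass
class PlacedFeature:
    """One realized surface feature in a rendered B-scan."""

    kind: str
    center_col: int
    diameter_um: float
    amplitude_um: float


@dataclass
class PhantomTruth:
    """Ground truth of one rendered B-scan."""

    surface_trace: np.ndarray           # row index per column
    bm_trace: np.ndarray                # row index per column
    masks: dict                         # label -> bool image
    true_thickness_geom: np.ndarray     # um per column
    features: list                      # list[PlacedFeature]
    params: dict                        # profile dict, geometry dict, seed
    vessel_ratio_achieved: float = 0.0
    vessel_status: str = "ok"           # 'ok' | 'saturated'

    @property
    def geometry(self) -> ScanGeometry:
        return ScanGeometry.from_dict(self.params["geometry"])

    def epithelial_band_area_px(self) -> int:
        """Pixel area of the epithelial band, rows [surface, bm) per column."""
        return int(np.sum(self.bm_trace - self.surface_trace))

    def lesion_count(self) -> int:
        return sum(1 for f in self.features if f.kind == "lesion")


# ---------------------------------------------------------------------------
# region presets
#
# Thickness means/SDs are the published regional reference values (geometric
# um).  Feature and component rates are chosen so that the Poisson presence
# probabilities match the published percentage distributions over a 2.4 mm
# field.  The tonsil preset lowers the lamina propria reflectivity to give
# the weak epithelium/lamina contrast that makes its basement membrane
# read as 'unsharp'.
# ---------------------------------------------------------------------------

REGION_PRESETS: dict[str, dict] = {
    "labial": dict(
        thickness_mean_geom=243.0, thickness_sd_geom=25.0,
        vessel_density_target=0.39, gland_rate=0.18,
    ),
    "alveolar": dict(
        thickness_mean_geom=142.0, thickness_sd_geom=15.0,
        vessel_density_target=0.41, gland_rate=0.27,
    ),
    "buccal": dict(
        thickness_mean_geom=336.0, thickness_sd_geom=25.0,
        vessel_density_target=0.21,
        surface_features=(
            SurfaceFeatureSpec("lesion", (80.0, 140.0), (25.0, 35.0), rate_per_mm=0.20),
            SurfaceFeatureSpec("ridge", (280.0, 400.0), (45.0, 55.0), rate_per_mm=0.064),
        ),
    ),
    "sublingual": dict(
        thickness_mean_geom=120.0, thickness_sd_geom=15.0,
        vessel_density_target=0.82,
    ),
    "hard_palate": dict(
        thickness_mean_geom=198.0, thickness_sd_geom=26.0,
        keratinized=True, vessel_density_target=0.0, gland_rate=0.07,
        surface_features=(
            SurfaceFeatureSpec("lesion", (80.0, 140.0), (25.0, 35.0), rate_per_mm=0.60),
            SurfaceFeatureSpec("ridge", (280.0, 450.0), (45.0, 55.0), rate_per_mm=0.20),
        ),
        thickness_by_sex={"male": (218.0, 19.0), "female": (175.0, 11.0)},
    ),
    "soft_palate_oropharynx": dict(
        thickness_mean_geom=130.0, thickness_sd_geom=11.0,
        vessel_density_target=0.34, gland_rate=0.39,
    ),
    "tonsil": dict(
        thickness_mean_geom=125.0, thickness_sd_geom=17.0,
        vessel_density_target=0.19, follicle_rate=0.83,
        surface_features=(
            SurfaceFeatureSpec("crypt", (250.0, 350.0), (45.0, 55.0), rate_per_mm=0.87),
        ),
        reflectivity=Reflectivity(mu_lp=0.33),
    ),
}


def build_profile(region_id: str, overrides: dict | None = None) -> TissueProfile:
    """Preset :class:`TissueProfile` for one of the seven investigation areas.

    ``overrides`` replaces any profile field verbatim (e.g.
    ``{"thickness_mean_geom": 500}``); unknown keys raise ``ValueError``.
    """
    if region_id not in REGION_PRESETS:
        raise ValueError(
            f"unknown region {region_id!r}; expected one of {sorted(REGION_PRESETS)}")
    profile = TissueProfile(region_id=region_id, **REGION_PRESETS[region_id])
    if overrides:
        valid = {f.name for f in fields(TissueProfile)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown TissueProfile fields in overrides: {sorted(unknown)}")
        profile = replace(profile, **overrides)
    return profile


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _feature_delta_rows(n_columns: int, center_col: float, diameter_um: float,
                        amplitude_rows: float, lateral_pixel: float) -> np.ndarray:
    """Flat-topped excursion profile (rows, >=0) with short cosine shoulders."""
    cols = np.arange(n_columns, dtype=float)
    x = np.abs(cols - center_col) * lateral_pixel       # um from center
    half = diameter_um / 2.0
    edge = min(FEATURE_EDGE_UM, half / 2.0)
    delta = np.zeros(n_columns)
    plateau = x <= half - edge
    shoulder = (x > half - edge) & (x <= half)
    delta[plateau] = amplitude_rows
    delta[shoulder] = amplitude_rows * 0.5 * (
        1.0 + np.cos(np.pi * (x[shoulder] - (half - edge)) / edge))
    return delta


def _sample_features(profile: TissueProfile, geometry: ScanGeometry,
                     rng: np.random.Generator) -> list[PlacedFeature]:
    width_mm = geometry.fast_field_um / 1000.0
    placed: list[PlacedFeature] = []
    intervals: list[tuple[float, float]] = []   # occupied lateral spans, um
    for spec in profile.surface_features:
        count = rng.poisson(spec.rate_per_mm * width_mm)
        for _ in range(count):
            diameter = rng.uniform(*spec.diameter_um)
            amplitude = rng.uniform(*spec.amplitude_um)
            margin = diameter / 2.0 / geometry.lateral_pixel_fast + 2
            # features do not stack laterally (folds/crypts/lesions are
            # disjoint structures); resample the position on collision
            for _attempt in range(30):
                center = rng.uniform(margin, geometry.n_columns - margin)
                c_um = center * geometry.lateral_pixel_fast
                half = diameter / 2.0 + FEATURE_EDGE_UM
                if all(c_um + half < lo or c_um - half > hi for lo, hi in intervals):
                    intervals.append((c_um - half, c_um + half))
                    placed.append(PlacedFeature(spec.kind, int(round(center)),
                                                diameter, amplitude))
                    break
    return placed


def _place_inclusions(kind: str, rate_per_mm: float, occupied: np.ndarray,
                      bm_trace: np.ndarray, geometry: ScanGeometry,
                      rng: np.random.Generator) -> tuple[np.ndarray, list]:
    """Poisson-place gland/follicle ellipses in the lamina propria."""
    mask = np.zeros(geometry.shape, dtype=bool)
    centers: list[tuple[int, int, float, float]] = []
    width_mm = geometry.fast_field_um / 1000.0
    count = rng.poisson(rate_per_mm * width_mm)
    bm_max = int(bm_trace.max())
    for _ in range(count):
        for _attempt in range(50):
            b = rng.uniform(15, 30)                    # lateral semi-axis, px
            a = b * 1.2                                # axial semi-axis, px
            # glands and follicles cluster close below the membrane, which
            # also keeps them above the SNR-limited imaging depth
            lo = bm_max + a + _INCLUSION_CLEARANCE_ROWS
            hi = min(geometry.n_rows - a - 2, lo + 140)
            if hi <= lo:
                break
            r0 = rng.uniform(lo, hi)
            c0 = rng.uniform(b + 2, geometry.n_columns - b - 2)
            rr, cc = _draw_ellipse(r0, c0, a, b, shape=geometry.shape)
            if rr.size == 0 or occupied[rr, cc].any():
                continue
            if (rr <= bm_trace[cc] + _INCLUSION_CLEARANCE_ROWS).any():
                continue
            mask[rr, cc] = True
            occupied[rr, cc] = True
            centers.append((int(round(r0)), int(round(c0)), a, b))
            break
    return mask, centers


def _place_vessels_into(masks: dict, surface_trace: np.ndarray, bm_trace: np.ndarray,
                        target_ratio: float, geometry: ScanGeometry,
                        rng: np.random.Generator) -> tuple[float, str]:
    """Add elliptic vessel lumina to ``masks['vessel']`` until the summed
    luminal area reaches ``target_ratio`` of the epithelial band area
    (within +/- 0.01), or the lamina propria saturates."""
    if target_ratio < 0:
        raise ValueError("target_ratio must be >= 0")
    epith_area = float(np.sum(bm_trace - surface_trace))
    if epith_area <= 0:
        raise ValueError("epithelial band is empty; cannot place vessels")
    vessel = masks["vessel"]
    occupied = masks["gland"] | masks["follicle"] | vessel
    target_px = target_ratio * epith_area
    tol_px = 0.01 * epith_area
    failures = 0
    while True:
        deficit = target_px - vessel.sum()
        if deficit <= tol_px:
            status = "ok"
            break
        if failures > 4000:
            status = "saturated"
            break
        # vessel lumina stay below gland/follicle scale (<= ~100 um across)
        b = float(np.clip(np.sqrt(deficit / (np.pi * 0.8)), 2.0, 10.0))
        a = max(2.0, 0.8 * b)
        r0 = rng.uniform(float(bm_trace.min()) + a + _INCLUSION_CLEARANCE_ROWS,
                         geometry.n_rows - a - 1)
        c0 = rng.uniform(b + 1, geometry.n_columns - b - 1)
        rr, cc = _draw_ellipse(r0, c0, a, b, shape=geometry.shape)
        if rr.size == 0:
            failures += 1
            continue
        # lumen must sit fully in the lamina propria, clear of the band and
        # of other inclusions (with spacing, so neighbouring lumina stay
        # resolvable as separate structures)
        rr_sp, cc_sp = _draw_ellipse(r0, c0, a + 5, b + 5, shape=geometry.shape)
        if (rr <= bm_trace[np.clip(cc, 0, geometry.n_columns - 1)]
                + _INCLUSION_CLEARANCE_ROWS).any() \
                or rr.max() >= geometry.n_rows - 1 or occupied[rr_sp, cc_sp].any():
            failures += 1
            continue
        vessel[rr, cc] = True
        occupied[rr, cc] = True
        failures = 0
    achieved = float(vessel.sum() / epith_area)
    if status == "saturated":
        warnings.warn(
            f"vessel target ratio {target_ratio:.3f} unreachable; achieved {achieved:.3f}",
            RuntimeWarning, stacklevel=2)
    return achieved, status


def place_vessels(truth: PhantomTruth, target_ratio: float, seed: int) -> PhantomTruth:
    """Return a copy of ``truth`` with vessel lumina re-placed to ``target_ratio``.

    The summed luminal pixel area relative to the epithelial band area lands
    within +/-0.01 of the target unless the lamina propria saturates first, in
    which case a ``RuntimeWarning`` is issued and ``vessel_status`` is set to
    ``'saturated'`` with the achieved ratio recorded.
    """
    out = copy.deepcopy(truth)
    out.masks["vessel"] = np.zeros_like(out.masks["vessel"])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    achieved, status = _place_vessels_into(
        out.masks, out.surface_trace, out.bm_trace, target_ratio,
        out.geometry, rng)
    out.vessel_ratio_achieved = achieved
    out.vessel_status = status
    return out


def _render_with_rng(profile: TissueProfile, geometry: ScanGeometry,
                     rng: np.random.Generator, seed_record,
                     surface_offset_rows: float = 0.0,
                     thickness_geom: float | None = None) -> tuple[BScan, PhantomTruth]:
    n_rows, n_cols = geometry.shape
    n = profile.refractive_index
    if thickness_geom is None:
        thickness_geom = profile.thickness_mean_geom
    band_rows = int(round(geometry.um_geometric_to_rows(thickness_geom, n)))
    if band_rows < 2:
        raise ValueError(f"epithelium of {thickness_geom} um spans fewer than 2 rows")
    base_row = int(round(profile.surface_standoff_um / geometry.axial_pixel
                         + surface_offset_rows))
    base_row = max(base_row, 4)
    if base_row + band_rows + _BOTTOM_MARGIN_ROWS >= n_rows:
        raise ValueError(
            f"requested epithelial thickness {thickness_geom} um ({band_rows} rows) "
            f"does not fit below row {base_row} in a {n_rows}-row image")

    features = _sample_features(profile, geometry, rng)
    surface = np.full(n_cols, float(base_row))
    for f in features:
        amp_rows = f.amplitude_um / geometry.axial_pixel   # displacement in air
        delta = _feature_delta_rows(n_cols, f.center_col, f.diameter_um,
                                    amp_rows, geometry.lateral_pixel_fast)
        if f.kind == "ridge":
            surface -= delta
        else:                                              # crypt or lesion: concave
            surface += delta
    surface = np.clip(np.round(surface), 2, n_rows - _BOTTOM_MARGIN_ROWS - 2).astype(np.int64)
    bm = np.full(n_cols, base_row + band_rows, dtype=np.int64)
    bm = np.maximum(bm, surface + 1)

    masks = {k: np.zeros(geometry.shape, dtype=bool) for k in MASK_LABELS}
    rows = np.arange(n_rows)[:, None]
    band = (rows >= surface[None, :]) & (rows < bm[None, :])

    if profile.keratinized:
        k_rows = max(3, int(round(0.15 * band_rows)))
        masks["keratin"] = band & (rows < (surface + k_rows)[None, :])

    for f in features:
        if f.kind == "lesion":
            half_cols = f.diameter_um / 2.0 / geometry.lateral_pixel_fast
            lo = max(0, int(np.floor(f.center_col - half_cols)))
            hi = min(n_cols, int(np.ceil(f.center_col + half_cols)) + 1)
            lesion_cols = np.zeros(n_cols, dtype=bool)
            lesion_cols[lo:hi] = True
            masks["lesion"] |= band & lesion_cols[None, :]

    masks["gland"], _ = _place_inclusions(
        "gland", profile.gland_rate, masks["gland"].copy(), bm, geometry, rng)
    occupied = masks["gland"].copy()
    masks["follicle"], follicle_centers = _place_inclusions(
        "follicle", profile.follicle_rate, occupied, bm, geometry, rng)

    truth = PhantomTruth(
        surface_trace=surface, bm_trace=bm, masks=masks,
        true_thickness_geom=(bm - surface) * geometry.axial_pixel / n,
        features=features,
        params={"profile": profile.to_dict(), "geometry": geometry.to_dict(),
                "seed": seed_record},
    )
    if profile.vessel_density_target > 0:
        truth.vessel_ratio_achieved, truth.vessel_status = _place_vessels_into(
            masks, surface, bm, profile.vessel_density_target, geometry, rng)

    # --- paint the mean-reflectivity map --------------------------------
    refl = profile.reflectivity
    mean_map = np.zeros(geometry.shape)
    mean_map[rows >= bm[None, :]] = refl.mu_lp
    mean_map[band] = refl.mu_ep
    mean_map[masks["keratin"]] = refl.mu_keratin
    for m in ("vessel", "gland"):
        mean_map[masks[m]] = refl.mu_inclusion
    mean_map[masks["follicle"]] = refl.mu_inclusion
    for (r0, c0, a, b) in follicle_centers:                # brighter germinal centre
        rr, cc = _draw_ellipse(r0, c0, 0.45 * a, 0.45 * b, shape=geometry.shape)
        mean_map[rr, cc] = refl.mu_follicle_core
    # subtle local backscatter reduction under the notch; a lesion is a
    # surface defect, not a reflectivity anomaly of the deep epithelium
    mean_map[masks["lesion"]] *= 0.8

    att = profile.attenuation
    att_map = np.zeros(geometry.shape)
    att_map[band] = att.ep
    att_map[rows >= bm[None, :]] = att.lp
    transmission = np.exp(-np.cumsum(att_map * geometry.axial_pixel, axis=0))

    mean_map = mean_map * transmission + profile.noise_floor
    if profile.speckle:
        image = mean_map * rng.exponential(1.0, size=geometry.shape)
    else:
        image = mean_map
    return BScan(image, geometry), truth


def render_bscan(profile: TissueProfile, geometry: ScanGeometry | None = None,
                 seed: int = 0, *, surface_offset_rows: float = 0.0,
                 thickness_geom: float | None = None) -> tuple[BScan, PhantomTruth]:
    """Render one B-scan and its ground truth.  Deterministic for fixed seed."""
    geometry = geometry or ScanGeometry()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _render_with_rng(profile, geometry, rng, seed,
                            surface_offset_rows=surface_offset_rows,
                            thickness_geom=thickness_geom)


def render_series(profile: TissueProfile, geometry: ScanGeometry | None = None,
                  seed: int = 0, *, thickness_geom: float | None = None,
                  ) -> tuple[BScanSeries, list[PhantomTruth]]:
    """Render a series of B-scans of one (subject, measurement point).

    The subject's true epithelial thickness is drawn once per series from
    ``N(thickness_mean_geom, thickness_sd_geom)`` (or fixed via
    ``thickness_geom``); each B-scan then receives an independent rigid
    surface offset (Gaussian, ``surface_jitter_sd_rows``) emulating
    handheld acquisition.  Per-scan randomness flows through named
    sub-streams of ``seed``, so identical seeds give identical series.
    """
    geometry = geometry or ScanGeometry()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(geometry.series_length + 1)
    rng_series = np.random.default_rng(children[0])
    if thickness_geom is None:
        thickness_geom = float(max(
            30.0, rng_series.normal(profile.thickness_mean_geom, profile.thickness_sd_geom)))
    offsets = rng_series.normal(0.0, profile.surface_jitter_sd_rows,
                                size=geometry.series_length)
    images, truths = [], []
    for i in range(geometry.series_length):
        rng = np.random.default_rng(children[i + 1])
        bscan, truth = _render_with_rng(
            profile, geometry, rng, seed_record=(seed, i),
            surface_offset_rows=float(offsets[i]), thickness_geom=thickness_geom)
        images.append(bscan.image)
        truths.append(truth)
    return BScanSeries(np.stack(images), geometry), truths


def to_display_uint8(image: np.ndarray, floor_db: float = -40.0) -> np.ndarray:
    """Log-compressed 8-bit export for visualization only.

    Analysis always operates on the linear intensity; this transform maps
    ``floor_db`` .. 0 dB (relative to the image maximum) onto 0..255.
    """
    img = np.asarray(image, dtype=float)
    peak = img.max()
    if peak <= 0:
        return np.zeros(img.shape, dtype=np.uint8)
    db = 10.0 * np.log10(np.maximum(img, 1e-12) / peak)
    scaled = np.clip((db - floor_db) / (-floor_db), 0.0, 1.0)
    return np.round(scaled * 255).astype(np.uint8)
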