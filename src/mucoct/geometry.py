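"""Scan geometry and in-memory image containers.

An OCT B-scan is a 2-D array of backscattered intensity: rows are depth
(optical path length, OPL), columns are the lateral fast axis.  Row 0 is
the shallowest depth and rows increase downward.  Depth is measured in
OPL, so converting a pixel count to geometric tissue depth divides by the
refractive index of the medium (``opl / n``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanGeometry", "BScan", "BScanSeries"]

#: default refractive index of the oral epithelium at 840 nm
DEFAULT_REFRACTIVE_INDEX = 1.37


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel geometry of a B-scan series.

    Parameters
    ----------
    n_columns : int
        A-scans per B-scan (lateral fast axis).
    n_rows : int
        Axial pixel count.
    axial_pixel : float
        Optical path length per row in air, micrometres.
    lateral_pixel_fast, lateral_pixel_slow : float
        Lateral pixel pitch along the fast / slow scanning axis, micrometres.
    series_length : int
        B-scans per analysis series.
    nominal_field_um : tuple of float, optional
        The (fast, slow) field of view as printed on the acquisition
        protocol.  Kept verbatim; it is *not* required to equal the pixel
        count times the pitch (the slow axis of the reference protocol is
        nominally 0.6 mm although 64 x 10 um = 0.64 mm) and is never used
        in computation.
    """

    n_columns: int = 480
    n_rows: int = 512
    axial_pixel: float = 5.0
    lateral_pixel_fast: float = 5.0
    lateral_pixel_slow: float = 10.0
    series_length: int = 5
    nominal_field_um: tuple[float, float] | None = (2400.0, 600.0)

    def __post_init__(self) -> None:
        for name in ("n_columns", "n_rows", "axial_pixel",
                     "lateral_pixel_fast", "lateral_pixel_slow",
                     "series_length"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"ScanGeometry.{name} must be strictly positive, got {value!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_columns)

    @property
    def fast_field_um(self) -> float:
        """Lateral extent of one B-scan along the fast axis, micrometres."""
        return self.n_columns * self.lateral_pixel_fast

    @property
    def slow_field_um(self) -> float:
        """Extent covered by a 64-scan stack step along the slow axis equals
        ``n * lateral_pixel_slow`` for n scans; here per-scan pitch only."""
        return self.lateral_pixel_slow

    def um_geometric_to_rows(self, um: float, refractive_index: float) -> float:
        """Geometric tissue length (um) -> axial pixel count (OPL rows)."""
        return um * refractive_index / self.axial_pixel

    def rows_to_um_geometric(self, rows: float, refractive_index: float) -> float:
        """Axial pixel count (OPL rows) -> geometric tissue length (um)."""
        return rows * self.axial_pixel / refractive_index

    def to_dict(self) -> dict:
        return {
            "n_columns": self.n_columns,
            "n_rows": self.n_rows,
            "axial_pixel": self.axial_pixel,
            "lateral_pixel_fast": self.lateral_pixel_fast,
            "lateral_pixel_slow": self.lateral_pixel_slow,
            "series_length": self.series_length,
            "nominal_field_um": list(self.nominal_field_um) if self.nominal_field_um else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        nf = d.get("nominal_field_um")
        if nf is not None:
            d["nominal_field_um"] = tuple(nf)
        return cls(**d)


@dataclass
class BScan:
    """One calibrated cross-sectional intensity image."""

    image: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("BScan.image must be 2-D (rows x columns)")
        if self.image.shape != self.geometry.shape:
            raise ValueError(
                f"image shape {self.image.shape} does not match geometry {self.geometry.shape}")


@dataclass
class BScanSeries:
    """A series of B-scans from one measurement point (the unit of analysis)."""

    images: np.ndarray  # (series_length, n_rows, n_columns)
    geometry: ScanGeometry
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("BScanSeries.images must be 3-D (scan, rows, columns)")
        if self.images.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"page shape {self.images.shape[1:]} does not match geometry {self.geometry.shape}")

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> BScan:
        return BScan(self.images[i], self.geometry)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]
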