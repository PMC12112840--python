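"""Landmark detection and sagittal alignment parameters.

From the five C3–C7 vertebral polygons of one lateral radiograph this module
derives:

* vertebral body centroids (area-weighted, shoelace formula);
* the C3 inferior and C7 superior endplate lines, each anchored by the
  extreme boundary points of the leftmost and rightmost horizontal bands of
  the vertebral contour (band width 25% of the contour's x-extent by
  default);
* the posterosuperior corner of C7, which drops the vertical plumb line for
  the sagittal vertical axis (SVA).

The four parameters reported per radiograph:

``sva``
    Horizontal offset of the C3 centroid from the C7 posterosuperior plumb
    line; positive = anterior displacement.
``lordosis_deg``
    Cobb angle between the C3 inferior and C7 superior endplate lines;
    positive = lordotic.
``vertical_length``
    Absolute vertical distance between the C3 and C7 centroids.
``curved_length``
    Sum of Euclidean distances between consecutive C3→C7 centroids — a
    chord-length approximation of the cervical curve, hence always at least
    the straight C3–C7 distance.

All quantities are in image pixels; ``MeasurementConfig.pixel_spacing``
scales lengths to physical units when the detector geometry is known.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .annotation_io import (
    VERTEBRA_LABELS,
    AnnotationError,
    Contour,
    Point2D,
    RadiographAnnotation,
    extract_contour,
    rasterize_polygon,
    validate_annotation,
)

__all__ = [
    "LineSegment",
    "LandmarkSet",
    "AlignmentParameters",
    "MeasurementConfig",
    "MeasurementError",
    "polygon_centroid",
    "band_extreme_point",
    "endplate_line",
    "cobb_angle",
    "posterosuperior_point",
    "compute_sva",
    "compute_vertical_length",
    "compute_curved_length",
    "measure_radiograph",
]


class MeasurementError(ValueError):
    """Raised when a landmark or parameter cannot be computed."""


class LineSegment(NamedTuple):
    a: Point2D
    b: Point2D


@dataclass(frozen=True)
class AlignmentParameters:
    """The four per-radiograph sagittal alignment measurements."""

    sva: float
    lordosis_deg: float
    vertical_length: float
    curved_length: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sva, self.lordosis_deg, self.vertical_length, self.curved_length)


@dataclass(frozen=True)
class LandmarkSet:
    """Intermediate landmarks extracted before parameter computation."""

    centroids: dict[str, Point2D]
    c3_inferior_endplate: LineSegment
    c7_superior_endplate: LineSegment
    c7_posterosuperior: Point2D


@dataclass(frozen=True)
class MeasurementConfig:
    """Measurement conventions.

    anterior_side
        Which image side the patient faces; fixes the sign of SVA and
        lordosis and which band of the C7 contour is posterior.
    band_fraction
        Width of the horizontal contour bands used for endplate and corner
        detection, as a fraction of the contour's x-extent (in (0, 0.5]).
    contour_source
        ``polygon_direct`` uses the annotation vertices as the contour
        (exact); ``raster`` reproduces the mask → boundary-trace pipeline.
    pixel_spacing
        Physical size of one pixel; multiplies sva and both lengths.
    """

    anterior_side: Literal["left", "right"] = "right"
    band_fraction: float = 0.25
    contour_source: Literal["polygon_direct", "raster"] = "polygon_direct"
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.band_fraction <= 0.5):
            raise ValueError("band_fraction must lie in (0, 0.5]")
        if self.anterior_side not in ("left", "right"):
            raise ValueError("anterior_side must be 'left' or 'right'")
        if self.contour_source not in ("polygon_direct", "raster"):
            raise ValueError("contour_source must be 'polygon_direct' or 'raster'")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def sign(self) -> float:
        """+1 when anterior is image-right, -1 when image-left."""
        return 1.0 if self.anterior_side == "right" else -1.0


# ---------------------------------------------------------------------------
# Elementary landmark operations
# ---------------------------------------------------------------------------


def polygon_centroid(polygon: Sequence[Point2D] | np.ndarray) -> Point2D:
    """Area-weighted centroid of a simple polygon (shoelace formula).

    Independent of vertex orientation and of which vertex starts the ring.
    """
    arr = np.asarray(polygon, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise MeasurementError("polygon must have at least 3 vertices")
    x, y = arr[:, 0], arr[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = cross.sum()  # twice the signed area
    if abs(area2) < 1e-12:
        raise MeasurementError("degenerate polygon: zero enclosed area")
    cx = ((x + xn) * cross).sum() / (3.0 * area2)
    cy = ((y + yn) * cross).sum() / (3.0 * area2)
    return Point2D(float(cx), float(cy))


def band_extreme_point(
    contour: Contour,
    band: Literal["leftmost", "rightmost"],
    extreme: Literal["lowest", "highest"],
    band_fraction: float = 0.25,
) -> Point2D:
    """Extreme contour point within a horizontal band of the contour.

    The band spans ``band_fraction`` of the contour's x-extent from the left
    (or right) edge. "lowest" means maximum y (image convention, y grows
    downward), "highest" minimum y. Ties are broken by smaller x, then by
    earlier position along the contour.
    """
    pts = contour.points_array()
    if pts.shape[0] < 3:
        raise MeasurementError("contour must have at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    x_min, x_max = x.min(), x.max()
    width = x_max - x_min
    if band == "leftmost":
        in_band = x <= x_min + band_fraction * width
    elif band == "rightmost":
        in_band = x >= x_max - band_fraction * width
    else:
        raise ValueError(f"unknown band {band!r}")
    idx = np.nonzero(in_band)[0]
    if idx.size == 0:  # unreachable: the extreme-x point always qualifies
        raise MeasurementError("empty contour band")
    yb = y[idx]
    key = yb if extreme == "highest" else -yb
    best = np.min(key)
    tied = idx[np.abs(key - best) == 0]
    tied = tied[x[tied] == x[tied].min()]
    i = int(tied.min())
    return Point2D(float(x[i]), float(y[i]))


def endplate_line(
    contour: Contour,
    kind: Literal["c3_inferior", "c7_superior"],
    cfg: MeasurementConfig = MeasurementConfig(),
) -> LineSegment:
    """Endplate tangent line anchored by both horizontal-band extreme points.

    ``c3_inferior`` joins the lowest points of the leftmost and rightmost
    bands; ``c7_superior`` the highest points. Degenerate (coincident
    endpoints) raises.
    """
    extreme = "lowest" if kind == "c3_inferior" else "highest"
    a = band_extreme_point(contour, "leftmost", extreme, cfg.band_fraction)
    b = band_extreme_point(contour, "rightmost", extreme, cfg.band_fraction)
    if a == b:
        raise MeasurementError(f"degenerate {kind} endplate: coincident anchor points")
    return LineSegment(a, b)


def _line_angle_deg(seg: LineSegment) -> float:
    """Direction angle of the undirected line through seg, in (-90, 90]."""
    dx = seg.b.x - seg.a.x
    dy = seg.b.y - seg.a.y
    ang = math.degrees(math.atan2(dy, dx))
    while ang > 90.0:
        ang -= 180.0
    while ang <= -90.0:
        ang += 180.0
    return ang


def cobb_angle(
    c3_inferior: LineSegment,
    c7_superior: LineSegment,
    cfg: MeasurementConfig = MeasurementConfig(),
) -> float:
    """Signed Cobb angle between the two endplate lines, in (-90, 90] degrees.

    Sign convention: positive = lordotic, i.e. the endplate lines diverge
    toward the anterior side. With anterior on image-right this is
    angle(C7 superior) - angle(C3 inferior), angles measured with y down.
    """
    diff = _line_angle_deg(c7_superior) - _line_angle_deg(c3_inferior)
    while diff > 90.0:
        diff -= 180.0
    while diff <= -90.0:
        diff += 180.0
    return cfg.sign * diff


def posterosuperior_point(
    c7_contour: Contour, cfg: MeasurementConfig = MeasurementConfig()
) -> Point2D:
    """Posterosuperior corner of C7: highest point of the posterior band."""
    posterior_band = "leftmost" if cfg.anterior_side == "right" else "rightmost"
    return band_extreme_point(c7_contour, posterior_band, "highest", cfg.band_fraction)


def compute_sva(
    c3_centroid: Point2D, c7_posterosuperior: Point2D, cfg: MeasurementConfig = MeasurementConfig()
) -> float:
    """Signed horizontal offset of the C3 centroid from the C7 plumb line."""
    return cfg.sign * (c3_centroid.x - c7_posterosuperior.x)


def compute_vertical_length(c3_centroid: Point2D, c7_centroid: Point2D) -> float:
    """Absolute vertical displacement between the C3 and C7 centroids."""
    return abs(c3_centroid.y - c7_centroid.y)


def compute_curved_length(centroids: Sequence[Point2D]) -> float:
    """Sum of Euclidean distances between consecutive C3→C7 centroids."""
    if len(centroids) != 5:
        raise MeasurementError(
            f"need exactly 5 centroids (C3..C7), got {len(centroids)}"
        )
    arr = np.asarray(centroids, dtype=float)
    return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# Full-radiograph measurement
# ---------------------------------------------------------------------------


def _contour_for(
    annotation: RadiographAnnotation, label: str, cfg: MeasurementConfig
) -> Contour:
    poly = annotation.vertebrae[label].polygon
    if cfg.contour_source == "polygon_direct":
        return Contour(points=tuple(poly))
    mask = rasterize_polygon(poly, annotation.image_width, annotation.image_height)
    return extract_contour(mask)


def measure_radiograph(
    annotation: RadiographAnnotation, cfg: MeasurementConfig = MeasurementConfig()
) -> tuple[LandmarkSet, AlignmentParameters]:
    """Extract all landmarks and the four alignment parameters.

    The record must pass :func:`cervimorph.annotation_io.validate_annotation`;
    issues are reported in the raised error. Centroids always come from the
    polygon centroid formula; endplate and corner detection follows
    ``cfg.contour_source``. Deterministic for a fixed configuration.
    """
    issues = validate_annotation(annotation)
    if issues:
        raise MeasurementError(
            f"record {annotation.image_id!r} is not measurable: {', '.join(issues)}"
        )
    try:
        centroids = {
            label: polygon_centroid(annotation.vertebrae[label].polygon)
            for label in VERTEBRA_LABELS
        }
        c3_contour = _contour_for(annotation, "C3", cfg)
        c7_contour = _contour_for(annotation, "C7", cfg)
        c3_inf = endplate_line(c3_contour, "c3_inferior", cfg)
        c7_sup = endplate_line(c7_contour, "c7_superior", cfg)
        c7_ps = posterosuperior_point(c7_contour, cfg)
    except (MeasurementError, AnnotationError) as exc:
        raise MeasurementError(f"record {annotation.image_id!r}: {exc}") from exc

    landmarks = LandmarkSet(
        centroids=centroids,
        c3_inferior_endplate=c3_inf,
        c7_superior_endplate=c7_sup,
        c7_posterosuperior=c7_ps,
    )
    lordosis = cobb_angle(c3_inf, c7_sup, cfg)
    if abs(lordosis) > 90.0:  # unreachable given the (-90, 90] wrap; defensive
        warnings.warn(f"implausible lordosis {lordosis:.1f} deg", stacklevel=2)
    s = cfg.pixel_spacing
    params = AlignmentParameters(
        sva=s * compute_sva(centroids["C3"], c7_ps, cfg),
        lordosis_deg=lordosis,
        vertical_length=s * compute_vertical_length(centroids["C3"], centroids["C7"]),
        curved_length=s
        * compute_curved_length([centroids[label] for label in VERTEBRA_LABELS]),
    )
    return landmarks, params
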