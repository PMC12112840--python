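"""Reading, validating and rasterizing polygon vertebral annotations.

The native annotation format is a JSON document holding, for each lateral
cervical radiograph, one labelled polygon outline per vertebral body C3–C7
in image pixel coordinates (x rightward, y downward, origin top-left)::

    {"images": [{"image_id": "...", "width": 1024, "height": 1024,
                 "vertebrae": {"C3": [[x, y], ...], ..., "C7": [[x, y], ...]}}]}

Measurement operators can work either directly on the polygon vertices or on
a rasterized binary mask followed by boundary tracing; both paths start here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "VERTEBRA_LABELS",
    "Point2D",
    "VertebraAnnotation",
    "RadiographAnnotation",
    "BinaryMask",
    "Contour",
    "AnnotationError",
    "load_annotations",
    "save_annotations",
    "validate_annotation",
    "rasterize_polygon",
    "extract_contour",
    "write_parameters_table",
    "read_parameters_table",
]

#: Vertebral body labels used throughout, in cranio-caudal order.
VERTEBRA_LABELS: tuple[str, ...] = ("C3", "C4", "C5", "C6", "C7")

PARAMETER_COLUMNS = ("sva", "lordosis_deg", "vertical_length", "curved_length")


class Point2D(NamedTuple):
    """Image-plane point in pixel units; x grows rightward, y downward."""

    x: float
    y: float


@dataclass(frozen=True)
class VertebraAnnotation:
    """A labelled simple polygon outlining one vertebral body."""

    label: str
    polygon: tuple[Point2D, ...]

    def polygon_array(self) -> np.ndarray:
        return np.asarray(self.polygon, dtype=float)


@dataclass
class RadiographAnnotation:
    """All vertebral polygons of one lateral radiograph."""

    image_id: str
    image_width: int
    image_height: int
    vertebrae: dict[str, VertebraAnnotation]


@dataclass
class BinaryMask:
    """Boolean raster; ``pixels[row, col]`` is True for foreground cells."""

    width: int
    height: int
    pixels: np.ndarray

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Contour:
    """Ordered closed boundary; the last point connects back to the first."""

    points: tuple[Point2D, ...]

    def points_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid geometry."""


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def _parse_polygon(label: str, raw: object, image_id: str) -> VertebraAnnotation:
    if not isinstance(raw, (list, tuple)) or len(raw) < 3:
        raise AnnotationError(
            f"record {image_id!r}: polygon for {label} must be a list of >=3 [x, y] pairs"
        )
    pts = []
    for vertex in raw:
        if not isinstance(vertex, (list, tuple)) or len(vertex) != 2:
            raise AnnotationError(
                f"record {image_id!r}: vertex {vertex!r} of {label} is not an [x, y] pair"
            )
        x, y = float(vertex[0]), float(vertex[1])
        if not (np.isfinite(x) and np.isfinite(y)):
            raise AnnotationError(f"record {image_id!r}: non-finite vertex in {label}")
        pts.append(Point2D(x, y))
    return VertebraAnnotation(label=label, polygon=tuple(pts))


def load_annotations(path: str | Path) -> list[RadiographAnnotation]:
    """Load radiograph annotations from a native-format JSON file.

    Vertebra labels are normalised to upper case; unknown or duplicate labels
    raise :class:`AnnotationError`. Completeness (all five labels present,
    polygons simple, vertices in-bounds) is *not* enforced here — use
    :func:`validate_annotation` so that incomplete records can be reported
    and skipped rather than aborting a cohort load.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "images" not in doc:
        raise AnnotationError(f"{path}: expected a top-level object with an 'images' list")
    records: list[RadiographAnnotation] = []
    for i, item in enumerate(doc["images"]):
        image_id = str(item.get("image_id", f"record_{i}"))
        for key in ("width", "height", "vertebrae"):
            if key not in item:
                raise AnnotationError(f"record {image_id!r}: missing field {key!r}")
        vertebrae: dict[str, VertebraAnnotation] = {}
        for raw_label, raw_poly in item["vertebrae"].items():
            label = str(raw_label).strip().upper()
            if label not in VERTEBRA_LABELS:
                raise AnnotationError(
                    f"record {image_id!r}: unknown vertebra label {raw_label!r}"
                )
            if label in vertebrae:
                raise AnnotationError(f"record {image_id!r}: duplicate label {label}")
            vertebrae[label] = _parse_polygon(label, raw_poly, image_id)
        records.append(
            RadiographAnnotation(
                image_id=image_id,
                image_width=int(item["width"]),
                image_height=int(item["height"]),
                vertebrae=vertebrae,
            )
        )
    return records


def save_annotations(records: Iterable[RadiographAnnotation], path: str | Path) -> None:
    """Write records to the native JSON format (inverse of :func:`load_annotations`)."""
    images = []
    for rec in records:
        images.append(
            {
                "image_id": rec.image_id,
                "width": rec.image_width,
                "height": rec.image_height,
                "vertebrae": {
                    label: [[p.x, p.y] for p in ann.polygon]
                    for label, ann in rec.vertebrae.items()
                },
            }
        )
    Path(path).write_text(json.dumps({"images": images}, indent=1))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_annotation(a: RadiographAnnotation) -> list[str]:
    """Return a list of issue codes; empty means the record is measurable.

    Codes: ``MISSING_LABEL(Cx)``, ``DEGENERATE_POLYGON(Cx)`` (fewer than 3
    vertices or zero enclosed area), ``NON_SIMPLE_POLYGON(Cx)``
    (self-intersecting outline), ``OUT_OF_BOUNDS(Cx)`` (vertex outside the
    image frame). Pure: the same record always yields the same list.
    """
    issues: list[str] = []
    for label in VERTEBRA_LABELS:
        if label not in a.vertebrae:
            issues.append(f"MISSING_LABEL({label})")
            continue
        poly = a.vertebrae[label].polygon
        if len(poly) < 3:
            issues.append(f"DEGENERATE_POLYGON({label})")
            continue
        sp = ShapelyPolygon(poly)
        if not sp.is_valid:
            issues.append(f"NON_SIMPLE_POLYGON({label})")
            continue
        if sp.area <= 0.0:
            issues.append(f"DEGENERATE_POLYGON({label})")
            continue
        arr = np.asarray(poly, dtype=float)
        if (
            arr[:, 0].min() < 0
            or arr[:, 1].min() < 0
            or arr[:, 0].max() > a.image_width
            or arr[:, 1].max() > a.image_height
        ):
            issues.append(f"OUT_OF_BOUNDS({label})")
    return issues


# ---------------------------------------------------------------------------
# Rasterization and boundary tracing
# ---------------------------------------------------------------------------


def rasterize_polygon(
    polygon: Sequence[Point2D] | np.ndarray, width: int, height: int
) -> BinaryMask:
    """Rasterize a simple polygon to a binary mask.

    Pixel model: cell (col i, row j) is foreground iff its centre
    (i + 0.5, j + 0.5) lies inside or on the polygon boundary (even-odd
    rule; boundary ties count as inside). A 10x10 axis-aligned square with
    corners (0,0)-(10,10) therefore covers exactly 100 cells.
    """
    arr = np.asarray(polygon, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise AnnotationError("polygon must have at least 3 vertices")
    sp = ShapelyPolygon(arr)
    if not sp.is_valid or sp.area <= 0.0:
        raise AnnotationError("cannot rasterize a degenerate or self-intersecting polygon")
    pixels = np.zeros((height, width), dtype=bool)
    # only pixel centres within the polygon bounding box can be foreground
    minx, miny, maxx, maxy = sp.bounds
    i0 = max(int(np.floor(minx - 0.5)), 0)
    i1 = min(int(np.ceil(maxx + 0.5)), width)
    j0 = max(int(np.floor(miny - 0.5)), 0)
    j1 = min(int(np.ceil(maxy + 0.5)), height)
    if i0 >= i1 or j0 >= j1:
        raise AnnotationError("polygon lies entirely outside the image frame")
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1))
    inside = shapely.intersects_xy(sp, ii.ravel() + 0.5, jj.ravel() + 0.5)
    pixels[jj.ravel()[inside], ii.ravel()[inside]] = True
    if not pixels.any():
        raise AnnotationError("rasterization produced an empty mask")
    return BinaryMask(width=width, height=height, pixels=pixels)


_MOORE_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def extract_contour(mask: BinaryMask) -> Contour:
    """Trace the closed outer boundary of a single connected component.

    Moore-neighbour tracing (8-connectivity) starting from the top-most,
    left-most foreground cell; contour points are the centres of boundary
    cells in trace order. A single-pixel mask yields a one-point contour
    (flagged with a warning).
    """
    if not mask.pixels.any():
        raise AnnotationError("cannot trace an empty mask")
    labeled, n_components = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n_components > 1:
        raise AnnotationError(
            f"mask has {n_components} connected components; expected exactly one"
        )
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 1:
        warnings.warn("single-pixel mask: degenerate one-point contour", stacklevel=2)
        return Contour(points=(Point2D(cols[0] + 0.5, rows[0] + 0.5),))

    fg = mask.pixels

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < mask.height and 0 <= c < mask.width and fg[r, c]

    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    boundary: list[tuple[int, int]] = [start]
    # entered the start cell moving rightward, so backtrack points left
    prev_dir = 6  # index of (0, -1) in _MOORE_OFFSETS
    current = start
    while True:
        found = False
        # scan clockwise starting just past the backtrack direction
        for step in range(1, 9):
            d = (prev_dir + step) % 8
            dr, dc = _MOORE_OFFSETS[d]
            r, c = current[0] + dr, current[1] + dc
            if is_fg(r, c):
                current = (r, c)
                prev_dir = (d + 4) % 8  # direction pointing back where we came from
                found = True
                break
        if not found:  # isolated pixel already handled above; defensive
            break
        if current == start:
            break
        boundary.append(current)
    return Contour(points=tuple(Point2D(c + 0.5, r + 0.5) for r, c in boundary))


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------


def write_parameters_table(rows: Sequence[tuple[str, object]], path: str | Path) -> None:
    """Write (image_id, AlignmentParameters) rows to CSV.

    Columns: ``image_id,sva,lordosis_deg,vertical_length,curved_length``.
    """
    if len(rows) == 0:
        raise ValueError("refusing to write an empty parameters table")
    data = {
        "image_id": [image_id for image_id, _ in rows],
        **{
            col: [getattr(params, col) for _, params in rows]
            for col in PARAMETER_COLUMNS
        },
    }
    pd.DataFrame(data).to_csv(path, index=False)


def read_parameters_table(path: str | Path) -> pd.DataFrame:
    """Read a parameters CSV back into a DataFrame indexed by image_id."""
    df = pd.read_csv(path)
    missing = [c for c in ("image_id", *PARAMETER_COLUMNS) if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    return df
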