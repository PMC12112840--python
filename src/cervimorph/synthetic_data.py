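"""Synthetic inputs for the phenotyping pipeline.

Two generators stand in for the access-restricted clinical dataset:

1. **Parameter cohorts** — per-cluster independent Gaussians over the four
   alignment parameters, defaulting to the published three-cluster profile
   (sizes 703/387/228 with the printed mean ± SD per cell). These feed the
   clustering and statistics stages.

2. **Spine phantoms** — five rectangular vertebral "bodies" (C3–C7) placed
   along a polyline with prescribed tilts, built so that the four alignment
   parameters of the construction are known in closed form. Consecutive
   body tilts differ by lordosis/4, making the C3 inferior and C7 superior
   endplate lines subtend exactly the configured Cobb angle, and the
   horizontal centroid chain is sheared so the configured SVA holds
   exactly. Rectangles (rather than anatomical silhouettes) keep the
   endplate anchors and posterosuperior corner exact, which is what makes
   them usable as measurement ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    VERTEBRA_LABELS,
    Point2D,
    RadiographAnnotation,
    VertebraAnnotation,
    save_annotations,
)
from .geometry import AlignmentParameters

__all__ = [
    "PARAMETERS",
    "ClusterSpec",
    "SyntheticCohortConfig",
    "SimulatedCohort",
    "SpineGeometryConfig",
    "table1_config",
    "simulate_cohort",
    "generate_spine_annotation",
    "cohort_parameter_sampler",
    "generate_cohort_annotations",
]

PARAMETERS = ("sva", "lordosis_deg", "vertical_length", "curved_length")


@dataclass(frozen=True)
class ClusterSpec:
    """Size and per-parameter (mean, sd) of one generating cluster."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cluster size must be >= 2")
        for p in PARAMETERS:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"missing parameter {p!r} in cluster spec")
            if self.sds[p] <= 0:
                raise ValueError(f"sd for {p!r} must be positive")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    clusters: tuple[ClusterSpec, ...]
    seed: int = 0


@dataclass
class SimulatedCohort:
    """Shuffled cohort draw with its generating labels (1-based)."""

    params: pd.DataFrame
    labels: np.ndarray
    permutation: np.ndarray
    config: SyntheticCohortConfig


# Published three-cluster profile: (mean, sd) per parameter, sizes 703/387/228.
_TABLE1_CLUSTERS = (
    (703, {"sva": (95.9, 60.2), "lordosis_deg": (8.3, 4.7),
           "vertical_length": (457.7, 53.8), "curved_length": (550.6, 67.0)}),
    (387, {"sva": (70.6, 50.2), "lordosis_deg": (24.1, 6.8),
           "vertical_length": (465.5, 56.0), "curved_length": (559.8, 74.8)}),
    (228, {"sva": (135.6, 76.7), "lordosis_deg": (13.9, 9.4),
           "vertical_length": (648.0, 95.1), "curved_length": (841.5, 151.3)}),
)


def table1_config(seed: int = 0) -> SyntheticCohortConfig:
    """Cohort config pre-filled with the published per-cluster profile.

    Cluster 1: forward-head (low lordosis), cluster 2: normal (highest
    lordosis), cluster 3: long-neck (longest, most anterior). Total n = 1318.
    """
    clusters = tuple(
        ClusterSpec(
            n=n,
            means={p: ms[0] for p, ms in cells.items()},
            sds={p: ms[1] for p, ms in cells.items()},
        )
        for n, cells in _TABLE1_CLUSTERS
    )
    return SyntheticCohortConfig(clusters=clusters, seed=seed)


def simulate_cohort(cfg: SyntheticCohortConfig) -> SimulatedCohort:
    """Draw a cohort of independent per-cluster Gaussians.

    Parameters are drawn independently within each cluster (no printed
    correlation structure exists to emulate). Rows are shuffled with a
    recorded permutation; reproducible for a fixed config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks, labels = [], []
    for idx, spec in enumerate(cfg.clusters, start=1):
        cols = {
            p: rng.normal(spec.means[p], spec.sds[p], size=spec.n) for p in PARAMETERS
        }
        blocks.append(pd.DataFrame(cols))
        labels.append(np.full(spec.n, idx))
    X = pd.concat(blocks, ignore_index=True)
    y = np.concatenate(labels)
    perm = rng.permutation(len(X))
    return SimulatedCohort(
        params=X.iloc[perm].reset_index(drop=True),
        labels=y[perm],
        permutation=perm,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Spine phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineGeometryConfig:
    """Geometric spine phantom: tilted rectangular bodies along a polyline.

    ``lordosis_deg`` and ``sva`` always hold exactly in the construction.
    When ``vertical_length`` and ``curved_length`` are both given, the
    centroid chain is bent (two step directions) so those hold exactly too;
    otherwise the chain follows the tilt arc with centroid spacing
    ``segment_gap`` and the resulting lengths are reported in closed form.
    Units are pixels; anterior defaults to image-right.
    """

    lordosis_deg: float = 10.0
    sva: float = 50.0
    segment_gap: float = 120.0
    body_width: float = 60.0
    body_height: float = 40.0
    vertical_length: float | None = None
    curved_length: float | None = None
    image_width: int | None = None
    image_height: int | None = None
    anterior_side: str = "right"
    margin: float = 20.0
    jitter_px: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.lordosis_deg) >= 90.0:
            raise ValueError("|lordosis_deg| must be < 90")
        if min(self.segment_gap, self.body_width, self.body_height) <= 0:
            raise ValueError("gap and body dimensions must be positive")
        if (self.vertical_length is None) != (self.curved_length is None):
            raise ValueError("vertical_length and curved_length must be set together")
        if self.vertical_length is not None:
            if self.curved_length <= 0 or self.vertical_length < 0:
                raise ValueError("lengths must be positive")
            if self.vertical_length > self.curved_length:
                raise ValueError("vertical_length cannot exceed curved_length")
        if self.anterior_side not in ("left", "right"):
            raise ValueError("anterior_side must be 'left' or 'right'")


def _body_corners(center: np.ndarray, phi: float, w: float, h: float) -> np.ndarray:
    """Corners of a w x h rectangle tilted by phi about its centre.

    Order: top-left (posterosuperior), top-right, bottom-right, bottom-left
    in the body's local frame (y down).
    """
    local = np.array(
        [[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]]
    )
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    return center + local @ rot.T


def _check_band_separation(phi: float, w: float, h: float) -> None:
    # endplate anchors are only the exact rectangle corners if both corners
    # of each vertical edge fall inside the 25% horizontal band
    extent = w * math.cos(phi) + h * abs(math.sin(phi))
    if h * abs(math.sin(phi)) > 0.25 * extent:
        raise ValueError(
            "body tilt too steep for its aspect ratio: endplate corners leave "
            "the 25% detection band; widen body_width or reduce lordosis"
        )


def _centroid_steps(cfg: SpineGeometryConfig, phis: np.ndarray) -> np.ndarray:
    """Four (dx, dy) centroid steps realising the configured parameters."""
    w, h = cfg.body_width, cfg.body_height
    phi7 = phis[-1]
    # horizontal travel of the chain required for the configured SVA,
    # accounting for the posterosuperior-corner offset of C7
    sx = (w / 2) * math.cos(phi7) - (h / 2) * math.sin(phi7) - cfg.sva
    if cfg.curved_length is None:
        g = cfg.segment_gap
        mids = (phis[:-1] + phis[1:]) / 2.0
        steps = np.stack([g * np.sin(mids), g * np.cos(mids)], axis=1)
        steps[:, 0] += (sx - steps[:, 0].sum()) / 4.0  # shear to meet SVA
        return steps
    C, V = cfg.curved_length, cfg.vertical_length
    target = np.array([2.0 * sx / C, 2.0 * V / C])  # sum of two unit steps
    norm = np.linalg.norm(target)
    if norm > 2.0:
        raise ValueError(
            f"infeasible configuration: sva/vertical/curved require a chain of "
            f"length {math.hypot(sx, V):.1f} > curved_length {C:.1f}"
        )
    theta = math.atan2(target[0], target[1])  # from the +y (caudal) axis
    delta = math.acos(min(1.0, norm / 2.0))
    u1 = np.array([math.sin(theta - delta), math.cos(theta - delta)])
    u2 = np.array([math.sin(theta + delta), math.cos(theta + delta)])
    return np.stack([u1, u1, u2, u2]) * (C / 4.0)


def generate_spine_annotation(
    cfg: SpineGeometryConfig, image_id: str = "synthetic_spine"
) -> tuple[RadiographAnnotation, AlignmentParameters]:
    """Build one spine phantom and its closed-form ground truth.

    Body tilts run from -lordosis/2 (C3) to +lordosis/2 (C7) in equal
    steps, so the C3 inferior and C7 superior endplates subtend exactly the
    configured Cobb angle. With ``jitter_px`` > 0, vertex noise breaks the
    exactness of the ground truth by design (robustness fixtures only).
    """
    L = math.radians(cfg.lordosis_deg)
    phis = np.array([-L / 2 + i * L / 4 for i in range(5)])
    for phi in (phis[0], phis[-1]):
        _check_band_separation(phi, cfg.body_width, cfg.body_height)
    steps = _centroid_steps(cfg, phis)
    centers = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    corners = [
        _body_corners(centers[i], phis[i], cfg.body_width, cfg.body_height)
        for i in range(5)
    ]
    all_pts = np.vstack(corners)
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    extent = hi - lo
    if cfg.image_width is None:
        width = int(math.ceil(extent[0] + 2 * cfg.margin))
        height = int(math.ceil(extent[1] + 2 * cfg.margin))
        shift = cfg.margin - lo
    else:
        width, height = cfg.image_width, cfg.image_height
        if extent[0] + 2 * cfg.margin > width or extent[1] + 2 * cfg.margin > height:
            raise ValueError("spine does not fit in the configured image frame")
        shift = (np.array([width, height]) - extent) / 2.0 - lo

    rng = np.random.default_rng(cfg.seed) if cfg.jitter_px > 0 else None
    vertebrae: dict[str, VertebraAnnotation] = {}
    for label, quad in zip(VERTEBRA_LABELS, corners):
        pts = quad + shift
        if cfg.anterior_side == "left":
            pts = pts.copy()
            pts[:, 0] = width - pts[:, 0]
        if rng is not None:
            pts = pts + rng.uniform(-cfg.jitter_px, cfg.jitter_px, size=pts.shape)
        vertebrae[label] = VertebraAnnotation(
            label=label, polygon=tuple(Point2D(float(x), float(y)) for x, y in pts)
        )

    if cfg.curved_length is None:
        vertical = float(steps[:, 1].sum())
        curved = float(np.linalg.norm(steps, axis=1).sum())
    else:
        vertical, curved = cfg.vertical_length, cfg.curved_length
    truth = AlignmentParameters(
        sva=cfg.sva,
        lordosis_deg=cfg.lordosis_deg,
        vertical_length=vertical,
        curved_length=curved,
    )
    annotation = RadiographAnnotation(
        image_id=image_id, image_width=width, image_height=height, vertebrae=vertebrae
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# Cohorts of phantoms
# ---------------------------------------------------------------------------


def cohort_parameter_sampler(
    cfg: SyntheticCohortConfig,
) -> Callable[[np.random.Generator], tuple[float, float, float, float]]:
    """Sampler drawing one (sva, lordosis, vertical, curved) tuple per call.

    Cluster membership is drawn proportionally to the configured sizes.
    """
    sizes = np.array([c.n for c in cfg.clusters], dtype=float)
    probs = sizes / sizes.sum()

    def sample(rng: np.random.Generator) -> tuple[float, float, float, float]:
        spec = cfg.clusters[rng.choice(len(cfg.clusters), p=probs)]
        return tuple(rng.normal(spec.means[p], spec.sds[p]) for p in PARAMETERS)

    return sample


def generate_cohort_annotations(
    n: int,
    sampler: Callable[[np.random.Generator], tuple[float, float, float, float]],
    template: SpineGeometryConfig,
    seed: int = 0,
    path: str | Path | None = None,
    max_draws_per_record: int = 100,
) -> tuple[list[RadiographAnnotation], pd.DataFrame]:
    """Sample parameter tuples and emit one spine phantom per tuple.

    Each record's ground truth equals its sampled tuple, enabling full
    measure-and-recover closure tests. Tuples that no phantom can realise
    (vertical > curved, or an SVA/length combination needing a longer
    chain) are redrawn; the redraw count is capped per record. When
    ``path`` is given the annotations are written as native JSON and the
    ground truth alongside as ``<path stem>_truth.csv``.
    """
    rng = np.random.default_rng(seed)
    records: list[RadiographAnnotation] = []
    truth_rows = []
    for i in range(n):
        for _ in range(max_draws_per_record):
            sva, lordosis, vertical, curved = sampler(rng)
            try:
                cfg = replace(
                    template,
                    sva=float(sva),
                    lordosis_deg=float(lordosis),
                    vertical_length=float(vertical),
                    curved_length=float(curved),
                )
                rec, truth = generate_spine_annotation(cfg, image_id=f"spine_{i:05d}")
            except ValueError:
                continue
            break
        else:
            raise ValueError(
                f"no feasible phantom found for record {i} in "
                f"{max_draws_per_record} draws"
            )
        records.append(rec)
        truth_rows.append({"image_id": rec.image_id, **dict(zip(PARAMETERS, truth.as_tuple()))})
    truth_df = pd.DataFrame(truth_rows)
    if path is not None:
        path = Path(path)
        save_annotations(records, path)
        truth_df.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)
    return records, truth_df
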