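from __future__ import annotations

import numpy as np
import pytest

from cervimorph.annotation_io import (
    Point2D,
    RadiographAnnotation,
    VertebraAnnotation,
)
from cervimorph.synthetic_data import simulate_cohort, table1_config


def rectangle(x0: float, y0: float, w: float, h: float) -> tuple[Point2D, ...]:
    return (
        Point2D(x0, y0),
        Point2D(x0 + w, y0),
        Point2D(x0 + w, y0 + h),
        Point2D(x0, y0 + h),
    )


def stacked_rectangle_annotation(
    image_id: str = "stack", gap: float = 80.0, w: float = 60.0, h: float = 40.0
) -> RadiographAnnotation:
    """Five level rectangles stacked vertically: the simplest valid record."""
    labels = ("C3", "C4", "C5", "C6", "C7")
    vertebrae = {
        label: VertebraAnnotation(label=label, polygon=rectangle(100.0, 50.0 + i * gap, w, h))
        for i, label in enumerate(labels)
    }
    return RadiographAnnotation(
        image_id=image_id, image_width=400, image_height=600, vertebrae=vertebrae
    )


@pytest.fixture
def stack_annotation() -> RadiographAnnotation:
    return stacked_rectangle_annotation()


@pytest.fixture(scope="session")
def table1_cohort():
    """Canonical simulated cohort: published cluster structure, fixed seed."""
    return simulate_cohort(table1_config(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
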