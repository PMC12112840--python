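"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (ray casting, O(n^2) loops,
exhaustive partition enumeration) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def ray_cast_inside(polygon: np.ndarray, x: float, y: float) -> bool:
    """Even-odd point-in-polygon by horizontal ray casting; boundary counts in."""
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # point exactly on the edge segment counts as inside
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(
                y1, y2
            ) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_at > x:
                inside = not inside
    return inside


def segments_properly_intersect(p1, p2, p3, p4) -> bool:
    """True if open segments p1p2 and p3p4 cross at an interior point."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polygon_is_simple(polygon: np.ndarray) -> bool:
    """Check simplicity by testing all non-adjacent edge pairs."""
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j == i + 1) or (i == 0 and j == n - 1):
                continue
            if segments_properly_intersect(*edges[i], *edges[j]):
                return False
    return True


def brute_wcss(F: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = F[labels == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def brute_silhouette(F: np.ndarray, labels: np.ndarray) -> float:
    n = len(F)
    dist = np.sqrt(((F[:, None, :] - F[None, :, :]) ** 2).sum(axis=2))
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def brute_calinski_harabasz(F: np.ndarray, labels: np.ndarray) -> float:
    n, k = len(F), np.unique(labels).size
    grand = F.mean(axis=0)
    ssb = sum(
        (labels == c).sum() * ((F[labels == c].mean(axis=0) - grand) ** 2).sum()
        for c in np.unique(labels)
    )
    ssw = brute_wcss(F, labels)
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def brute_davies_bouldin(F: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    cents = np.stack([F[labels == c].mean(axis=0) for c in uniq])
    spread = np.array(
        [np.linalg.norm(F[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    total = 0.0
    for i in range(len(uniq)):
        total += max(
            (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(uniq))
            if j != i
        )
    return float(total / len(uniq))


def exhaustive_kmeans_optimum(F: np.ndarray, k: int) -> float:
    """Global minimum WCSS over all surjective assignments (tiny n only)."""
    n = len(F)
    best = np.inf
    for assignment in product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        best = min(best, brute_wcss(F, np.asarray(assignment)))
    return float(best)
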