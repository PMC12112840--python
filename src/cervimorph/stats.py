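"""Cluster-comparison statistics: summaries, one-way ANOVA, post hoc tests.

Two ANOVA entry points are provided. :func:`anova_oneway_raw` works from
per-observation data; :func:`anova_oneway_from_summary` computes the same
decomposition from per-group (n, mean, SD) triples via the algebraic
identities SSB = sum n_i (m_i - grand_mean)^2 and SSW = sum (n_i - 1) s_i^2,
so published summary tables can be audited without the underlying data.

Pairwise post hoc comparisons use two-sided t tests — Welch (unpooled
variances, Welch–Satterthwaite df; the default) or pooled (MSW-based SE with
n - k df) — with Bonferroni correction across the k(k-1)/2 pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ClusterSummary",
    "AnovaResult",
    "PairResult",
    "PosthocResult",
    "cluster_summary",
    "anova_oneway_raw",
    "anova_oneway_from_summary",
    "pairwise_posthoc",
    "build_table1",
    "write_comparison_table",
]

PARAMETER_COLUMNS = ("sva", "lordosis_deg", "vertical_length", "curved_length")


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample SD (ddof=1) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class ClusterSummary:
    """Per-cluster, per-parameter summaries of a measured cohort."""

    clusters: tuple[int, ...]
    parameters: tuple[str, ...]
    cells: dict[tuple[int, str], GroupSummary]

    @property
    def sizes(self) -> dict[int, int]:
        first = self.parameters[0]
        return {c: self.cells[(c, first)].n for c in self.clusters}

    def groups(self, parameter: str) -> list[GroupSummary]:
        """Summaries of one parameter, in cluster order."""
        return [self.cells[(c, parameter)] for c in self.clusters]

    def mean(self, cluster: int, parameter: str) -> float:
        return self.cells[(cluster, parameter)].mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for p in self.parameters:
                g = self.cells[(c, p)]
                rows.append({"cluster": c, "parameter": p, "n": g.n, "mean": g.mean, "sd": g.sd})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PairResult:
    i: int
    j: int
    t: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass
class PosthocResult:
    pairs: list[PairResult]
    variance_model: str
    correction: str = "bonferroni"

    def p_adjusted(self, i: int, j: int) -> float:
        for pr in self.pairs:
            if {pr.i, pr.j} == {i, j}:
                return pr.p_adjusted
        raise KeyError((i, j))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def cluster_summary(
    params: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    parameter_names: Sequence[str] | None = None,
) -> ClusterSummary:
    """Sample mean and SD (ddof=1) per cluster and parameter.

    Every cluster must contain at least two observations.
    """
    if isinstance(params, pd.DataFrame):
        names = tuple(params.columns)
        X = params.to_numpy(dtype=float)
    else:
        X = np.asarray(params, dtype=float)
        names = tuple(parameter_names) if parameter_names else tuple(
            PARAMETER_COLUMNS[: X.shape[1]]
        )
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels and rows must align")
    clusters = tuple(int(c) for c in np.unique(labels))
    cells: dict[tuple[int, str], GroupSummary] = {}
    for c in clusters:
        sub = X[labels == c]
        if sub.shape[0] < 2:
            raise ValueError(f"cluster {c} has fewer than 2 observations")
        for k, name in enumerate(names):
            cells[(c, name)] = GroupSummary(
                n=sub.shape[0],
                mean=float(sub[:, k].mean()),
                sd=float(sub[:, k].std(ddof=1)),
            )
    return ClusterSummary(clusters=clusters, parameters=names, cells=cells)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _anova_from_components(
    ssb: float, ssw: float, df_between: int, df_within: int
) -> AnovaResult:
    if df_between < 1 or df_within < 1:
        raise ValueError("ANOVA needs >=2 groups and residual degrees of freedom")
    if ssw <= 0.0:
        if ssb <= 1e-12:
            return AnovaResult(F=0.0, df_between=df_between, df_within=df_within, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_between, df_within=df_within, p=0.0)
    F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


def anova_oneway_raw(values: Sequence[float] | np.ndarray, labels: Sequence[int]) -> AnovaResult:
    """One-way fixed-effects ANOVA from per-observation values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == c] for c in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return _anova_from_components(
        float(ssb), float(ssw), len(groups) - 1, values.size - len(groups)
    )


def anova_oneway_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (n, mean, SD) triples.

    Algebraically identical to :func:`anova_oneway_raw` on any dataset with
    those group summaries.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    return _anova_from_components(ssb, ssw, len(groups) - 1, int(n_total) - len(groups))


# ---------------------------------------------------------------------------
# Post hoc pairwise tests
# ---------------------------------------------------------------------------


def _welch_pair(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se = math.sqrt(va + vb)
    if se == 0.0:
        raise ValueError("zero standard error: degenerate pair")
    t = (a.mean - b.mean) / se
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return t, df, 2.0 * float(sps.t.sf(abs(t), df))


def _pooled_pair(a: GroupSummary, b: GroupSummary, msw: float, df: int) -> tuple[float, float, float]:
    se = math.sqrt(msw * (1.0 / a.n + 1.0 / b.n))
    if se == 0.0:
        raise ValueError("zero standard error: degenerate pair")
    t = (a.mean - b.mean) / se
    return t, float(df), 2.0 * float(sps.t.sf(abs(t), df))


def pairwise_posthoc(
    groups: Sequence[GroupSummary],
    variance_model: Literal["welch", "pooled"] = "welch",
    correction: Literal["bonferroni"] = "bonferroni",
) -> PosthocResult:
    """All pairwise two-sided t tests with Bonferroni correction.

    ``welch`` uses per-group variances with Welch–Satterthwaite degrees of
    freedom; ``pooled`` uses the common within-group mean square with
    n - k degrees of freedom. Adjusted p = min(1, m * p) with m = number of
    pairs; groups are indexed 1..k in the order given.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    m = len(groups) * (len(groups) - 1) // 2
    if variance_model == "pooled":
        df_within = sum(g.n for g in groups) - len(groups)
        ssw = sum((g.n - 1) * g.sd**2 for g in groups)
        msw = ssw / df_within
    pairs: list[PairResult] = []
    for (i, a), (j, b) in combinations(enumerate(groups, start=1), 2):
        if variance_model == "welch":
            t, df, p = _welch_pair(a, b)
        elif variance_model == "pooled":
            t, df, p = _pooled_pair(a, b, msw, df_within)
        else:
            raise ValueError(f"unknown variance model {variance_model!r}")
        pairs.append(
            PairResult(i=i, j=j, t=t, df=df, p_raw=p, p_adjusted=min(1.0, m * p))
        )
    return PosthocResult(pairs=pairs, variance_model=variance_model)


# ---------------------------------------------------------------------------
# Full comparison table
# ---------------------------------------------------------------------------


def build_table1(
    params: pd.DataFrame,
    labels: Sequence[int],
    variance_model: Literal["welch", "pooled"] = "welch",
) -> pd.DataFrame:
    """Per-parameter cluster comparison: summaries, ANOVA F/p, pairwise p.

    One row per parameter; columns hold each cluster's "mean +/- sd (n)"
    inputs at full precision, the ANOVA F statistic and p value, and the
    Bonferroni-adjusted p for every cluster pair.
    """
    summary = cluster_summary(params, labels)
    rows = []
    for p_name in summary.parameters:
        groups = summary.groups(p_name)
        anova = anova_oneway_from_summary(groups)
        posthoc = pairwise_posthoc(groups, variance_model=variance_model)
        row: dict[str, object] = {"parameter": p_name}
        for c, g in zip(summary.clusters, groups):
            row[f"cluster{c}_n"] = g.n
            row[f"cluster{c}_mean"] = g.mean
            row[f"cluster{c}_sd"] = g.sd
        row["F"] = anova.F
        row["p"] = anova.p
        for pr in posthoc.pairs:
            row[f"p_{pr.i}_vs_{pr.j}"] = pr.p_adjusted
        rows.append(row)
    return pd.DataFrame(rows)


def _format_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.3f}"


def write_comparison_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the comparison table as CSV, rendering small p values as '<0.01'.

    Full-precision values should be kept via ``table.to_csv`` or JSON; this
    writer mirrors the display convention of published tables.
    """
    out = table.copy()
    for col in out.columns:
        if col == "p" or col.startswith("p_"):
            out[col] = out[col].map(_format_p)
    out.to_csv(path, index=False)
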