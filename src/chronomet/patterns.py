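"""Canonical temporal patterns and cross-group pattern-change accounting.

Cluster centroids are mapped onto a small library of canonical trajectory
shapes (rise-then-fall, fall-then-rise, monotone up/down, late rise) by
Pearson correlation; the best-correlated template names the cluster's
pattern. Core metabolites shared by two groups can then be compared: a
metabolite "changed pattern" when its cluster maps to different templates
in the two groups, and the membership delta quantifies how strongly its
cluster affiliation shifted even when the pattern is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .softcluster import ClusterResult, CoreSet


@dataclass(frozen=True)
class PatternTemplate:
    """A standardized (mean 0, sd 1) trajectory shape on the study's day grid."""

    pattern_id: int
    name: str
    values: np.ndarray  # over timepoints, z-scored

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if abs(v.mean()) > 1e-9 or abs(v.std(ddof=1) - 1.0) > 1e-9:
            raise ValueError(f"template {self.name!r} is not standardized")


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)


def archetype_templates(
    timepoints: Sequence[int],
    library: str = "default5",
    peak_day: int | None = 28,
) -> list[PatternTemplate]:
    """The default library of five canonical shapes on the given day grid.

    P1 rise-then-fall (peak at an interior day, default 28), P2 fall-then-
    rise (its mirror), P3 monotone up, P4 monotone down, P5 late rise (flat
    until the final recovery timepoint). Every template is z-scored.
    """
    days = np.asarray([int(d) for d in timepoints], dtype=float)
    if days.size < 3:
        raise ValueError("need at least 3 timepoints")
    if not np.all(np.diff(days) > 0):
        raise ValueError("timepoints must be strictly increasing")
    if library != "default5":
        raise ValueError(f"unknown template library {library!r}")
    if peak_day is None:
        peak_day = int(days[len(days) // 2])
    if not days[0] < peak_day < days[-1]:
        raise ValueError(f"peak_day {peak_day} must be interior to the day grid")

    first, last = days[0], days[-1]
    tent = np.where(
        days <= peak_day,
        (days - first) / (peak_day - first),
        (last - days) / (last - peak_day),
    )
    rise_fall = _zscore(tent)
    monotone_up = _zscore(days)
    late = np.zeros_like(days)
    late[-1] = 1.0
    return [
        PatternTemplate(1, "rise_then_fall", rise_fall),
        PatternTemplate(2, "fall_then_rise", -rise_fall),
        PatternTemplate(3, "monotone_up", monotone_up),
        PatternTemplate(4, "monotone_down", -monotone_up),
        PatternTemplate(5, "late_rise", _zscore(late)),
    ]


def assign_pattern(
    centroid: np.ndarray, templates: Sequence[PatternTemplate]
) -> tuple[int, str, float]:
    """Best-correlated template for one centroid.

    Returns (pattern_id, name, correlation); ties go to the lowest
    pattern_id. A zero-variance centroid has no defined correlation.
    """
    v = np.asarray(centroid, dtype=float)
    if v.std(ddof=1) == 0:
        raise ValueError("zero-variance centroid has no pattern correlation")
    if v.size != templates[0].values.size:
        raise ValueError("centroid length does not match the template grid")
    ordered = sorted(templates, key=lambda t: t.pattern_id)
    corrs = np.array([np.corrcoef(v, t.values)[0, 1] for t in ordered])
    best = int(np.argmax(corrs))  # argmax takes the first = lowest pattern_id
    return ordered[best].pattern_id, ordered[best].name, float(corrs[best])


def assign_cluster_patterns(
    result: ClusterResult, templates: Sequence[PatternTemplate]
) -> pd.DataFrame:
    """Pattern assignment for every cluster centroid of a clustering run."""
    rows = []
    for k in range(result.c):
        pid, name, corr = assign_pattern(result.centroids[k], templates)
        rows.append((k, pid, name, corr))
    return pd.DataFrame(
        rows, columns=["cluster", "pattern_id", "pattern_name", "correlation"]
    ).set_index("cluster")


@dataclass
class PatternChangeReport:
    """Core metabolites shared by two groups, with pattern-change flags."""

    table: pd.DataFrame
    group_x: str
    group_y: str

    @property
    def n_shared(self) -> int:
        return len(self.table)

    @property
    def n_changed(self) -> int:
        return int(self.table["pattern_changed"].sum()) if len(self.table) else 0


def compare_core_patterns(
    core_x: CoreSet,
    assign_x: pd.DataFrame,
    core_y: CoreSet,
    assign_y: pd.DataFrame,
    group_x: str = "X",
    group_y: str = "Y",
) -> PatternChangeReport:
    """Compare the temporal pattern of core metabolites shared by two groups.

    A metabolite changed pattern iff its cluster's template differs between
    the groups; the membership columns report how strongly it belonged to
    its cluster on each side ("cluster score").
    """
    tx = core_x.table.set_index("metabolite_name")
    ty = core_y.table.set_index("metabolite_name")
    shared = sorted(set(tx.index) & set(ty.index))
    if not shared:
        warnings.warn(f"no core metabolites shared between {group_x} and {group_y}")
    rows = []
    for met in shared:
        cx, cy = int(tx.loc[met, "cluster"]), int(ty.loc[met, "cluster"])
        px, py = int(assign_x.loc[cx, "pattern_id"]), int(assign_y.loc[cy, "pattern_id"])
        mx, my = float(tx.loc[met, "membership"]), float(ty.loc[met, "membership"])
        rows.append((met, cx, cy, px, py, mx, my, my - mx, px != py))
    table = pd.DataFrame(
        rows,
        columns=[
            "metabolite_name",
            f"cluster_{group_x}",
            f"cluster_{group_y}",
            f"pattern_{group_x}",
            f"pattern_{group_y}",
            f"membership_{group_x}",
            f"membership_{group_y}",
            "membership_delta",
            "pattern_changed",
        ],
    ).set_index("metabolite_name")
    return PatternChangeReport(table, group_x, group_y)
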