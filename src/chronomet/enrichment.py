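"""Over-representation analysis against a user-supplied pathway annotation.

The test is the one-sided hypergeometric tail: drawing n selected
metabolites from a universe of N, of which K belong to a pathway, the
pathway's p-value is P[X >= k] for the observed overlap k. Benjamini-
Hochberg q-values are reported alongside, but ranking is by raw p.
Compound-class composition summaries use the same annotation's class map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """Pathway membership and compound classes over a metabolite universe."""

    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, members)
    universe: frozenset[str]
    class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"pathway {pid!r} has members outside the universe: {sorted(stray)[:5]}"
                )


def read_annotation(
    annotation_path: str | Path,
    classes_path: str | Path | None = None,
    universe: set[str] | None = None,
) -> AnnotationMap:
    """Load annotation.tsv (metabolite_name, pathway_id, pathway_name) and an
    optional classes.tsv (metabolite_name, compound_class).

    When no explicit universe is given it is the union of annotated and
    classed metabolites.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"metabolite_name", "pathway_id", "pathway_name"}
    if missing := required - set(ann.columns):
        raise ValueError(f"{annotation_path}: missing columns {sorted(missing)}")
    class_map: dict[str, str] = {}
    if classes_path is not None:
        cls = pd.read_csv(classes_path, sep="\t", dtype=str)
        class_map = dict(zip(cls["metabolite_name"], cls["compound_class"]))
    if universe is None:
        universe = set(ann["metabolite_name"]) | set(class_map)
    pathways = {}
    for (pid, pname), sub in ann.groupby(["pathway_id", "pathway_name"], sort=True):
        members = frozenset(sub["metabolite_name"]) & set(universe)
        pathways[pid] = (pname, members)
    return AnnotationMap(pathways, frozenset(universe), class_map)


def hypergeom_enrich(
    selected: set[str],
    annotation: AnnotationMap,
    min_k: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each pathway.

    Selected metabolites outside the universe are dropped with a warning.
    Pathways overlapping fewer than ``min_k`` selected metabolites are
    omitted. Rows are sorted by ascending p, then pathway_id.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    stray = set(selected) - set(annotation.universe)
    if stray:
        warnings.warn(
            f"{len(stray)} selected metabolite(s) outside the universe dropped"
        )
    sel = set(selected) & set(annotation.universe)
    if not sel:
        raise ValueError("no selected metabolites inside the universe")
    n_universe = len(annotation.universe)
    n_sel = len(sel)
    rows = []
    for pid in sorted(annotation.pathways):
        pname, members = annotation.pathways[pid]
        k = len(sel & members)
        if k < min_k:
            continue
        p = float(hypergeom.sf(k - 1, n_universe, len(members), n_sel))
        rows.append((pid, pname, k, len(members), n_sel, n_universe, p))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "pathway_name", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out.set_index("pathway_id")


def class_composition(selected: set[str], annotation: AnnotationMap) -> pd.DataFrame:
    """Compound-class counts and fractions of a selected set, sorted by
    descending count; metabolites without a class are 'unclassified'."""
    if not selected:
        raise ValueError("selected set is empty")
    counts: dict[str, int] = {}
    for met in selected:
        cls = annotation.class_map.get(met, "unclassified")
        counts[cls] = counts.get(cls, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["compound_class", "count"],
    )
    out["fraction"] = out["count"] / out["count"].sum()
    return out.set_index("compound_class")
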