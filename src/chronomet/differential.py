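"""Paired end-vs-baseline differential statistics and set overlaps.

For each metabolite within a group, the late-timepoint intensity is compared
with the baseline of the same subject: the effect is the mean per-subject
log2 ratio and the p-value comes from a two-sided paired test on the log2
intensities (t-test by default, Wilcoxon signed-rank optionally). Two strict
screens follow: p < 0.05 for "changed", additionally |log2FC| > 1 for
"strongly changed" — the volcano-plot quadrants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MetaboliteMatrix


@dataclass
class DiffStats:
    """Per-metabolite paired statistics for one group."""

    table: pd.DataFrame  # index metabolite_name: log2fc, p_value, q_value, n_pairs
    group: str
    day_ref: int
    day_cmp: int


def paired_change(
    matrix: MetaboliteMatrix,
    group: str,
    day_ref: int = 0,
    day_cmp: int = 63,
    test: str = "t",
) -> DiffStats:
    """Paired day_cmp-vs-day_ref statistics for one group.

    Only subjects observed (non-missing) at both days contribute. log2fc is
    the mean per-subject log2(day_cmp / day_ref); the p-value is two-sided
    on the per-subject log2 differences. Metabolites with fewer than three
    complete pairs, or zero-variance differences, get a missing p-value.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    sheet = matrix.samples
    ref_rows = sheet.biological(group=group, day=day_ref)
    cmp_rows = sheet.biological(group=group, day=day_cmp)
    if ref_rows.empty or cmp_rows.empty:
        raise ValueError(
            f"group {group!r} lacks samples at day {day_ref} or {day_cmp}"
        )
    ref_by_subj = dict(zip(ref_rows["subject_id"], ref_rows.index))
    cmp_by_subj = dict(zip(cmp_rows["subject_id"], cmp_rows.index))
    subjects = sorted(set(ref_by_subj) & set(cmp_by_subj))
    ref = matrix.values[[ref_by_subj[s] for s in subjects]].to_numpy(dtype=float)
    cmp_ = matrix.values[[cmp_by_subj[s] for s in subjects]].to_numpy(dtype=float)

    diffs = np.log2(cmp_) - np.log2(ref)  # metabolite x subject
    rows = []
    for i, met in enumerate(matrix.metabolites):
        d = diffs[i][~np.isnan(diffs[i])]
        n = d.size
        lfc = float(d.mean()) if n else np.nan
        p = np.nan
        if n >= 3 and np.ptp(d) > 0:
            if test == "t":
                p = float(stats.ttest_1samp(d, 0.0).pvalue)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = float(stats.wilcoxon(d).pvalue)
        rows.append((met, lfc, p, n))
    out = pd.DataFrame(
        rows, columns=["metabolite_name", "log2fc", "p_value", "n_pairs"]
    ).set_index("metabolite_name")
    out["q_value"] = np.nan
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out = out[["log2fc", "p_value", "q_value", "n_pairs"]]
    return DiffStats(out, group, day_ref, day_cmp)


def classify_significant(
    stats_: DiffStats,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Two-stage screen: changed (p < p_thresh) and strongly changed
    (additionally |log2fc| > lfc_thresh). Both inequalities strict."""
    t = stats_.table
    changed = set(t.index[(t["p_value"] < p_thresh).fillna(False)])
    strong = {m for m in changed if abs(t.loc[m, "log2fc"]) > lfc_thresh}
    return changed, strong


def volcano_table(
    stats_: DiffStats,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Plot-ready classification of every metabolite."""
    changed, strong = classify_significant(stats_, p_thresh, lfc_thresh)
    t = stats_.table.copy()
    labels = []
    for m in t.index:
        if m in strong:
            labels.append("up_strong" if t.loc[m, "log2fc"] > 0 else "down_strong")
        elif m in changed:
            labels.append("changed")
        else:
            labels.append("ns")
    t["class"] = labels
    return t


def overlap_sets(sets: dict[str, set[str]]) -> dict[str, int]:
    """Exact Venn-region cardinalities for k >= 2 named sets.

    Keys are '&'-joined sorted member names of the exclusive region, e.g.
    "A&C" counts elements in A and C but no other set.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            counts["&".join(combo)] = len(inside - outside)
    return counts
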