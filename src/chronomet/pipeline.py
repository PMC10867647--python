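"""End-to-end orchestration of the analysis stages for one study.

Each ionization channel is analyzed independently: preprocessing, paired
differential statistics per group, soft temporal clustering per group with
pattern assignment and cross-group pattern-change accounting, mixed-model
trend classification with concordance selection, and enrichment of the
concordant set. All outputs are plain TSV/JSON with deterministic layout.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import differential, enrichment, lmm, patterns, preprocess, softcluster
from .datatypes import FeatureTable, ION_MODES, SampleSheet
from .io import write_table

log = logging.getLogger("chronomet")


def _mode_seed(seed: int, tag: str) -> int:
    ss = np.random.SeedSequence([int(seed), *(ord(ch) for ch in tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_json(obj: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_mode(
    table: FeatureTable,
    sheet: SampleSheet,
    ion_mode: str,
    out_dir: str | Path,
    config: dict,
    seed: int,
    annotation: enrichment.AnnotationMap | None = None,
) -> dict[str, Any]:
    """Run every analysis stage for one ionization channel.

    Returns a summary dict (counts per stage) that run_all aggregates.
    """
    out = Path(out_dir)
    groups = list(sheet.groups)
    summary: dict[str, Any] = {"ion_mode": ion_mode}

    # --- preprocess --------------------------------------------------------
    pcfg = config["preprocess"]
    matrix, qc = preprocess.preprocess_study(
        table,
        sheet,
        ion_mode=ion_mode,
        ms2_threshold=pcfg["ms2_threshold"],
        collapse=pcfg["collapse"],
        max_qc_cv=pcfg["max_qc_cv"],
    )
    write_table(matrix, out / "preprocess" / "metabolites.tsv")
    write_table(qc.to_frame(), out / "preprocess" / "qc_report.tsv")
    write_table(qc.pca_scores, out / "preprocess" / "pca_scores.tsv")
    summary["n_metabolites"] = len(matrix)

    # --- paired differential ------------------------------------------------
    dcfg = config["differential"]
    changed_sets: dict[str, set[str]] = {}
    strong_sets: dict[str, set[str]] = {}
    for group in groups:
        stats_ = differential.paired_change(
            matrix, group, day_ref=dcfg["day_ref"], day_cmp=dcfg["day_cmp"],
            test=dcfg["test"],
        )
        volcano = differential.volcano_table(
            stats_, p_thresh=dcfg["p_threshold"], lfc_thresh=dcfg["lfc_threshold"]
        )
        write_table(volcano, out / "differential" / f"volcano_{group}.tsv")
        changed_sets[group], strong_sets[group] = differential.classify_significant(
            stats_, p_thresh=dcfg["p_threshold"], lfc_thresh=dcfg["lfc_threshold"]
        )
    overlaps = {
        "changed": differential.overlap_sets(changed_sets),
        "strong": differential.overlap_sets(strong_sets),
    }
    _write_json(overlaps, out / "differential" / "overlaps.json")
    summary["n_changed"] = {g: len(s) for g, s in sorted(changed_sets.items())}
    summary["n_strong"] = {g: len(s) for g, s in sorted(strong_sets.items())}

    # --- soft clustering + patterns -----------------------------------------
    ccfg, ptcfg = config["cluster"], config["patterns"]
    templates = patterns.archetype_templates(
        sorted({int(d) for d in sheet.biological()["day"]}),
        library=ptcfg["library"],
        peak_day=ptcfg["peak_day"],
    )
    cores: dict[str, softcluster.CoreSet] = {}
    assigns: dict[str, pd.DataFrame] = {}
    summary["optimal_c"] = {}
    for group in groups:
        gdir = out / "cluster" / group
        profile = softcluster.standardize_profile(
            softcluster.timepoint_medians(matrix, group)
        )
        m = softcluster.estimate_fuzzifier(profile, ccfg["m"])
        gseed = _mode_seed(seed, f"{ion_mode}:{group}")
        c_max = min(int(ccfg["c_max"]), len(profile) - 1)
        curve = softcluster.dmin_curve(
            profile, c_max=c_max, c_min=int(ccfg["c_min"]), m=m,
            repeats=int(ccfg["repeats"]), seed=gseed,
            tol=float(ccfg["tol"]), max_iter=int(ccfg["max_iter"]),
        )
        if ccfg["c"] == "auto":
            chosen = softcluster.select_optimal_c(
                curve, delta=float(ccfg["delta"]), force_c=ccfg["force_c"]
            ).c
        else:
            chosen = int(ccfg["c"])
        result = softcluster.fuzzy_cmeans(
            profile, chosen, m=m, seed=gseed,
            tol=float(ccfg["tol"]), max_iter=int(ccfg["max_iter"]),
        )
        core = softcluster.core_members(result, ccfg["membership_threshold"])
        assign = patterns.assign_cluster_patterns(result, templates)
        cores[group], assigns[group] = core, assign
        summary["optimal_c"][group] = chosen

        dmin_df = pd.DataFrame(
            sorted(curve.dmin.items()), columns=["c", "dmin"]
        ).set_index("c")
        write_table(dmin_df, gdir / "dmin_curve.tsv")
        write_table(result.membership.rename(columns=lambda k: f"cluster_{k}"),
                    gdir / "membership.tsv")
        cent = pd.DataFrame(result.centroids, columns=profile.values.columns)
        cent.index.name = "cluster"
        write_table(cent, gdir / "centroids.tsv")
        write_table(core.table.set_index("metabolite_name"), gdir / "core.tsv")
        write_table(assign, gdir / "pattern_assignments.tsv")
        write_table(softcluster.heatmap_matrix(result, core, profile),
                    gdir / "heatmap_matrix.tsv")

    pattern_counts: dict[str, dict[str, int]] = {}
    for gx, gy in (("C", "A"), ("A", "AE")):
        if gx in cores and gy in cores:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = patterns.compare_core_patterns(
                    cores[gx], assigns[gx], cores[gy], assigns[gy], gx, gy
                )
            write_table(report.table, out / "patterns" / f"changes_{gx}_{gy}.tsv")
            pattern_counts[f"{gx}_vs_{gy}"] = {
                "n_shared": report.n_shared, "n_changed": report.n_changed
            }
    _write_json(pattern_counts, out / "patterns" / "counts.json")
    summary["pattern_changes"] = pattern_counts

    # --- mixed-model trends + concordance -----------------------------------
    lcfg = config["lmm"]
    classes: dict[str, pd.DataFrame] = {}
    all_fits = []
    for group in groups:
        fits = lmm.fit_trend_models(matrix, group)
        all_fits.append(lmm.fits_to_frame(fits))
        classes[group] = lmm.classify_trends(
            fits, alpha=lcfg["alpha"], select=lcfg["select"]
        )
    write_table(pd.concat(all_fits), out / "lmm" / "trend_fits.tsv")
    write_table(pd.concat(classes.values()), out / "lmm" / "trend_classes.tsv")
    concordant = lmm.concordance_select(classes, mode=lcfg["concordance"])
    write_table(concordant, out / "lmm" / "concordant.tsv")
    selected = set(concordant.index[concordant["selected"]])
    summary["n_concordant_selected"] = len(selected)

    # --- enrichment ----------------------------------------------------------
    if annotation is not None and selected:
        universe = frozenset(annotation.universe) & set(matrix.metabolites)
        ann = enrichment.AnnotationMap(
            {pid: (name, members & universe)
             for pid, (name, members) in annotation.pathways.items()},
            frozenset(universe),
            annotation.class_map,
        )
        sel_in = selected & set(universe)
        if sel_in:
            enr = enrichment.hypergeom_enrich(sel_in, ann, min_k=config["enrich"]["min_k"])
            write_table(enr, out / "enrich" / "enrichment.tsv")
            write_table(enrichment.class_composition(sel_in, ann),
                        out / "enrich" / "class_composition.tsv")
            summary["n_enriched_pathways"] = int((enr["p_value"] < 0.05).sum())
    return summary


def run_all(
    table: FeatureTable,
    sheet: SampleSheet,
    out_dir: str | Path,
    config: dict,
    seed: int,
    annotation: enrichment.AnnotationMap | None = None,
) -> dict[str, Any]:
    """Run the full pipeline for every ionization channel present."""
    out = Path(out_dir)
    modes = [m for m in ION_MODES if (sheet.df["ion_mode"] == m).any()]
    summaries = {}
    for mode in modes:
        log.info("analyzing ion mode %s", mode)
        summaries[mode] = run_mode(
            table, sheet, mode, out / mode, config, seed, annotation=annotation
        )
    _write_json(summaries, out / "summary.json")
    return summaries
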