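"""Synthetic longitudinal metabolomics studies with known ground truth.

The generator emulates the structure the pipeline assumes: three groups
(control C, induced aging A, aging plus exercise AE) of repeatedly sampled
subjects on a five-day grid, metabolites measured as strictly positive LC-MS
intensities in two ionization channels, duplicate features per metabolite
with MS2 identification scores straddling the 0.5 filter, pooled QC
injections, and subject-level attrition concentrated on day 63.

Log2 intensity of metabolite i in sample (group g, subject s, day d):

    y = baseline_i + effect_size * shape_ig(d) + b_is + e

with b_is ~ N(0, subject_sd^2) per metabolite x subject and
e ~ N(0, resid_sd^2); intensities are 2^y (lognormal noise). Trajectory
shapes come from the same canonical template library the pattern module
analyzes, so planted truth and analysis share one definition. Three kinds
of metabolite are planted: archetype metabolites following one template in
every group (cluster-recovery truth), concordant metabolites moving one way
in C and AE and the opposite way in A (concordance truth), and null
metabolites with no time effect (type-I truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, SampleSheet
from .io import write_table
from .patterns import archetype_templates

_CLASSES = (
    "amino acids and peptides",
    "fatty acid and conjugate",
    "pyridines",
    "TCA",
    "benzoic acid",
    "nucleosides",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the generator."""

    n_subjects_per_group: int = 15
    days: tuple[int, ...] = (0, 14, 28, 63, 91)
    groups: tuple[str, ...] = ("C", "A", "AE")
    #: template id -> number of metabolites following that shape in all groups
    n_per_archetype: Mapping[int, int] = field(
        default_factory=lambda: {1: 12, 2: 12, 3: 12, 4: 12, 5: 12}
    )
    n_null: int = 25
    n_concordant: int = 15
    effect_size: float = 1.0       # amplitude of the standardized shape, log2 units
    subject_sd: float = 0.3        # random-intercept sd, log2 units
    resid_sd: float = 0.3          # residual sd, log2 units
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    n_features_per_metabolite: int = 2
    ms2_primary_range: tuple[float, float] = (0.55, 0.95)
    ms2_secondary_range: tuple[float, float] = (0.05, 0.95)
    feature_offset_mean: float = -0.2  # secondary features sit below the primary
    feature_offset_sd: float = 0.1
    feature_jitter_sd: float = 0.05
    qc_n: int = 6
    qc_sd: float = 0.1
    day63_missing_frac: float = 0.10
    pos_fraction: float = 0.6      # share of metabolites detected in POS mode
    peak_day: int = 28
    seed: int = 42

    def validate(self) -> None:
        if min(self.subject_sd, self.resid_sd, self.baseline_log2_sd,
               self.feature_jitter_sd, self.qc_sd) <= 0:
            raise ValueError("all standard deviations must be positive")
        if not 0 <= self.day63_missing_frac < 1:
            raise ValueError("day63_missing_frac must be in [0, 1)")
        if not 0 <= self.pos_fraction <= 1:
            raise ValueError("pos_fraction must be in [0, 1]")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if len(self.days) < 3:
            raise ValueError("need at least 3 sampling days")
        if self.n_subjects_per_group < 1 or self.qc_n < 0:
            raise ValueError("invalid sample counts")
        if self.n_features_per_metabolite < 1:
            raise ValueError("need at least one feature per metabolite")
        if any(n < 0 for n in self.n_per_archetype.values()):
            raise ValueError("archetype counts must be non-negative")
        known = {t.pattern_id for t in archetype_templates(self.days, peak_day=self.peak_day)}
        if set(self.n_per_archetype) - known:
            raise ValueError(f"unknown archetype ids: {set(self.n_per_archetype) - known}")

    @property
    def n_metabolites(self) -> int:
        return sum(self.n_per_archetype.values()) + self.n_null + self.n_concordant


@dataclass
class SimTruth:
    """Ground truth emitted with every generated study."""

    metabolites: pd.DataFrame   # (metabolite, group): ion_mode, kind, archetype_id, direction
    missing_samples: list[str]  # sample_ids deleted by day-63 attrition
    seed: int

    def archetype_of(self, ion_mode: str, group: str) -> pd.Series:
        """metabolite -> planted archetype id (archetype metabolites only)."""
        t = self.metabolites
        sub = t[(t["ion_mode"] == ion_mode) & (t["group"] == group) & (t["kind"] == "archetype")]
        return sub.set_index("metabolite_name")["archetype_id"].astype(int)

    @property
    def concordant_set(self) -> set[str]:
        t = self.metabolites
        return set(t.loc[t["kind"] == "concordant", "metabolite_name"])


def generate_study(config: SimConfig) -> tuple[FeatureTable, SampleSheet, SimTruth]:
    """Generate one complete study: features, sample sheet, ground truth.

    Fully deterministic in ``config.seed``; intensities are strictly
    positive and the only missing cells are the ones the design implies
    (each feature is observed only in its own ionization channel).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days)
    templates = {
        t.pattern_id: t.values
        for t in archetype_templates(config.days, peak_day=config.peak_day)
    }
    up_id, down_id = 3, 4  # monotone templates define concordant directions

    # --- metabolite roster -------------------------------------------------
    # kind: archetype (same shape in every group) | concordant | null
    roster: list[dict] = []
    idx = 0
    for pid in sorted(config.n_per_archetype):
        for _ in range(config.n_per_archetype[pid]):
            roster.append({"name": f"met_{idx:04d}", "kind": "archetype", "pid": pid})
            idx += 1
    for j in range(config.n_concordant):
        direction = "up" if j % 2 == 0 else "down"
        roster.append({"name": f"met_{idx:04d}", "kind": "concordant", "dir": direction})
        idx += 1
    for _ in range(config.n_null):
        roster.append({"name": f"met_{idx:04d}", "kind": "null"})
        idx += 1
    for met in roster:
        met["mode"] = "POS" if rng.random() < config.pos_fraction else "NEG"

    # --- sample sheet ------------------------------------------------------
    sheet_rows = []
    bio_samples: dict[str, list[tuple[str, str, str, int]]] = {"POS": [], "NEG": []}
    for group in config.groups:
        for s in range(1, config.n_subjects_per_group + 1):
            subject = f"{group}{s:02d}"
            for day in config.days:
                for mode in ("POS", "NEG"):
                    sid = f"{subject}_d{day:03d}_{mode}"
                    sheet_rows.append((sid, subject, group, day, mode, False))
                    bio_samples[mode].append((sid, subject, group, int(day)))
    for mode in ("POS", "NEG"):
        for q in range(1, config.qc_n + 1):
            sheet_rows.append((f"QC{q:02d}_{mode}", None, None, None, mode, True))

    # --- day-63 attrition: whole blood draws vanish in both channels -------
    missing: list[str] = []
    if config.day63_missing_frac > 0 and 63 in config.days:
        for group in config.groups:
            for s in range(1, config.n_subjects_per_group + 1):
                if rng.random() < config.day63_missing_frac:
                    subject = f"{group}{s:02d}"
                    missing.extend(f"{subject}_d063_{m}" for m in ("POS", "NEG"))
    missing_set = set(missing)
    sheet_rows = [r for r in sheet_rows if r[0] not in missing_set]
    for mode in ("POS", "NEG"):
        bio_samples[mode] = [r for r in bio_samples[mode] if r[0] not in missing_set]

    sheet_df = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "subject_id", "group", "day", "ion_mode", "is_qc"],
    ).set_index("sample_id")
    sheet_df["day"] = sheet_df["day"].astype("Int64")
    sheet = SampleSheet(sheet_df, days=config.days, groups=config.groups)

    # --- intensities -------------------------------------------------------
    day_pos = {int(d): i for i, d in enumerate(days)}
    feature_rows: list[dict] = []
    truth_rows: list[tuple] = []
    for met in roster:
        mode = met["mode"]
        samples = bio_samples[mode]
        qc_ids = [f"QC{q:02d}_{mode}" for q in range(1, config.qc_n + 1)]
        baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)

        shapes: dict[str, np.ndarray] = {}
        for group in config.groups:
            if met["kind"] == "archetype":
                shapes[group] = templates[met["pid"]]
                truth_rows.append((met["name"], mode, group, "archetype", met["pid"],
                                   "none", False))
            elif met["kind"] == "concordant":
                planted_up = met["dir"] == "up"
                if group == "A":
                    pid = down_id if planted_up else up_id
                else:
                    pid = up_id if planted_up else down_id
                shapes[group] = templates[pid]
                direction = "up" if pid == up_id else "down"
                truth_rows.append((met["name"], mode, group, "concordant", pid,
                                   direction, True))
            else:
                shapes[group] = np.zeros(len(days))
                truth_rows.append((met["name"], mode, group, "null", None, "none", False))

        intercepts = {
            (g, s): rng.normal(0.0, config.subject_sd)
            for g in config.groups
            for s in range(1, config.n_subjects_per_group + 1)
        }
        signal = {}
        for sid, subject, group, day in samples:
            b = intercepts[(group, int(subject[len(group):]))]
            mu = (
                baseline
                + config.effect_size * shapes[group][day_pos[day]]
                + b
                + rng.normal(0.0, config.resid_sd)
            )
            signal[sid] = mu
        grand_mean = float(np.mean(list(signal.values())))
        for qid in qc_ids:
            signal[qid] = grand_mean + rng.normal(0.0, config.qc_sd)

        letters = "abcdefghij"
        for f in range(config.n_features_per_metabolite):
            fid = f"f_{met['name']}_{letters[f]}"
            if f == 0:
                ms2 = rng.uniform(*config.ms2_primary_range)
                offset = 0.0
            else:
                ms2 = rng.uniform(*config.ms2_secondary_range)
                offset = rng.normal(config.feature_offset_mean, config.feature_offset_sd)
            row = {"feature_id": fid, "metabolite_name": met["name"],
                   "ms2_score": round(float(ms2), 4)}
            for sid, mu in signal.items():
                row[sid] = float(2.0 ** (mu + offset + rng.normal(0.0, config.feature_jitter_sd)))
            feature_rows.append(row)

    feat_df = pd.DataFrame(feature_rows).set_index("feature_id")
    # column order: metadata, then sample-sheet order; absent-mode cells stay NaN
    feat_df = feat_df.reindex(
        columns=["metabolite_name", "ms2_score", *sheet.sample_ids]
    )
    table = FeatureTable(feat_df)
    truth = SimTruth(
        pd.DataFrame(
            truth_rows,
            columns=["metabolite_name", "ion_mode", "group", "kind",
                     "archetype_id", "direction", "is_concordant"],
        ),
        missing,
        config.seed,
    )
    return table, sheet, truth


# ---------------------------------------------------------------------------
# toy annotation


def build_annotation(truth: SimTruth, seed: int = 0, n_pathways: int = 12) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A packaged toy pathway annotation over the generated metabolite names.

    The first pathways oversample the planted concordant set so enrichment
    has signal to find; compound classes skew the concordant metabolites
    toward amino acids. Returns (annotation, classes) data frames.
    """
    rng = np.random.default_rng(seed)
    names = sorted(set(truth.metabolites["metabolite_name"]))
    concordant = sorted(truth.concordant_set)
    others = [n for n in names if n not in set(concordant)]

    ann_rows = []
    for p in range(1, n_pathways + 1):
        pid = f"pw{p:02d}"
        pname = f"pathway_{p:02d}"
        size = int(rng.integers(6, 16))
        if p <= 3 and concordant:
            n_conc = min(len(concordant), max(2, size // 2))
            members = list(rng.choice(concordant, size=n_conc, replace=False))
            members += list(rng.choice(others, size=max(0, size - n_conc), replace=False))
        else:
            members = list(rng.choice(names, size=min(size, len(names)), replace=False))
        for met in sorted(set(members)):
            ann_rows.append((met, pid, pname))
    annotation = pd.DataFrame(
        ann_rows, columns=["metabolite_name", "pathway_id", "pathway_name"]
    )

    cls_rows = []
    for name in names:
        if name in set(concordant) and rng.random() < 0.6:
            cls = _CLASSES[0]
        else:
            cls = _CLASSES[int(rng.integers(0, len(_CLASSES)))]
        cls_rows.append((name, cls))
    classes = pd.DataFrame(cls_rows, columns=["metabolite_name", "compound_class"])
    return annotation, classes


# ---------------------------------------------------------------------------
# fixtures

FIXTURES: dict[str, SimConfig] = {
    # <= 30 metabolites, small subject count: fast unit-test study
    "tiny": SimConfig(
        n_subjects_per_group=6,
        n_per_archetype={1: 4, 2: 4, 3: 4},
        n_null=6,
        n_concordant=6,
        qc_n=3,
    ),
    # the generator's defaults: the standard study conditions
    "default": SimConfig(),
    # no time effects anywhere: type-I error checks
    "null": SimConfig(
        n_subjects_per_group=10,
        n_per_archetype={},
        n_null=150,
        n_concordant=0,
    ),
}


def make_fixture(
    name: str,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[FeatureTable, SampleSheet, SimTruth, pd.DataFrame, pd.DataFrame]:
    """Generate a named study fixture, optionally writing it to disk.

    Writes features.tsv, samples.tsv, truth.tsv, missing_samples.tsv,
    annotation.tsv and classes.tsv when ``out_dir`` is given.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    config = FIXTURES[name]
    if seed is not None:
        config = replace(config, seed=int(seed))
    table, sheet, truth = generate_study(config)
    annotation, classes = build_annotation(truth, seed=config.seed)
    if out_dir is not None:
        out = Path(out_dir)
        write_table(table, out / "features.tsv")
        write_table(sheet, out / "samples.tsv")
        t = truth.metabolites.set_index("metabolite_name")
        write_table(t, out / "truth.tsv")
        write_table(
            pd.DataFrame({"sample_id": truth.missing_samples}).set_index("sample_id"),
            out / "missing_samples.tsv",
        )
        write_table(annotation.set_index("metabolite_name"), out / "annotation.tsv")
        write_table(classes.set_index("metabolite_name"), out / "classes.tsv")
    return table, sheet, truth, annotation, classes
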