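"""Feature-table preprocessing: identification filter, metabolite collapse, QC.

Positive- and negative-mode features are processed separately. Features are
first screened on their MS2 identification score (strictly greater than the
threshold; unscored features are treated as unidentified and dropped). When
several features map to the same metabolite name, the metabolite's value is
the highest feature value — by default per sample, optionally per feature.
Instrument stability is summarized from pooled QC injections via per-
metabolite coefficients of variation and a PCA score plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import FEATURE_META_COLS, FeatureTable, MetaboliteMatrix, SampleSheet


def split_ion_mode(table: FeatureTable, sheet: SampleSheet, ion_mode: str) -> tuple[FeatureTable, SampleSheet]:
    """Restrict a study to one ionization channel.

    Keeps the samples acquired in ``ion_mode`` (QC included) and the features
    with at least one intensity among them.
    """
    ids = [s for s in sheet.sample_ids if sheet.df.loc[s, "ion_mode"] == ion_mode]
    if not ids:
        raise ValueError(f"no samples with ion_mode={ion_mode!r}")
    return table.restrict_samples(ids), sheet.subset(ids)


def filter_ms2(table: FeatureTable, threshold: float = 0.5) -> FeatureTable:
    """Keep features whose MS2 score is strictly greater than ``threshold``.

    Features without a score are dropped; row order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep = table.df["ms2_score"] > threshold  # NaN compares False
    return FeatureTable(table.df[keep].copy())


def collapse_to_metabolites(
    table: FeatureTable,
    sheet: SampleSheet,
    method: str = "elementwise_max",
) -> MetaboliteMatrix:
    """Collapse duplicate features of a metabolite into a single row.

    ``elementwise_max``: per-sample maximum over the metabolite's features,
    ignoring missing cells (an all-missing cell stays missing).
    ``best_feature``: the feature with the highest mean intensity provides
    the whole row.
    """
    if len(table) == 0:
        raise ValueError("cannot collapse an empty feature table")
    inten = table.intensities
    names = table.df["metabolite_name"]
    order = list(dict.fromkeys(names))  # first-appearance order
    if method == "elementwise_max":
        collapsed = inten.groupby(names, sort=False).max()
    elif method == "best_feature":
        best = inten.mean(axis=1).groupby(names, sort=False).idxmax()
        collapsed = inten.loc[best]
        collapsed.index = best.index
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    collapsed = collapsed.loc[order]
    collapsed.index.name = "metabolite_name"
    return MetaboliteMatrix(collapsed, sheet.subset(collapsed.columns))


@dataclass
class QCReport:
    """Stability summary from pooled QC injections."""

    cv: pd.Series                      # per-metabolite sd/mean over QC samples
    pca_scores: pd.DataFrame           # sample x component
    explained_variance_ratio: np.ndarray
    n_qc: int
    failed_cv: list[str] = field(default_factory=list)  # metabolites over max_qc_cv

    def to_frame(self) -> pd.DataFrame:
        out = self.cv.rename("qc_cv").to_frame()
        out.index.name = "metabolite_name"
        return out


def qc_report(
    matrix: MetaboliteMatrix,
    n_components: int = 2,
    max_qc_cv: float | None = None,
) -> QCReport:
    """Per-metabolite QC coefficient of variation plus a PCA of all samples.

    CV uses the sample (n-1) standard deviation over complete QC cells. PCA
    runs on log2 intensities with each metabolite centered; metabolites with
    any missing value are excluded from the PCA.
    """
    qc_ids = matrix.samples.qc_ids()
    n_qc = len(qc_ids)
    if n_qc >= 2:
        qc = matrix.values[qc_ids]
        cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    else:
        warnings.warn(f"only {n_qc} QC sample(s); CV section left empty")
        cv = pd.Series(dtype=float, name="qc_cv")
        cv.index.name = "metabolite_name"

    vals = matrix.values
    if vals.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    complete = vals.dropna(axis=0)
    n_components = min(n_components, complete.shape[0], vals.shape[1])
    logged = np.log2(complete.to_numpy(dtype=float))
    centered = logged - logged.mean(axis=1, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered.T)  # samples x components
    pca_scores = pd.DataFrame(
        scores,
        index=pd.Index(vals.columns, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )

    failed = []
    if max_qc_cv is not None and len(cv):
        failed = sorted(cv.index[cv > max_qc_cv])
    return QCReport(cv, pca_scores, pca.explained_variance_ratio_, n_qc, failed)


def apply_cv_filter(matrix: MetaboliteMatrix, report: QCReport, max_qc_cv: float) -> MetaboliteMatrix:
    """Drop metabolites whose QC CV exceeds the cutoff (opt-in)."""
    bad = set(report.cv.index[report.cv > max_qc_cv])
    keep = [m for m in matrix.metabolites if m not in bad]
    return MetaboliteMatrix(matrix.values.loc[keep], matrix.samples)


def preprocess_study(
    table: FeatureTable,
    sheet: SampleSheet,
    ion_mode: str | None = None,
    ms2_threshold: float = 0.5,
    collapse: str = "elementwise_max",
    max_qc_cv: float | None = None,
) -> tuple[MetaboliteMatrix, QCReport]:
    """Full preprocessing for one ionization channel."""
    if ion_mode is not None:
        table, sheet = split_ion_mode(table, sheet, ion_mode)
    filtered = filter_ms2(table, ms2_threshold)
    if len(filtered) == 0:
        raise ValueError("no features survive the MS2 score filter")
    matrix = collapse_to_metabolites(filtered, sheet, method=collapse)
    report = qc_report(matrix, max_qc_cv=max_qc_cv)
    if max_qc_cv is not None and report.failed_cv:
        matrix = apply_cv_filter(matrix, report, max_qc_cv)
    return matrix, report
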