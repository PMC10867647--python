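"""Mixed-model trend screening over the full time course.

For each metabolite within a group, log2 intensity is modeled with a random
intercept per subject (repeated measures) and polynomial fixed effects of
scaled time t = day/max(day), centered:

    M0: y ~ 1            + (1 | subject)
    M1: y ~ 1 + t        + (1 | subject)
    M2: y ~ 1 + t + t^2  + (1 | subject)

Models are fit by maximum likelihood so nested fixed effects can be compared
with likelihood-ratio tests (chi-squared, 1 df each). A metabolite is
classified as quadratic ("model2", sign of the t^2 coefficient) when the
quadratic term is significant, otherwise linear ("model1", sign of the slope)
when the linear term is, otherwise unclassified. Metabolites whose direction
agrees between the control (C) and exercised-aging (AE) groups while the
untreated aging group (A) moves the opposite way are the concordant set fed
to enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .datatypes import MetaboliteMatrix

LABELS = ("model1_up", "model1_down", "model2_up", "model2_down", "none")

_FIT_METHODS = ("lbfgs", "bfgs", "powell", "nm")


@dataclass
class TrendFit:
    """Per-metabolite mixed-model summary for one group."""

    metabolite: str
    group: str
    beta_lin: float
    beta_quad: float
    p_lin: float
    p_quad: float
    aic_m0: float
    aic_m1: float
    aic_m2: float
    sigma_subject: float
    sigma_resid: float
    n_obs: int
    converged: bool


@dataclass
class TrendClass:
    metabolite: str
    group: str
    label: str      # one of LABELS
    direction: str  # "up" | "down" | "none"


def _fit_ml(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """ML MixedLM fit with an optimizer fallback chain; None if all fail."""
    for method in _FIT_METHODS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(y, x, groups=groups).fit(
                    reml=False, method=method, disp=False
                )
            if np.isfinite(res.llf):
                return res
        except Exception:
            continue
    return None


def _lrt_p(ll_full: float, ll_null: float, df: int = 1) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    return float(stats.chi2.sf(stat, df))


def fit_trend_models(matrix: MetaboliteMatrix, group: str) -> list[TrendFit]:
    """Fit the nested random-intercept models for every metabolite in a group.

    Missing samples (e.g. day-63 attrition) simply shorten the likelihood;
    no imputation. Metabolites observed on fewer than two distinct days are
    flagged unconverged and skipped.
    """
    bio = matrix.samples.biological(group=group)
    if bio.empty:
        raise ValueError(f"no biological samples for group {group!r}")
    days = bio["day"].astype(int).to_numpy()
    if len(set(days)) < 3:
        raise ValueError("trend models need at least 3 timepoints")
    if bio["subject_id"].nunique() < 4:
        raise ValueError("trend models need at least 4 subjects")
    sample_ids = list(bio.index)
    subj_codes = pd.Categorical(bio["subject_id"]).codes
    t_all = days / days.max()

    vals = matrix.values[sample_ids].to_numpy(dtype=float)
    fits: list[TrendFit] = []
    for i, met in enumerate(matrix.metabolites):
        row = vals[i]
        obs = ~np.isnan(row)
        y = np.log2(row[obs])
        t = t_all[obs]
        subj = subj_codes[obs]
        nan = float("nan")
        if len(np.unique(days[obs])) < 2:
            fits.append(
                TrendFit(met, group, nan, nan, nan, nan, nan, nan, nan, nan, nan,
                         int(obs.sum()), False)
            )
            continue
        tc = t - t.mean()
        ones = np.ones_like(tc)
        r0 = _fit_ml(y, ones[:, None], subj)
        r1 = _fit_ml(y, np.column_stack([ones, tc]), subj)
        r2 = _fit_ml(y, np.column_stack([ones, tc, tc**2]), subj)
        if r0 is None or r1 is None or r2 is None:
            fits.append(
                TrendFit(met, group, nan, nan, nan, nan, nan, nan, nan, nan, nan,
                         int(obs.sum()), False)
            )
            continue
        fits.append(
            TrendFit(
                metabolite=met,
                group=group,
                beta_lin=float(r1.params[1]),
                beta_quad=float(r2.params[2]),
                p_lin=_lrt_p(r1.llf, r0.llf),
                p_quad=_lrt_p(r2.llf, r1.llf),
                aic_m0=float(r0.aic),
                aic_m1=float(r1.aic),
                aic_m2=float(r2.aic),
                sigma_subject=float(np.sqrt(max(0.0, np.asarray(r2.cov_re)[0, 0]))),
                sigma_resid=float(np.sqrt(r2.scale)),
                n_obs=int(obs.sum()),
                converged=True,
            )
        )
    return fits


def classify_trend(fit: TrendFit, alpha: float = 0.05, select: str = "lrt") -> TrendClass:
    """Four-way trend label for one fitted metabolite.

    ``lrt``: quadratic wins when p_quad < alpha, else linear when
    p_lin < alpha, else none. ``aic``: the polynomial order with the lowest
    AIC wins, still gated on its LRT p-value. Direction is the sign of the
    winning order's coefficient.
    """
    if not fit.converged:
        warnings.warn(f"{fit.metabolite}: unconverged fit classified as none")
        return TrendClass(fit.metabolite, fit.group, "none", "none")
    if select not in ("lrt", "aic"):
        raise ValueError(f"unknown selection rule {select!r}")

    if select == "lrt":
        quadratic = fit.p_quad < alpha
        linear = fit.p_lin < alpha
    else:
        best = min(
            (fit.aic_m0, 0), (fit.aic_m1, 1), (fit.aic_m2, 2), key=lambda p: p[0]
        )[1]
        quadratic = best == 2 and fit.p_quad < alpha
        linear = best == 1 and fit.p_lin < alpha

    if quadratic and fit.beta_quad != 0:
        direction = "up" if fit.beta_quad > 0 else "down"
        return TrendClass(fit.metabolite, fit.group, f"model2_{direction}", direction)
    if linear and fit.beta_lin != 0:
        direction = "up" if fit.beta_lin > 0 else "down"
        return TrendClass(fit.metabolite, fit.group, f"model1_{direction}", direction)
    return TrendClass(fit.metabolite, fit.group, "none", "none")


def classify_trends(
    fits: list[TrendFit], alpha: float = 0.05, select: str = "lrt"
) -> pd.DataFrame:
    rows = [classify_trend(f, alpha=alpha, select=select) for f in fits]
    return pd.DataFrame(
        [(r.metabolite, r.group, r.label, r.direction) for r in rows],
        columns=["metabolite_name", "group", "label", "direction"],
    ).set_index("metabolite_name")


def fits_to_frame(fits: list[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits]).set_index("metabolite")


def concordance_select(
    classes: dict[str, pd.DataFrame],
    mode: str = "direction",
) -> pd.DataFrame:
    """Metabolites moving the same way in C and AE and the opposite way in A.

    ``classes`` maps group name -> classify_trends output. ``direction``
    compares up/down only; ``class`` additionally requires C and AE to share
    the full four-way label. Metabolites missing a class in any group are
    not selected.
    """
    for g in ("C", "A", "AE"):
        if g not in classes:
            raise ValueError(f"concordance needs classes for group {g!r}")
    if mode not in ("direction", "class"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    mets = sorted(
        set(classes["C"].index) | set(classes["A"].index) | set(classes["AE"].index)
    )
    opposite = {"up": "down", "down": "up"}
    rows = []
    for met in mets:
        entry = {}
        for g in ("C", "A", "AE"):
            if met in classes[g].index:
                entry[g] = (classes[g].loc[met, "label"], classes[g].loc[met, "direction"])
            else:
                entry[g] = ("none", "none")
        (lab_c, dir_c), (lab_a, dir_a), (lab_ae, dir_ae) = entry["C"], entry["A"], entry["AE"]
        selected = (
            dir_c in opposite
            and dir_c == dir_ae
            and dir_a == opposite[dir_c]
            and (mode == "direction" or lab_c == lab_ae)
        )
        rows.append((met, lab_c, lab_a, lab_ae, selected))
    return pd.DataFrame(
        rows, columns=["metabolite_name", "class_C", "class_A", "class_AE", "selected"]
    ).set_index("metabolite_name")
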