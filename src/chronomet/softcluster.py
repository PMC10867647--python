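"""Soft temporal clustering of metabolite time profiles.

Within a group, each metabolite is summarized by its median intensity per
sampling day, the profiles are z-scored, and fuzzy c-means partitions them
into c soft clusters. The objective is

    J(U, V) = sum_i sum_k u_ik^m ||x_i - v_k||^2,

minimized by alternating the membership update

    u_ik = [ sum_j (d_ik / d_ij)^(2/(m-1)) ]^(-1)

and the centroid update v_k = sum_i u_ik^m x_i / sum_i u_ik^m. The number of
clusters is chosen from the minimum pairwise centroid distance (Dmin) curve:
past the true cluster count, additional centroids split real groups and Dmin
collapses, so the selected c is the largest one whose Dmin still drops
sharply to the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datatypes import MetaboliteMatrix, TimeProfile


# ---------------------------------------------------------------------------
# profile construction


def timepoint_medians(matrix: MetaboliteMatrix, group: str) -> TimeProfile:
    """Per-day median intensity of each metabolite in a group, on log2 scale.

    The median is taken over the group's samples at each day (arithmetic
    midpoint for even counts) and stored as log2, where the pipeline's
    noise model is additive, so the subsequent row z-scoring preserves
    trajectory shape.
    """
    sheet = matrix.samples
    days = sorted({int(d) for d in sheet.biological(group=group)["day"]})
    cols = {}
    for day in days:
        ids = list(sheet.biological(group=group, day=day).index)
        med = np.log2(matrix.values[ids].median(axis=1))
        if med.isna().any():
            bad = med.index[med.isna()][0]
            raise ValueError(
                f"metabolite {bad!r} has no sample at day {day} in group {group!r}"
            )
        cols[day] = med
    values = pd.DataFrame(cols)
    values.index.name = "metabolite_name"
    return TimeProfile(values, standardized=False)


def standardize_profile(profile: TimeProfile) -> TimeProfile:
    """Z-score each row across timepoints (sample sd, ddof=1).

    Zero-variance rows carry no temporal shape; they are removed and
    recorded in ``dropped_zero_variance``.
    """
    if profile.standardized:
        raise ValueError("profile is already standardized")
    vals = profile.values
    sd = vals.std(axis=1, ddof=1)
    flat = sd <= 0
    dropped = list(vals.index[flat])
    if flat.all():
        raise ValueError("every profile row has zero variance across timepoints")
    kept = vals[~flat]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    return TimeProfile(z, standardized=True, dropped_zero_variance=dropped)


# ---------------------------------------------------------------------------
# fuzzy c-means


@dataclass
class ClusterResult:
    """A converged fuzzy c-means solution."""

    c: int
    m: float
    centroids: np.ndarray            # c x timepoints
    membership: pd.DataFrame         # metabolite x cluster (columns 0..c-1)
    objective: float
    objective_trace: list[float]
    n_iter: int
    seed: int
    timepoints: list[int]


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix from squared distances (n x c).

    A point coincident with one or more centroids splits its membership
    equally among the zero-distance centroids.
    """
    n, c = d2.shape
    u = np.empty_like(d2)
    zero_rows = (d2 == 0.0).any(axis=1)
    with np.errstate(divide="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
    ok = ~zero_rows
    u[ok] = w[ok] / w[ok].sum(axis=1, keepdims=True)
    if zero_rows.any():
        for i in np.flatnonzero(zero_rows):
            hits = d2[i] == 0.0
            u[i] = 0.0
            u[i, hits] = 1.0 / hits.sum()
    return u


def fuzzy_cmeans(
    profile: TimeProfile,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterResult:
    """Fuzzy c-means on a standardized time profile.

    Initial centroids are ``c`` distinct rows drawn by a seeded RNG.
    Iteration stops when the largest absolute membership change falls below
    ``tol`` or after ``max_iter`` sweeps.
    """
    if not profile.standardized:
        raise ValueError("profile must be standardized before clustering")
    x = profile.values.to_numpy(dtype=float)
    n = x.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"c must be in [1, {n}], got {c}")
    if m <= 1.0:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")

    rng = np.random.default_rng(seed)
    v = x[rng.choice(n, size=c, replace=False)].copy()

    d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    u = _memberships(d2, m)
    trace = [float((u**m * d2).sum())]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        v = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        u_new = _memberships(d2, m)
        trace.append(float((u_new**m * d2).sum()))
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break
    membership = pd.DataFrame(u, index=profile.values.index, columns=range(c))
    return ClusterResult(
        c=c,
        m=m,
        centroids=v,
        membership=membership,
        objective=trace[-1],
        objective_trace=trace,
        n_iter=n_iter,
        seed=seed,
        timepoints=profile.timepoints,
    )


def estimate_fuzzifier(profile: TimeProfile, mode: float | str = 2.0) -> float:
    """Fuzzifier to use for clustering.

    A numeric ``mode`` is returned as-is (default 2.0). ``"estimate"``
    applies the Schwaemmle-Jensen (2010) heuristic, which sets m from the
    dataset's feature count N and dimensionality D so that uniform noise is
    not assigned crisp clusters:

        m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    """
    if isinstance(mode, (int, float)):
        if mode <= 1:
            raise ValueError("fuzzifier must be > 1")
        return float(mode)
    if mode != "estimate":
        raise ValueError(f"unknown fuzzifier mode {mode!r}")
    n, d = profile.values.shape
    return 1.0 + (1418.0 / n + 22.05) * d**-2.0 + (12.33 / n + 0.243) * d ** (
        -0.0406 * np.log(n) - 0.1134
    )


# ---------------------------------------------------------------------------
# cluster-number selection


@dataclass
class DminCurve:
    """Minimum pairwise centroid distance per candidate cluster count."""

    dmin: dict[int, float]
    repeats: int
    seeds: dict[int, list[int]] = field(default_factory=dict)


def _min_centroid_distance(centroids: np.ndarray) -> float:
    c = centroids.shape[0]
    best = np.inf
    for i in range(c):
        d = np.linalg.norm(centroids[i + 1 :] - centroids[i], axis=1)
        if d.size:
            best = min(best, float(d.min()))
    return best


def _derived_seed(seed: int, c: int, repeat: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(c), int(repeat)])
    return int(ss.generate_state(1)[0] % (2**31))


def dmin_curve(
    profile: TimeProfile,
    c_max: int,
    c_min: int = 2,
    m: float = 2.0,
    repeats: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> DminCurve:
    """Dmin(c) = median over seeded repeats of the minimum pairwise centroid
    distance of a fuzzy c-means run with c clusters."""
    if c_max < c_min:
        raise ValueError("c_max must be >= c_min")
    if c_max > len(profile) - 1:
        raise ValueError("c_max must be at most n_rows - 1")
    curve: dict[int, float] = {}
    seeds: dict[int, list[int]] = {}
    for c in range(c_min, c_max + 1):
        vals, used = [], []
        for r in range(repeats):
            s = _derived_seed(seed, c, r)
            res = fuzzy_cmeans(profile, c, m=m, seed=s, tol=tol, max_iter=max_iter)
            vals.append(_min_centroid_distance(res.centroids))
            used.append(s)
        curve[c] = float(np.median(vals))
        seeds[c] = used
    return DminCurve(curve, repeats, seeds)


class OptimalC(NamedTuple):
    c: int
    fallback: bool  # True when no drop qualified and c_min was returned


def select_optimal_c(curve: DminCurve, delta: float = 0.2, force_c: int | None = None) -> OptimalC:
    """Largest c whose relative Dmin drop to c+1 is at least ``delta``.

    r(c) = (Dmin(c) - Dmin(c+1)) / Dmin(c); the drop is indexed by its left
    endpoint. With no qualifying drop the smallest candidate is returned
    with a fallback flag. ``force_c`` overrides the rule entirely.
    """
    if force_c is not None:
        return OptimalC(int(force_c), False)
    cs = sorted(curve.dmin)
    if len(cs) < 3:
        raise ValueError("need Dmin at three or more cluster counts")
    best = None
    for c in cs[:-1]:
        d_c, d_next = curve.dmin[c], curve.dmin[c + 1]
        if d_c > 0 and (d_c - d_next) / d_c >= delta:
            best = c
    if best is None:
        warnings.warn(
            f"no Dmin drop of at least {delta:.0%}; falling back to c={cs[0]}"
        )
        return OptimalC(cs[0], True)
    return OptimalC(best, False)


# ---------------------------------------------------------------------------
# core members and export


@dataclass
class CoreSet:
    """Per-cluster metabolites whose top membership exceeds the threshold."""

    table: pd.DataFrame  # columns: metabolite_name, cluster, membership
    threshold: float


def core_members(result: ClusterResult, threshold: float = 0.7) -> CoreSet:
    """Assign each metabolite to its argmax cluster (ties to the lowest
    index) and retain it iff that membership is strictly above ``threshold``."""
    u = result.membership.to_numpy()
    assign = u.argmax(axis=1)
    top = u[np.arange(len(u)), assign]
    keep = top > threshold
    table = pd.DataFrame(
        {
            "metabolite_name": result.membership.index[keep],
            "cluster": assign[keep],
            "membership": top[keep],
        }
    )
    table = table.sort_values(
        ["cluster", "membership", "metabolite_name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return CoreSet(table, threshold)


def heatmap_matrix(result: ClusterResult, core: CoreSet, profile: TimeProfile) -> pd.DataFrame:
    """Standardized profiles of core metabolites, grouped by cluster and
    ordered by descending membership — the heatmap row layout."""
    if not profile.standardized:
        raise ValueError("heatmap export expects the standardized profile")
    if core.table.empty:
        warnings.warn("no core metabolites; heatmap export is empty")
        out = pd.DataFrame(
            columns=["cluster", "membership", *profile.values.columns]
        )
        out.index.name = "metabolite_name"
        return out
    rows = profile.values.loc[core.table["metabolite_name"]]
    out = rows.copy()
    out.insert(0, "cluster", core.table["cluster"].to_numpy())
    out.insert(1, "membership", core.table["membership"].to_numpy())
    out.index.name = "metabolite_name"
    return out
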