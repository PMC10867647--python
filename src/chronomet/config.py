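"""Pipeline configuration: nested defaults plus optional YAML overrides."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "io": {
        # sampling-day grid; a study may override it
        "days": [0, 14, 28, 63, 91],
        "groups": ["C", "A", "AE"],
    },
    "preprocess": {
        "ms2_threshold": 0.5,
        # "elementwise_max" (per-sample max over duplicate features) or
        # "best_feature" (feature with highest mean intensity wins whole row)
        "collapse": "elementwise_max",
        # optional QC-CV cutoff; None disables CV-based removal
        "max_qc_cv": None,
    },
    "differential": {
        "test": "t",          # "t" | "wilcoxon", on log2 intensities
        "day_ref": 0,
        "day_cmp": 63,
        "p_threshold": 0.05,
        "lfc_threshold": 1.0,
    },
    "cluster": {
        "m": 2.0,              # fuzzifier; "estimate" for the data-driven heuristic
        "c": "auto",
        "c_min": 2,
        "c_max": 8,
        "repeats": 3,
        "delta": 0.2,          # relative Dmin drop that still counts as an elbow
        "tol": 1e-6,
        "max_iter": 300,
        "membership_threshold": 0.7,
        "force_c": None,
    },
    "patterns": {
        "library": "default5",
        "peak_day": 28,
    },
    "lmm": {
        "alpha": 0.05,
        "select": "lrt",               # "lrt" | "aic" for linear-vs-quadratic
        "concordance": "direction",    # "direction" | "class"
        "model2_direction": "coefficient",  # or "net_change"
    },
    "enrich": {
        "min_k": 1,
    },
    "simulate": {},  # see simulate.SimConfig for generator defaults
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, merged with a YAML file if given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return _deep_merge(DEFAULTS, user)
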