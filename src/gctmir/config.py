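"""Pipeline configuration: every numeric threshold with its default.

A single YAML file can override any subset of the defaults; unknown keys
are rejected to catch typos.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    # differential expression selection rules
    "mirna_de": {"logfc_min": 0.0, "p_adj_max": 0.01},
    "mrna_de": {"logfc_min": 1.5, "p_adj_max": 0.01},
    "tf_screen": {"logfc_min": 1.0, "p_adj_max": 0.01},
    "heatmap_p_adj_max": 1e-5,
    "test_method": "student",       # or "welch"
    "adjust_method": "bh",           # or "holm", "by"
    "clustering": {"linkage": "average", "distance": "euclidean"},
    # qPCR
    "ct_range": [0.0, 45.0],
    "welch_alpha": 0.05,
    # TF ~ miR regression
    "regression_alpha": 0.05,
    "mir302_members": ["miR-302a", "miR-302b", "miR-302c", "miR-302d", "miR-367"],
    # motif scanning
    "transfac_pseudocount": 0.01,
    "background": {"order": 0, "pseudocount": 0.01},
    "scan": {
        "bin_width_bits": 1.0,
        "alpha": 0.05,
        "n_shuffles": 100_000,
        "evalue_alpha": 0.05,
        "both_strands": True,
    },
    "dust": {"window": 64, "threshold": 2.0},
    # seed enrichment
    "chi2_continuity": False,
    "disjoint_background": False,
    "seed_2to7": "AAGUGC",
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise KeyError(f"unknown config key: {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)
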