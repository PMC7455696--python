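"""Run configuration: one YAML drives every pipeline stage.

The config is a nested mapping merged over package defaults, so a demo
file only needs to state what it changes.  Stage parameters mirror the
operation defaults documented in each module.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 1,
    "out_dir": "ailmap_out",
    "map": {
        "rate_cM_per_Mb": 2.8,
        "region_start_bp": 168_600_000,
        "region_end_bp": 171_700_000,
    },
    "sim": {
        "grid_spacing_bp": 2000,
        "n_founders": [16, 15],
        "generation_sizes": [150, 150, 150, 150, 150, 150, 150, 150, 600],
        "n_hap_per_pool": [4, 4],
        "frac_diagnostic": 0.05,
        "q_intervals": [],
        "qtl": {
            "loci": [
                {"position_bp": 169_240_000, "effect_g": 120.0, "high_allele": 1},
                {"position_bp": 169_650_000, "effect_g": 90.0, "high_allele": 1},
            ],
            "baseline_g": 700.0,
            "sex_effect_g": 250.0,
            "batch_effects_g": [0.0, 25.0, -20.0, 10.0],
            "residual_sd_g": 100.0,
        },
        "panel": {
            "breeds": [
                {"name": "HQLA", "group": "high", "n": 16, "q_carrier_freq": 0.9},
                {"name": "CB1", "group": "high", "n": 29, "q_carrier_freq": 0.85},
                {"name": "CB2", "group": "high", "n": 30, "q_carrier_freq": 0.85},
                {"name": "HB", "group": "low", "n": 15, "q_carrier_freq": 0.05},
                {"name": "SK", "group": "low", "n": 30, "q_carrier_freq": 0.05},
                {"name": "CH", "group": "low", "n": 30, "q_carrier_freq": 0.1},
                {"name": "TBC", "group": "low", "n": 30, "q_carrier_freq": 0.05},
                {"name": "DWS", "group": "low", "n": 31, "q_carrier_freq": 0.05},
                {"name": "XSD", "group": "low", "n": 8, "q_carrier_freq": 0.1},
                {"name": "SUM", "group": "low", "n": 15, "q_carrier_freq": 0.1},
            ],
        },
    },
    "markers": {
        "tier1": 0.95,
        "tier2": 0.75,
        "annot_tier": 0.3,
        "spacing_bp": 100,
        "ld_r2_max": 0.4,
        "alphas": [0.01, 0.05],
    },
    "assoc": {"covariates": ["sex", "batch"]},
    "ibd": {"min_support": 2},
    "haplo": {"min_freq": 0.01, "fdr": 0.05, "n_tag_snps": 12},
    "sharing": {"bin_bp": 2000, "threshold": 0.4, "sub_region": None},
    "popgen": {
        "pi_window_bp": 50_000,
        "pi_step_bp": 25_000,
        "tajd_bin_bp": 25_000,
        "fst_window_bp": 20_000,
        "hap_div_bin_bp": 2000,
        "xpehh_core_step": 10,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over package defaults; validate ranges."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    m = cfg["map"]
    if m["region_end_bp"] <= m["region_start_bp"]:
        raise ValueError("map region end must exceed start")
    if m["rate_cM_per_Mb"] < 0:
        raise ValueError("map rate must be non-negative")
    mk = cfg["markers"]
    for key in ("tier1", "tier2", "annot_tier"):
        if not 0 <= mk[key] <= 1:
            raise ValueError(f"markers.{key} outside [0, 1]")
    if not 0 < cfg["haplo"]["fdr"] < 1:
        raise ValueError("haplo.fdr must lie in (0, 1)")
    if not 0 <= cfg["sharing"]["threshold"] <= 1:
        raise ValueError("sharing.threshold outside [0, 1]")
    if int(cfg["seed"]) < 0:
        raise ValueError("seed must be non-negative")
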