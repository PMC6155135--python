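"""Pipeline configuration: schema validation, normalization, fingerprinting.

Configurations are plain nested dicts (typically loaded from YAML).  They
are validated fully before any computation: unknown keys are rejected, and
a stable fingerprint (SHA-256 of the canonical JSON form) is embedded in
every output so results can be traced back to the exact settings that
produced them.  Semantically identical configs (key reordering, list vs
tuple) fingerprint identically.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml

from .core import NDNTParams
from .identify import CONNECTIVITIES, FilterRule

__all__ = ["load_config", "validate_config", "config_fingerprint", "ndnt_params_from", "rules_from"]

_TOP_KEYS = {
    "input",
    "gate_input",
    "output_dir",
    "seed",
    "preprocess",
    "ndnt",
    "identify",
    "reconstruct",
    "evaluate",
}
_INPUT_KEYS = {"path", "format", "dataset"}
_PREPROCESS_KEYS = {"steps", "mode"}
_NDNT_KEYS = {"window", "t", "polarity", "tile", "tile_overlap"}
_IDENTIFY_KEYS = {
    "min_size",
    "morphology",
    "connectivity",
    "mode",
    "stitch_min_overlap",
    "rules",
    "default",
    "overlap_gate",
    "keep_largest",
}
_GATE_KEYS = {"min_overlap", "min_size", "ndnt"}
_RULE_KEYS = {"class", "priority", "predicates"}
_RECONSTRUCT_KEYS = {"flatten", "report_formats", "spacing", "save_class_volumes", "volume_format"}
_EVALUATE_KEYS = {"truth_path", "truth_format", "truth_dataset", "metrics"}

_POLARITIES = {"dark_foreground", "bright_foreground", "both"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    if not isinstance(section, dict):
        raise ValueError(f"config section {where!r} must be a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where!r}: {sorted(unknown)}")


def _validate_ndnt(section: dict, where: str = "ndnt") -> None:
    _check_keys(section, _NDNT_KEYS, where)
    if "window" not in section:
        raise ValueError(f"{where}: 'window' is required")
    t = section.get("t", 10)
    if not 0 <= float(t) <= 100:
        raise ValueError(f"{where}: t must lie in [0, 100]")
    pol = section.get("polarity", "dark_foreground")
    if pol not in _POLARITIES:
        raise ValueError(f"{where}: unknown polarity {pol!r}")


def validate_config(cfg: dict) -> dict:
    """Validate a pipeline configuration dict; returns it unchanged.

    Raises ``ValueError`` on unknown keys, malformed sections, duplicate
    rule priorities or out-of-range parameters.
    """
    _check_keys(cfg, _TOP_KEYS, "<top level>")
    if "ndnt" not in cfg:
        raise ValueError("config requires an 'ndnt' section")
    _validate_ndnt(cfg["ndnt"])
    if "input" in cfg:
        _check_keys(cfg["input"], _INPUT_KEYS, "input")
    if "gate_input" in cfg:
        _check_keys(cfg["gate_input"], _INPUT_KEYS, "gate_input")
    if "preprocess" in cfg:
        _check_keys(cfg["preprocess"], _PREPROCESS_KEYS, "preprocess")
        if cfg["preprocess"].get("mode", "3d") not in ("2d", "3d"):
            raise ValueError("preprocess.mode must be '2d' or '3d'")
    ident = cfg.get("identify", {})
    _check_keys(ident, _IDENTIFY_KEYS, "identify")
    if ident.get("connectivity", "face") not in CONNECTIVITIES:
        raise ValueError(f"identify.connectivity must be one of {sorted(CONNECTIVITIES)}")
    if ident.get("mode", "3d") not in ("3d", "2d_stitch"):
        raise ValueError("identify.mode must be '3d' or '2d_stitch'")
    if ident.get("default", "keep_unassigned") not in ("discard", "keep_unassigned"):
        raise ValueError("identify.default must be 'discard' or 'keep_unassigned'")
    rules = ident.get("rules", [])
    priorities = []
    for rule in rules:
        _check_keys(rule, _RULE_KEYS, "identify.rules[]")
        if "class" not in rule or "predicates" not in rule:
            raise ValueError("each rule needs 'class' and 'predicates'")
        priorities.append(rule.get("priority", 0))
    if len(set(priorities)) != len(priorities):
        raise ValueError("filter rule priorities must be unique")
    if "overlap_gate" in ident and ident["overlap_gate"] is not None:
        _check_keys(ident["overlap_gate"], _GATE_KEYS, "identify.overlap_gate")
        if "ndnt" in ident["overlap_gate"]:
            _validate_ndnt(ident["overlap_gate"]["ndnt"], "identify.overlap_gate.ndnt")
    if "reconstruct" in cfg:
        _check_keys(cfg["reconstruct"], _RECONSTRUCT_KEYS, "reconstruct")
    if "evaluate" in cfg:
        _check_keys(cfg["evaluate"], _EVALUATE_KEYS, "evaluate")
    return cfg


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return validate_config(cfg or {})


def _normalize(obj):
    if isinstance(obj, dict):
        return {str(k): _normalize(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_normalize(v) for v in obj]
    if isinstance(obj, float) and obj.is_integer():
        return int(obj)
    if obj == float("inf"):
        return "inf"
    return obj


def config_fingerprint(cfg: dict) -> str:
    """Stable hash of the normalized configuration."""
    canon = json.dumps(_normalize(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def ndnt_params_from(section: dict) -> NDNTParams:
    """Build :class:`NDNTParams` from an ``ndnt`` config section.

    A polarity of ``both`` is handled one level up (two passes are run and
    their masks merged); here it materializes as dark polarity.
    """
    pol = section.get("polarity", "dark_foreground")
    if pol == "both":
        pol = "dark_foreground"
    tile = section.get("tile")
    overlap = section.get("tile_overlap")
    return NDNTParams(
        window_shape=tuple(section["window"]),
        threshold_t=float(section.get("t", 10)),
        polarity=pol,
        tile_shape=None if tile is None else tuple(tile),
        tile_overlap=None if overlap is None else tuple(overlap),
    )


def rules_from(rule_dicts) -> list:
    """Build :class:`FilterRule` objects from config rule entries."""
    rules = []
    for i, rd in enumerate(rule_dicts):
        preds = {
            name: (float(lo), float(hi)) for name, (lo, hi) in rd["predicates"].items()
        }
        rules.append(
            FilterRule(class_label=rd["class"], predicates=preds, priority=int(rd.get("priority", i)))
        )
    return rules
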