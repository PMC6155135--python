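"""End-to-end pipeline runner: segment -> identify -> reconstruct -> evaluate.

The library entry point is :func:`run_pipeline_arrays`, which takes
in-memory volumes and a validated configuration dict and returns every
intermediate product.  :func:`run_pipeline` wraps it with file I/O: it
reads the input volume(s), writes masks, per-class volumes, the optional
2D flattening, the statistical report (JSON + CSV), evaluation metrics and
a structured run log to the configured output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as vio
from .config import config_fingerprint, ndnt_params_from, rules_from, validate_config
from .core import ndnt_threshold
from .evaluate import hausdorff, mean_hausdorff, voxel_recall_precision
from .identify import (
    classify_components,
    extract_records,
    keep_largest_components,
    label_components,
    morphological_cleanup,
    overlap_filter,
    stitch_2d_components,
)
from .preprocess import PreprocessConfig, run_segmentation
from .reconstruct import StatReport, build_report, flatten_to_2d, render_class_volumes

__all__ = ["PipelineResult", "run_pipeline_arrays", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    records: list
    class_volumes: Dict[str, np.ndarray]
    report: StatReport
    flat: Optional[np.ndarray] = None
    gate_mask: Optional[np.ndarray] = None
    metrics: Dict[str, float] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)


def _segment(volume: np.ndarray, cfg: dict) -> np.ndarray:
    """Run preprocessing + NDNT; polarity 'both' unions a dark and a bright pass."""
    pre = cfg.get("preprocess", {})
    steps = [tuple(s) if isinstance(s, (list, tuple)) else (s,) for s in pre.get("steps", [])]
    mode = pre.get("mode", "3d")
    polarity = cfg["ndnt"].get("polarity", "dark_foreground")
    polarities = ["dark_foreground", "bright_foreground"] if polarity == "both" else [polarity]
    mask = np.zeros(volume.shape, dtype=bool)
    for pol in polarities:
        section = dict(cfg["ndnt"])
        section["polarity"] = pol
        params = ndnt_params_from(section)
        pcfg = PreprocessConfig(ndnt=params, steps=steps, mode=mode)
        mask |= run_segmentation(volume, pcfg)
    return mask


def _identify(mask: np.ndarray, volume: np.ndarray, cfg: dict):
    ident = cfg.get("identify", {})
    connectivity = ident.get("connectivity", "face")
    morphology = [tuple(op) for op in ident.get("morphology", [])]
    cleaned = morphological_cleanup(
        mask, min_size=int(ident.get("min_size", 0)), ops=morphology, connectivity=connectivity
    )
    if ident.get("mode", "3d") == "2d_stitch":
        per_slice = [label_components(cleaned[z], connectivity)[0] for z in range(cleaned.shape[0])]
        labels, k = stitch_2d_components(
            per_slice, min_overlap_voxels=int(ident.get("stitch_min_overlap", 1))
        )
    else:
        labels, k = label_components(cleaned, connectivity)
    return cleaned, labels, k


def run_pipeline_arrays(
    volume: np.ndarray,
    cfg: dict,
    gate_volume: Optional[np.ndarray] = None,
    truth: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Execute the full pipeline on in-memory arrays.

    ``gate_volume`` is an optional second channel of identical shape; when
    the config carries ``identify.overlap_gate`` it is segmented with its
    own threshold settings and primary components not overlapping the gate
    mask are dropped.  ``truth`` is an optional ground-truth mask for the
    evaluation stage.  Input arrays are never mutated.
    """
    cfg = validate_config(cfg)
    fingerprint = config_fingerprint(cfg)
    timings: Dict[str, float] = {}
    volume = np.asarray(volume)

    t0 = time.perf_counter()
    mask = _segment(volume, cfg)
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cleaned, labels, k = _identify(mask, volume, cfg)
    ident = cfg.get("identify", {})
    connectivity = ident.get("connectivity", "face")

    gate_mask = None
    if gate_volume is not None and ident.get("overlap_gate") is not None:
        gate_cfg = ident["overlap_gate"]
        gate_section = gate_cfg.get("ndnt", cfg["ndnt"])
        gate_mask = ndnt_threshold(np.asarray(gate_volume), ndnt_params_from(gate_section))
        # the gate channel gets the same small-component cleanup as the
        # primary channel so isolated noise voxels cannot gate anything in
        gate_mask = morphological_cleanup(
            gate_mask, min_size=int(gate_cfg.get("min_size", 0)), connectivity=connectivity
        )
        labels, k = overlap_filter(
            labels, gate_mask, min_overlap_voxels=int(gate_cfg.get("min_overlap", 1))
        )
    if ident.get("keep_largest") is not None:
        labels, k = keep_largest_components(labels, int(ident["keep_largest"]))

    records = extract_records(labels, volume)
    rules = rules_from(ident.get("rules", []))
    if rules:
        records = classify_components(records, rules, default=ident.get("default", "keep_unassigned"))
    timings["identification"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    class_volumes = render_class_volumes(labels, records) if records else {}
    recon = cfg.get("reconstruct", {})
    spacing = recon.get("spacing")
    report = build_report(records, volume.shape, spacing=spacing, config_fingerprint=fingerprint)
    flat = flatten_to_2d(labels) if recon.get("flatten", False) else None
    timings["reconstruction"] = time.perf_counter() - t0

    metrics: Dict[str, float] = {}
    if truth is not None:
        t0 = time.perf_counter()
        truth_mask = np.asarray(truth) != 0
        pred_mask = labels > 0
        wanted = cfg.get("evaluate", {}).get(
            "metrics", ["hausdorff", "mean_hausdorff", "recall_precision"]
        )
        if "hausdorff" in wanted:
            metrics["hausdorff"] = hausdorff(pred_mask, truth_mask, spacing=spacing).value
        if "mean_hausdorff" in wanted:
            metrics["mean_hausdorff"] = mean_hausdorff(pred_mask, truth_mask, spacing=spacing).value
        if "recall_precision" in wanted:
            r, p = voxel_recall_precision(pred_mask, truth_mask)
            metrics["voxel_recall"] = r
            metrics["voxel_precision"] = p
        timings["evaluation"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        log.info("stage=%s seconds=%.3f", stage, dt)
    log.info("components=%d classes=%s", k, sorted(report.per_class))

    return PipelineResult(
        mask=cleaned,
        labels=labels,
        n_components=k,
        records=records,
        class_volumes=class_volumes,
        report=report,
        flat=flat,
        gate_mask=gate_mask,
        metrics=metrics,
        timings=timings,
    )


def run_pipeline(cfg: dict) -> PipelineResult:
    """File-based pipeline run; writes all artifacts to ``cfg['output_dir']``."""
    cfg = validate_config(cfg)
    if "input" not in cfg or "output_dir" not in cfg:
        raise ValueError("file-based runs require 'input' and 'output_dir'")
    inp = cfg["input"]
    volume = vio.read_volume(inp["path"], inp.get("format", "tiff_stack"), inp.get("dataset"))
    gate = None
    if "gate_input" in cfg:
        g = cfg["gate_input"]
        gate = vio.read_volume(g["path"], g.get("format", "tiff_stack"), g.get("dataset"))
    truth = None
    ev = cfg.get("evaluate", {})
    if ev.get("truth_path"):
        truth = vio.read_volume(ev["truth_path"], ev.get("truth_format", "tiff_stack"), ev.get("truth_dataset"))

    result = run_pipeline_arrays(volume, cfg, gate_volume=gate, truth=truth)

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    recon = cfg.get("reconstruct", {})
    fmt = recon.get("volume_format", "tiff_stack")
    ext = {"tiff_stack": ".tiff", "hdf5": ".h5", "image_sequence": ""}[fmt]
    vio.write_volume(result.mask.astype(np.uint8), out / f"mask{ext or '.tiff'}", fmt)
    vio.write_volume(result.labels, out / f"labels{ext or '.tiff'}", fmt, is_labels=True)
    if recon.get("save_class_volumes", True):
        for cls, vol in result.class_volumes.items():
            vio.write_volume(vol, out / f"class_{cls}{ext or '.tiff'}", fmt, is_labels=True)
    if result.flat is not None:
        vio.write_volume(result.flat, out / "flat.tiff", "tiff_stack", is_labels=True)
    formats = recon.get("report_formats", ["json", "csv"])
    if "json" in formats:
        (out / "report.json").write_text(result.report.to_json())
    if "csv" in formats:
        result.report.to_csv(out / "report.csv")
    if result.metrics:
        (out / "metrics.json").write_text(json.dumps(result.metrics, indent=2, sort_keys=True))
    logpath = out / "run_log.json"
    logpath.write_text(
        json.dumps(
            {
                "config_fingerprint": result.report.config_fingerprint,
                "n_components": result.n_components,
                "per_class_counts": {c: v["object_count"] for c, v in result.report.per_class.items()},
                "timings_seconds": result.timings,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return result
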