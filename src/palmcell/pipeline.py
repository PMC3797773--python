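"""End-to-end pipeline orchestration: drift -> (registration) -> clustering
-> cells -> population statistics, driven by a single config.

The config (dict, or YAML/JSON file via the CLI) either points at input
files or asks for a synthetic scene; every stage persists its intermediate
artifact into the output directory, and a ``summary.json`` records
versions, parameters, seeds and QC verdicts so a run is reproducible and
auditable.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .cells import assign_clusters_to_cells, cells_to_frame, cells_to_json, detect_cells
from .clustering import ClusterParams, clusters_to_frame, clusters_to_json, find_clusters
from .drift import apply_drift, drift_residuals, estimate_mean_drift, link_fiducials
from .errors import ParameterError, StageError
from .io_core import (
    ImageStack,
    read_image_stack,
    read_localization_table,
    write_image_stack,
    write_localization_table,
)
from .registration import fit_channel_transform
from .stats_report import population_maps, save_report
from .synthetic import gen_full_scene

DEFAULT_CONFIG = {
    "seed": 0,
    "pixel_size_nm": 110.0,
    "frame_time_ms": 50.0,
    "loc_precision_nm": 25.0,
    "drift": {"threshold_nm": 10.0, "max_jump_nm": 500.0},
    "registration": {"min_beads": 7},
    "cluster": {},
    "cells": {},
    "report": {},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline config and validate referenced files."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a mapping")
    return cfg


def _merged(config: dict) -> dict:
    out = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("drift", "registration", "cluster", "cells", "report"):
        out[key] = {**DEFAULT_CONFIG[key], **(config.get(key) or {})}
    return out


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns the summary dict written to summary.json.

    Raises StageError (carrying the stage name) on any stage failure;
    partial outputs written before the failure are retained.
    """
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    # -- validate inputs up front (before any computation) -------------------
    inputs = cfg.get("inputs") or {}
    for key, p in inputs.items():
        if not Path(p).exists():
            raise ParameterError(f"input file for '{key}' does not exist: {p}")

    summary: dict = {
        "palmcell_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": {k: cfg[k] for k in ("pixel_size_nm", "frame_time_ms", "loc_precision_nm",
                                           "drift", "registration", "cluster")},
        "qc": {},
        "counts": {},
    }
    meta = dict(
        pixel_size_nm=cfg["pixel_size_nm"],
        frame_time_ms=cfg["frame_time_ms"],
        loc_precision_nm=cfg["loc_precision_nm"],
    )

    # -- stage: inputs / simulation ------------------------------------------
    try:
        if "simulate" in cfg:
            sim = dict(cfg["simulate"] or {})
            scene = gen_full_scene(seed=seed, **sim)
            beads = scene["beads"]
            locs = scene["locs_raw"]
            dna = scene["cells"]["dna"]
            membrane = scene["cells"]["membrane"]
            write_localization_table(beads, outdir / "beads.csv")
            write_localization_table(locs, outdir / "locs_raw.csv")
            write_image_stack(dna, outdir / "dna.tif")
            write_image_stack(membrane, outdir / "membrane.tif")
            summary["counts"]["truth_clusters"] = scene["loc_truth"]["n_clusters"]
            summary["counts"]["truth_cells"] = len(scene["cells"]["truth"]["cells"])
        else:
            beads = read_localization_table(inputs["beads"], **meta)
            locs = read_localization_table(inputs["locs"], **meta)
            dna = read_image_stack(inputs["dna"], pixel_size_nm=cfg["pixel_size_nm"])
            membrane = read_image_stack(inputs["membrane"], pixel_size_nm=cfg["pixel_size_nm"])
    except Exception as exc:
        raise StageError("inputs", str(exc)) from exc

    # -- stage: drift ---------------------------------------------------------
    try:
        tracks = link_fiducials(beads, max_jump_nm=cfg["drift"]["max_jump_nm"])
        model = estimate_mean_drift(tracks)
        model = drift_residuals(tracks, model, threshold_nm=cfg["drift"]["threshold_nm"])
        model.to_json(outdir / "drift_model.json")
        corrected = apply_drift(locs, model, override=cfg["drift"].get("override", False))
        write_localization_table(corrected, outdir / "locs_corrected.csv")
        summary["qc"]["drift_accepted"] = model.accepted
        summary["qc"]["drift_max_residual_nm"] = model.max_residual_nm
        summary["counts"]["fiducial_tracks"] = len(tracks)
    except Exception as exc:
        raise StageError("drift", str(exc)) from exc

    # -- stage: registration (optional, needs a second-channel bead table) ----
    if "register_src" in inputs and "register_dst" in inputs:
        try:
            src = read_localization_table(inputs["register_src"], **meta)
            dst = read_localization_table(inputs["register_dst"], **meta)
            tf = fit_channel_transform(
                src.xy, dst.xy,
                min_beads=cfg["registration"]["min_beads"],
                pixel_size_nm=cfg["pixel_size_nm"],
            )
            tf.to_json(outdir / "channel_transform.json")
            summary["qc"]["registration_residual_max_px"] = tf.residual_max_px
        except Exception as exc:
            raise StageError("registration", str(exc)) from exc

    # -- stage: clustering -----------------------------------------------------
    try:
        params = ClusterParams(**cfg["cluster"])
        clusters = find_clusters(corrected, params)
        clusters_to_frame(clusters).to_csv(outdir / "clusters.csv", index=False)
        clusters_to_json(clusters, outdir / "clusters.json")
        summary["counts"]["clusters"] = len(clusters)
        summary["counts"]["palm_limited"] = sum(c.type == "palm_limited" for c in clusters)
        summary["counts"]["dynamic"] = sum(c.type == "dynamic" for c in clusters)
    except Exception as exc:
        raise StageError("clustering", str(exc)) from exc

    # -- stage: cells ----------------------------------------------------------
    try:
        cell_records = detect_cells(dna, membrane, refine_kwargs=cfg["cells"].get("refine"))
        orphans = assign_clusters_to_cells(
            cell_records, clusters, loc_precision_nm=cfg["loc_precision_nm"]
        )
        cells_to_frame(cell_records).to_csv(outdir / "cells.csv", index=False)
        cells_to_json(cell_records, outdir / "cells.json")
        summary["counts"]["cells"] = len(cell_records)
        summary["counts"]["orphan_clusters"] = len(orphans)
        summary["qc"]["cells_flagged_low_confidence"] = sum(c.low_confidence for c in cell_records)
        summary["counts"]["stages"] = {
            s: sum(c.stage == s for c in cell_records)
            for s in ("vegetative_predivisional", "dividing", "sporulating")
        }
    except Exception as exc:
        raise StageError("cells", str(exc)) from exc

    # -- stage: report ----------------------------------------------------------
    try:
        stats = population_maps(cell_records, clusters, **cfg["report"])
        save_report(stats, outdir / "report")
        summary["counts"]["clusters_in_maps"] = stats.n_assigned
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
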