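"""End-to-end orchestration: simulate / analyze / coloc runs writing artifacts.

These functions are the library face of the command line; each writes its
outputs (TIFF channels, paths CSV, profiles CSV, compartments CSV, summary
JSON) into a directory, stamping every JSON artifact with the tool version
and the config hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisConfig
from .datatypes import Roi, TwoChannelImage
from .simulate import GroundTruth, PlantedCompartment, SimulationSpec, make_network, render_scene
from .trace import load_paths, sample_profile, subtract_background, trace_paths, write_paths
from .compartments import analyze_cell, compartments_table, summarize
from .coloc import coloc_score

log = logging.getLogger("mtllps")

__all__ = ["run_simulate", "run_analyze", "run_coloc", "load_image"]


def _meta(config: AnalysisConfig | None) -> dict:
    return {
        "tool": "mtllps",
        "version": __version__,
        "config_hash": None if config is None else config.hash(),
    }


def load_image(
    ch1_file: str | Path,
    ch2_file: str | Path | None = None,
    pixel_size_nm: float = 30.0,
) -> TwoChannelImage:
    """Read a two-channel TIFF (one stacked file, or two single-channel files)."""
    a = tifffile.imread(ch1_file).astype(float)
    if ch2_file is not None:
        b = tifffile.imread(ch2_file).astype(float)
    else:
        if a.ndim != 3 or a.shape[0] < 2:
            raise ValueError(
                f"{ch1_file}: expected a multi-channel stack when no second file given"
            )
        a, b = a[0], a[1]
    return TwoChannelImage(ch1=a, ch2=b, pixel_size_nm=pixel_size_nm)


def run_simulate(
    spec: SimulationSpec,
    out_dir: str | Path,
    planted: list[PlantedCompartment] | None = None,
) -> GroundTruth:
    """Render a synthetic scene and write ch1/ch2 TIFFs, paths CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = make_network(spec)
    image, gt = render_scene(paths, planted or [], spec)
    tifffile.imwrite(out / "ch1.tif", image.ch1.astype(np.float32))
    tifffile.imwrite(out / "ch2.tif", image.ch2.astype(np.float32))
    write_paths(paths, out / "paths.csv")
    gt.write_json(out / "ground_truth.json")
    (out / "spec.json").write_text(json.dumps(spec.to_dict(), indent=1))
    log.info(
        "simulated scene: %d paths, %d planted compartments -> %s",
        len(paths),
        len(gt.planted),
        out,
    )
    return gt


def run_analyze(
    image: TwoChannelImage,
    config: AnalysisConfig,
    out_dir: str | Path,
    paths_file: str | Path | None = None,
    cell_id: str = "cell0",
    background_subtract: bool = False,
) -> dict:
    """Full analysis chain on one cell: trace -> profile -> detect -> attribute.

    ``paths_file`` supplies user polylines; when absent, paths are traced
    automatically from channel 1.  Writes profiles.csv, compartments.csv and
    summary.json; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if background_subtract:
        image = subtract_background(image, radius_px=config.background_radius_px)
    if paths_file is not None:
        paths = load_paths(
            paths_file, pixel_size_nm=image.pixel_size_nm, image_shape=image.shape
        )
    else:
        paths = trace_paths(
            image,
            min_length_um=config.min_path_length_um,
            ridge_sigma_px=config.ridge_sigma_px,
        )
    profiles = [
        sample_profile(
            image,
            p,
            line_thickness_nm=config.line_thickness_nm,
            step_um=config.effective_step_um,
        )
        for p in paths
    ]
    if not profiles:
        summary = {
            "n_cells": 1,
            "n_compartments": 0,
            "cells": [
                {
                    "cell_id": cell_id,
                    "total_analyzed_length_um": 0.0,
                    "qc_pass": False,
                    "n_compartments": 0,
                }
            ],
            "qc_all_cells_pass": False,
        }
    else:
        cell = analyze_cell(
            cell_id,
            profiles,
            threshold=config.ratio_threshold,
            min_run_samples=config.min_run_samples,
            smoothing_window=config.smoothing_window,
            epsilon_frac=config.epsilon_frac,
            min_total_length_um=config.min_total_length_um,
        )
        summary = summarize([cell])
        compartments_table([cell]).to_csv(out / "compartments.csv", index=False)
        prof_rows = []
        for p in profiles:
            for pos, i1, i2 in zip(p.positions_um, p.i_rbp1, p.i_rbp2):
                prof_rows.append(
                    {
                        "path_id": p.path_id,
                        "position_um": pos,
                        "I_RBP1": i1,
                        "I_RBP2": i2,
                    }
                )
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
    summary["meta"] = _meta(config)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    total = summary["cells"][0]["total_analyzed_length_um"]
    log.info(
        "cell %s: %.1f um analyzed, %d compartments%s",
        cell_id,
        total,
        summary["n_compartments"],
        "" if summary.get("qc_all_cells_pass") else
        f"  [QC: < {config.min_total_length_um:.0f} um analyzed]",
    )
    if not summary.get("qc_all_cells_pass"):
        summary["qc_warning"] = (
            f"analyzed length {total:.1f} um is below the "
            f"{config.min_total_length_um:.0f} um minimum"
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_coloc(
    image: TwoChannelImage,
    roi: Roi,
    config: AnalysisConfig,
    out_dir: str | Path,
    cell_id: str = "cell0",
) -> dict:
    """Colocalization score of one cell, written as coloc.csv + JSON meta."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    other = image.ch_mrna if image.ch_mrna is not None else image.ch2
    res = coloc_score(image.ch1, other, roi, image.pixel_size_nm, config.cutoff_um)
    row = {
        "cell_id": cell_id,
        "expression_level": res.expression_level,
        "spearman_rho": res.spearman_rho,
        "pearson_r": res.pearson_r,
        "n_pixels": res.n_pixels,
    }
    pd.DataFrame([row]).to_csv(out / "coloc.csv", index=False)
    payload = {**row, "meta": _meta(config)}
    (out / "coloc.json").write_text(json.dumps(payload, indent=1))
    log.info("cell %s: spearman_rho=%.3f over %d px", cell_id, res.spearman_rho, res.n_pixels)
    return payload
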