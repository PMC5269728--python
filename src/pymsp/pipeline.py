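"""End-to-end orchestration: manifests in, comparison report and curves out."""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import droplets as droplets_mod
from . import eyemodel, io as msp_io, msp, stats
from .config import PipelineConfig

log = logging.getLogger("pymsp")


def estimate_cells(records, cfg: PipelineConfig):
    """Per-cell estimates for a list of MSPRecord objects."""
    out = []
    for rec in records:
        est = msp.process_record(
            rec,
            baseline_window=cfg.baseline_window,
            peak_smoothing=cfg.peak_smoothing,
            primary_window=cfg.primary_window,
            n_points_primary=cfg.n_points_primary,
            n_points_secondary=cfg.n_points_secondary,
            refine_iterations=cfg.refine_iterations,
            include_beta=cfg.include_beta,
            min_density=cfg.min_density,
            max_limb_sd=cfg.max_limb_sd,
            max_method_diff=cfg.max_method_diff,
            peak_drop_fraction=cfg.peak_drop_fraction,
            shortwave_max=cfg.shortwave_max,
            class_overrides=cfg.class_overrides,
        )
        if not est.qc.passed:
            log.info("QC fail %s: %s", rec.cell_id,
                     ",".join(est.qc.failed_criteria))
        out.append((rec, est))
    return out


def run_pipeline(cell_records, droplet_records, cfg: PipelineConfig,
                 out_dir: Optional[Path] = None) -> dict:
    """Run estimation, QC, droplet cut-offs, comparison and eye models.

    Returns a dict with the per-cell table, droplet table, comparison
    report and eye-model curves; optionally writes everything under
    ``out_dir`` as delimited text / JSON.
    """
    estimates = estimate_cells(cell_records, cfg)
    cell_table = msp_io.estimates_table(estimates)

    processed = [droplets_mod.process_droplet(d, tangent_samples=cfg.tangent_samples)
                 for d in droplet_records]
    droplet_tab = droplets_mod.droplet_table(processed)

    passed = cell_table[cell_table["qc_passed"]].copy()
    passed_stats = passed.rename(columns={"lambda_max_primary": "value"})
    ok_droplets = droplet_tab[
        (droplet_tab["error"] == "")
        & np.isfinite(droplet_tab["lambda_cut"].astype(float))].copy()
    ok_droplets = ok_droplets.rename(columns={"lambda_cut": "value"})

    report = stats.comparison_report(
        passed_stats[["value", "bird_id", "population", "pigment_class"]],
        ok_droplets[["value", "bird_id", "population", "droplet_type"]],
        alpha=cfg.alpha, df_method=cfg.df_method,
    )

    models = {}
    if len(report.pigments) and len(report.droplets):
        models = eyemodel.population_eye_models(
            report.pigments, report.droplets,
            cone_ratios=cfg.cone_ratios,
            normalization=cfg.normalization_mode,
            include_beta=cfg.include_beta,
        )

    counts = {
        "cells_in": int(len(cell_table)),
        "cells_qc_passed": int(cell_table["qc_passed"].sum()),
        "cells_qc_failed": int((~cell_table["qc_passed"]).sum()),
        "droplets_in": int(len(droplet_tab)),
        "droplets_measured": int(len(ok_droplets)),
    }

    result = {
        "cells": cell_table,
        "droplets": droplet_tab,
        "report": report,
        "eye_models": models,
        "counts": counts,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cell_table.to_csv(out / "cell_estimates.tsv", sep="\t", index=False)
        droplet_tab.to_csv(out / "droplet_cuts.tsv", sep="\t", index=False)
        report.pigments.to_csv(out / "pigment_comparison.tsv", sep="\t",
                               index=False)
        report.droplets.to_csv(out / "droplet_comparison.tsv", sep="\t",
                               index=False)
        for pop, (spec, curves) in models.items():
            curves.to_csv(out / f"eye_model_{pop}.tsv", sep="\t", index=False)
        (out / "run_summary.json").write_text(json.dumps(counts, indent=2))
        cfg.write(out / "resolved_config.yaml")
    return result
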