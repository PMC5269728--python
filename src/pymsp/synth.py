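"""Synthetic study generator.

Emulates the raw inputs of a two-population retinal survey with the
hierarchy population -> bird -> cell: per cell, a latent lambda_max is
drawn as ``class mean + population contrast + bird effect + residual``,
and template-shaped outward/return absorbance scans (750 -> 350 nm and
351 -> 749 nm, 2 nm steps) are synthesized with a flat baseline and
i.i.d. Gaussian OD noise.  Post-bleach scans remove the pigment and add a
short-wavelength photoproduct band.  Droplet spectra are falling logistic
cut-off curves whose analytic tangent construction gives
``lambda_cut = midpoint - 2 * scale``.

All randomness flows through one ``numpy`` Generator seeded from the
design, so identical designs reproduce byte-identical studies.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import templates
from .exceptions import ContractViolation
from .msp import MSPRecord, SpectralScan
from .droplets import DropletRecord
from .msp import merge_scans, normalize

OUTWARD_GRID = np.arange(750.0, 349.0, -2.0)  # 750 -> 350, 201 samples
RETURN_GRID = np.arange(351.0, 750.0, 2.0)    # 351 -> 749, 200 samples


@dataclass
class PigmentClassDesign:
    """Generator settings for one pigment class."""

    mean_lambda_max: float
    between_bird_sd: float = 1.0
    residual_sd: float = 1.0
    contrast: float = 0.0        # added to the second population's mean
    n_cells_per_bird: int = 4
    morphology: str = "single cone"


@dataclass
class DropletClassDesign:
    """Generator settings for one droplet type."""

    mean_cut: float
    between_bird_sd: float = 1.0
    residual_sd: float = 1.0
    contrast: float = 0.0
    n_per_bird: int = 3
    logistic_scale: float = 8.0  # nm; lambda_cut = midpoint - 2*scale
    amplitude: float = 0.05      # OD


@dataclass
class StudyDesign:
    populations: dict[str, int] = field(
        default_factory=lambda: {"popA": 7, "popB": 5})
    pigment_classes: dict[str, PigmentClassDesign] = field(default_factory=dict)
    droplet_classes: dict[str, DropletClassDesign] = field(default_factory=dict)
    noise_sd_fraction: float = 0.08   # OD noise as fraction of density
    density_mean: float = 0.02
    density_sd: float = 0.004
    density_floor: float = 0.012
    baseline_od: float = 0.005
    photoproduct_centre: float = 380.0
    photoproduct_width: float = 30.0
    photoproduct_amplitude: float = 0.3  # fraction of pre-bleach density
    emit_post_bleach: bool = True
    seed: int = 0

    def __post_init__(self):
        for name, n in self.populations.items():
            if n < 1:
                raise ContractViolation(f"population {name}: n_birds must be >= 1")
        for cls, d in {**self.pigment_classes}.items():
            if min(d.between_bird_sd, d.residual_sd) < 0:
                raise ContractViolation(f"class {cls}: SDs must be >= 0")
        if self.noise_sd_fraction < 0 or self.density_mean <= 0:
            raise ContractViolation("invalid noise/density settings")


def default_design(seed: int = 0) -> StudyDesign:
    """A study design echoing the scale of the original survey:
    7 + 5 birds, five pigment classes, four measurable droplet types."""
    return StudyDesign(
        populations={"popA": 7, "popB": 5},
        pigment_classes={
            "LWS": PigmentClassDesign(563.0, 1.4, 2.6, 4.4, 6),
            "MWS": PigmentClassDesign(500.0, 2.6, 3.3, 8.8, 2),
            "SWS": PigmentClassDesign(450.0, 1.5, 3.0, -3.5, 1),
            "UVS": PigmentClassDesign(360.0, 1.5, 3.0, 6.4, 1,
                                      morphology="single cone"),
            "rod": PigmentClassDesign(500.5, 1.5, 0.9, 6.0, 5,
                                      morphology="rod"),
        },
        droplet_classes={
            "R": DropletClassDesign(569.0, 1.0, 1.5, 0.2, 2),
            "Y": DropletClassDesign(508.0, 2.0, 3.0, 1.0, 4),
            "C": DropletClassDesign(406.0, 2.0, 3.0, 1.8, 1),
            "P": DropletClassDesign(423.0, 10.0, 20.0, 1.1, 6),
        },
        seed=seed,
    )


@dataclass
class SyntheticStudy:
    records: list[MSPRecord]
    droplets: list[DropletRecord]
    truth: pd.DataFrame          # latent per-cell/per-droplet values
    design: StudyDesign


def _pigment_scans(rng, lambda_max, density, baseline, noise_sd,
                   include_beta=True):
    def absorbance(grid):
        a = baseline + density * templates.pigment_absorbance(
            float(np.clip(lambda_max, *templates.LAMBDA_MAX_RANGE)), grid,
            include_beta=include_beta)
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=len(grid))
        return a

    outward = SpectralScan(OUTWARD_GRID.copy(), absorbance(OUTWARD_GRID), "outward")
    return_ = SpectralScan(RETURN_GRID.copy(), absorbance(RETURN_GRID), "return")
    return outward, return_


def _post_bleach_scan(rng, design: StudyDesign, density, noise_sd):
    bump = design.photoproduct_amplitude * density * np.exp(
        -(((RETURN_GRID - design.photoproduct_centre)
           / design.photoproduct_width) ** 2))
    a = design.baseline_od + bump
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=len(RETURN_GRID))
    return SpectralScan(RETURN_GRID.copy(), a, "return")


def _droplet_scans(rng, d: DropletClassDesign, cut, baseline, noise_sd):
    midpoint = cut + 2.0 * d.logistic_scale

    def absorbance(grid):
        a = baseline + d.amplitude / (1.0 + np.exp((grid - midpoint)
                                                   / d.logistic_scale))
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=len(grid))
        return a

    outward = SpectralScan(OUTWARD_GRID.copy(), absorbance(OUTWARD_GRID), "outward")
    return_ = SpectralScan(RETURN_GRID.copy(), absorbance(RETURN_GRID), "return")
    return outward, return_


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Draw a full synthetic study (records, droplets, ground truth)."""
    rng = np.random.default_rng(design.seed)
    pop_names = list(design.populations)
    records: list[MSPRecord] = []
    droplets: list[DropletRecord] = []
    truth_rows = []

    for pop_i, (pop, n_birds) in enumerate(design.populations.items()):
        for b in range(n_birds):
            bird_id = f"{pop}_bird{b:02d}"
            bird_effects = {cls: rng.normal(0.0, d.between_bird_sd)
                            for cls, d in design.pigment_classes.items()}
            bird_cut_effects = {t: rng.normal(0.0, d.between_bird_sd)
                                for t, d in design.droplet_classes.items()}
            for cls, d in design.pigment_classes.items():
                for c in range(d.n_cells_per_bird):
                    lam = (d.mean_lambda_max
                           + (d.contrast if pop_i == 1 else 0.0)
                           + bird_effects[cls]
                           + rng.normal(0.0, d.residual_sd))
                    density = max(design.density_floor,
                                  rng.normal(design.density_mean,
                                             design.density_sd))
                    noise_sd = design.noise_sd_fraction * density
                    cell_id = f"{bird_id}_{cls}_{c:02d}"
                    outward, return_ = _pigment_scans(
                        rng, lam, density, design.baseline_od, noise_sd)
                    post = (_post_bleach_scan(rng, design, density, noise_sd)
                            if design.emit_post_bleach else None)
                    records.append(MSPRecord(
                        cell_id=cell_id, bird_id=bird_id, population=pop,
                        putative_class=cls, outward=outward, return_=return_,
                        post_bleach=post, morphology=d.morphology))
                    truth_rows.append({
                        "id": cell_id, "kind": "cell", "bird_id": bird_id,
                        "population": pop, "class": cls,
                        "true_lambda_max": lam, "true_density": density,
                        "noise_sd": noise_sd,
                        "bird_effect": bird_effects[cls]})
            for t, d in design.droplet_classes.items():
                for c in range(d.n_per_bird):
                    cut = (d.mean_cut
                           + (d.contrast if pop_i == 1 else 0.0)
                           + bird_cut_effects[t]
                           + rng.normal(0.0, d.residual_sd))
                    noise_sd = design.noise_sd_fraction * d.amplitude * 0.5
                    droplet_id = f"{bird_id}_{t}_{c:02d}"
                    outward, return_ = _droplet_scans(
                        rng, d, cut, design.baseline_od, noise_sd)
                    spectrum = normalize(merge_scans(outward, return_))
                    droplets.append(DropletRecord(
                        droplet_id=droplet_id, bird_id=bird_id,
                        population=pop, droplet_type=t, spectrum=spectrum))
                    truth_rows.append({
                        "id": droplet_id, "kind": "droplet",
                        "bird_id": bird_id, "population": pop, "class": t,
                        "true_lambda_cut": cut,
                        "bird_effect": bird_cut_effects[t]})

    truth = pd.DataFrame(truth_rows)
    return SyntheticStudy(records=records, droplets=droplets, truth=truth,
                          design=design)


def generate_failures(design: Optional[StudyDesign] = None,
                      seed: int = 12345) -> list[dict]:
    """Fixture records each violating exactly one strict QC criterion.

    Returns dicts with keys ``record``, ``expected_failure`` (the QC
    criterion name, or None for the clean control) and ``putative_class``.
    The limb-SD and method-difference fixtures are built by deforming the
    template shape itself, so the other criteria stay comfortably inside
    their thresholds.
    """
    if design is None:
        design = StudyDesign()
    rng = np.random.default_rng(seed)
    lam = 505.0
    baseline = design.baseline_od
    fixtures: list[dict] = []

    def scans_from_fraction(frac_fn, density):
        def absorbance(grid):
            return baseline + density * frac_fn(grid)
        return (SpectralScan(OUTWARD_GRID.copy(), absorbance(OUTWARD_GRID), "outward"),
                SpectralScan(RETURN_GRID.copy(), absorbance(RETURN_GRID), "return"))

    template = lambda g: templates.pigment_absorbance(lam, g)

    # clean control
    o, r = scans_from_fraction(template, 0.02)
    fixtures.append({"record": MSPRecord("clean", "bF", "popA", "MWS", o, r,
                                         morphology="single cone"),
                     "expected_failure": None})

    # transverse density at/below 0.01 (criterion is strictly greater-than)
    o, r = scans_from_fraction(template, 0.01)
    fixtures.append({"record": MSPRecord("low_density", "bF", "popA", "MWS", o, r,
                                         morphology="single cone"),
                     "expected_failure": "transverse_density"})

    # inflated right-limb SD: alternate limb samples follow templates
    # displaced +/- delta, leaving the mean (and the 50-point estimate)
    # essentially unchanged
    delta = 30.0
    def jagged(grid):
        t_hi = templates.pigment_absorbance(lam + delta, grid)
        t_lo = templates.pigment_absorbance(lam - delta, grid)
        base = templates.pigment_absorbance(lam, grid)
        out = np.array(base, copy=True)
        on_limb = grid > lam + 4
        alt = (np.round((grid - 350.5) / 2.0).astype(int) % 2 == 0)
        out = np.where(on_limb & alt, t_hi, out)
        out = np.where(on_limb & ~alt, t_lo, out)
        return out
    o, r = scans_from_fraction(jagged, 0.02)
    fixtures.append({"record": MSPRecord("jagged_limb", "bF", "popA", "MWS", o, r,
                                         morphology="single cone"),
                     "expected_failure": "sd_right_limb"})

    # distorted short limb: long limb follows the true template but the
    # short side is depressed to the short limb of a template displaced
    # 40 nm long-ward, dragging the 50-point estimate away from the
    # 20-point one while leaving the peak, density and limb SD intact
    shift = 40.0
    def distorted(grid):
        base = templates.pigment_absorbance(lam, grid)
        shifted = templates.pigment_absorbance(lam + shift, grid)
        return np.where(grid < lam, np.minimum(base, shifted), base)
    o, r = scans_from_fraction(distorted, 0.02)
    fixtures.append({"record": MSPRecord("distorted_short", "bF", "popA", "MWS", o, r,
                                         morphology="single cone"),
                     "expected_failure": "method_difference"})

    # relaxed-regime record that fails to bleach (post scan == pre scan)
    o, r = scans_from_fraction(lambda g: templates.pigment_absorbance(450.0, g), 0.02)
    post = SpectralScan(RETURN_GRID.copy(), np.array(r.absorbance), "return")
    fixtures.append({"record": MSPRecord("unbleachable", "bF", "popA", "SWS", o, r,
                                         post_bleach=post, morphology="single cone"),
                     "expected_failure": "bleach_confirmed"})
    return fixtures


# ---------------------------------------------------------------------------
# file emission (the formats the reader side consumes)

def write_study(study: SyntheticStudy, out_dir) -> Path:
    """Write scans, manifests and ground truth as delimited text files."""
    from . import io as msp_io

    out = Path(out_dir)
    scans = out / "scans"
    scans.mkdir(parents=True, exist_ok=True)
    cell_rows = []
    for rec in study.records:
        paths = {}
        for tag, scan in (("outward", rec.outward), ("return", rec.return_),
                          ("postbleach", rec.post_bleach)):
            if scan is None:
                paths[tag] = ""
                continue
            p = scans / f"{rec.cell_id}_{tag}.tsv"
            msp_io.write_scan(p, scan)
            paths[tag] = str(p.relative_to(out))
        cell_rows.append({
            "cell_id": rec.cell_id, "bird_id": rec.bird_id,
            "population": rec.population, "putative_class": rec.putative_class,
            "morphology": rec.morphology, "outward_path": paths["outward"],
            "return_path": paths["return"],
            "postbleach_path": paths["postbleach"]})
    pd.DataFrame(cell_rows).to_csv(out / "cells_manifest.tsv", sep="\t",
                                   index=False)

    droplet_rows = []
    for d in study.droplets:
        p = scans / f"{d.droplet_id}_spectrum.tsv"
        msp_io.write_merged(p, d.spectrum)
        droplet_rows.append({
            "droplet_id": d.droplet_id, "bird_id": d.bird_id,
            "population": d.population, "droplet_type": d.droplet_type,
            "spectrum_path": str(p.relative_to(out))})
    pd.DataFrame(droplet_rows).to_csv(out / "droplets_manifest.tsv", sep="\t",
                                      index=False)

    study.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    meta = {"seed": study.design.seed, "design": _design_to_dict(study.design)}
    (out / "design.json").write_text(json.dumps(meta, indent=2))
    return out


def _design_to_dict(design: StudyDesign) -> dict:
    d = asdict(design)
    return d


def design_from_dict(d: dict) -> StudyDesign:
    d = dict(d)
    d["pigment_classes"] = {k: PigmentClassDesign(**v)
                            for k, v in d.get("pigment_classes", {}).items()}
    d["droplet_classes"] = {k: DropletClassDesign(**v)
                            for k, v in d.get("droplet_classes", {}).items()}
    return StudyDesign(**d)
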