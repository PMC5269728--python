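"""Predicted single-cone spectral sensitivity curves.

Each single-cone class pairs a visual pigment with the oil droplet sitting
in its optical path: LWS-R, MWS-Y, SWS-C and UVS-T.  The T-type droplet
has no measurable absorbance, so the UVS curve is the bare pigment
template.  Sensitivity is the pointwise product of pigment absorbance and
droplet transmittance, normalized either to unit peak ("peak") or scaled
by user-supplied cone abundance ratios ("ratio").

Double cones and the P-type droplet are excluded from the model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import templates
from .exceptions import ContractViolation

CONE_DROPLET_PAIRING = {"LWS": "R", "MWS": "Y", "SWS": "C", "UVS": "T"}
CONE_CLASSES = ("UVS", "SWS", "MWS", "LWS")


@dataclass
class ConeSpec:
    lambda_max: float
    lambda_cut: Optional[float]  # None for the transparent T-type pairing


@dataclass
class EyeModelSpec:
    cones: dict[str, ConeSpec]
    cone_ratios: Optional[dict[str, float]] = None
    grid: np.ndarray = field(
        default_factory=lambda: np.arange(330.0, 751.0, 1.0))
    filter_mid_offset: float = 10.0
    filter_mid_slope: float = 1.0
    filter_b_mid: float = 0.08
    include_beta: bool = True

    def __post_init__(self):
        if self.cone_ratios is not None:
            for cls, w in self.cone_ratios.items():
                if w <= 0:
                    raise ContractViolation(f"cone ratio for {cls} must be > 0")


def cone_sensitivity(spec: EyeModelSpec, cone_class: str,
                     normalization: str = "peak") -> np.ndarray:
    """Sensitivity curve for one cone class on the spec's grid."""
    if cone_class not in spec.cones:
        raise ContractViolation(f"cone class {cone_class!r} not in model spec")
    cone = spec.cones[cone_class]
    pigment = templates.pigment_absorbance(
        cone.lambda_max, spec.grid, include_beta=spec.include_beta)
    needs_filter = CONE_DROPLET_PAIRING.get(cone_class) != "T"
    if needs_filter:
        if cone.lambda_cut is None or not np.isfinite(cone.lambda_cut):
            raise ContractViolation(
                f"{cone_class} requires a droplet lambda_cut "
                f"({CONE_DROPLET_PAIRING.get(cone_class)}-type)")
        filt = templates.droplet_filter_from_cut(
            cone.lambda_cut, mid_offset=spec.filter_mid_offset,
            mid_slope=spec.filter_mid_slope, b_mid=spec.filter_b_mid)
        curve = pigment * templates.droplet_transmittance(filt, spec.grid)
    else:
        curve = np.asarray(pigment, dtype=float)
    if normalization == "peak":
        peak = curve.max()
        if peak > 0:
            curve = curve / peak
    elif normalization == "ratio":
        if spec.cone_ratios is None:
            raise ContractViolation(
                "ratio normalization requires cone_ratios in the model spec")
        peak = curve.max()
        if peak > 0:
            curve = curve / peak
        total = sum(spec.cone_ratios.values())
        curve = curve * (spec.cone_ratios.get(cone_class, 0.0) / total)
    else:
        raise ContractViolation(f"unknown normalization {normalization!r}")
    return curve


def model_curves(spec: EyeModelSpec, normalization: str = "peak") -> pd.DataFrame:
    """All cone curves as one table (wavelength + one column per class)."""
    out = {"wavelength_nm": spec.grid}
    for cls in CONE_CLASSES:
        if cls in spec.cones:
            out[cls] = cone_sensitivity(spec, cls, normalization)
    return pd.DataFrame(out)


def population_eye_models(pigment_report: pd.DataFrame,
                          droplet_report: pd.DataFrame, *,
                          cone_ratios: Optional[dict[str, float]] = None,
                          grid: Optional[np.ndarray] = None,
                          normalization: str = "peak",
                          include_beta: bool = True
                          ) -> dict[str, tuple[EyeModelSpec, pd.DataFrame]]:
    """Build one eye model per population from comparison-report tables.

    Uses each population's estimated marginal mean (falling back to the
    raw mean) for pigment lambda_max and droplet lambda_cut.  Cone classes
    whose pigment or droplet mean is unavailable are omitted with a
    warning column left out, not fabricated.
    """
    def mean_for(df, type_name, pop):
        sub = df[df["type"] == type_name]
        if not len(sub):
            return None
        row = sub.iloc[0]
        for col in (f"emm_{pop}", f"mean_{pop}"):
            if col in row and np.isfinite(row[col]):
                return float(row[col])
        return None

    pops = sorted({c[len("mean_"):] for c in pigment_report.columns
                   if c.startswith("mean_")})
    models = {}
    for pop in pops:
        cones = {}
        for cls in CONE_CLASSES:
            lam = mean_for(pigment_report, cls, pop)
            if lam is None:
                continue
            droplet_type = CONE_DROPLET_PAIRING[cls]
            cut = None
            if droplet_type != "T":
                cut = mean_for(droplet_report, droplet_type, pop)
                if cut is None:
                    continue
            cones[cls] = ConeSpec(lambda_max=lam, lambda_cut=cut)
        spec = EyeModelSpec(cones=cones, cone_ratios=cone_ratios,
                            include_beta=include_beta)
        if grid is not None:
            spec.grid = np.asarray(grid, dtype=float)
        models[pop] = (spec, model_curves(spec, normalization))
    return models
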