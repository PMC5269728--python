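"""Pipeline configuration: one flat, schema-validated set of tunables.

Loaded from YAML; unknown keys are rejected so typos cannot silently fall
back to defaults.  Every run writes the resolved configuration next to
its outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .exceptions import FormatError


@dataclass
class PipelineConfig:
    # normalization
    baseline_window: tuple[float, float] = (730.0, 750.0)
    peak_smoothing: int = 11
    refine_iterations: int = 2
    # primary / secondary estimators
    primary_window: tuple[float, float] = (0.10, 0.90)
    n_points_primary: int = 20
    n_points_secondary: int = 50
    include_beta: bool = True
    class_overrides: dict = field(default_factory=lambda: {
        "UVS": {"primary_window": (0.15, 0.95), "n_points_primary": 15},
    })
    # QC thresholds (strict inequalities, as printed)
    min_density: float = 0.01
    max_limb_sd: float = 12.0
    max_method_diff: float = 6.0
    # bleach verification
    peak_drop_fraction: float = 0.5
    shortwave_max: float = 420.0
    # droplets
    tangent_samples: int = 5
    # statistics
    df_method: str = "satterthwaite"
    alpha: float = 0.05
    holm_correction: bool = False
    # eye model
    normalization_mode: str = "peak"
    cone_ratios: dict | None = None
    filter_mid_offset: float = 10.0
    filter_mid_slope: float = 1.0
    filter_b_mid: float = 0.08
    # misc
    mask_populations: bool = False
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["baseline_window"] = list(d["baseline_window"])
        d["primary_window"] = list(d["primary_window"])
        return yaml.safe_dump(d, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_yaml())


_FIELD_NAMES = {f.name for f in fields(PipelineConfig)}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a config file (YAML), apply overrides, validate keys."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("baseline_window", "primary_window"):
        if key in data and data[key] is not None:
            val = tuple(float(x) for x in data[key])
            if len(val) != 2:
                raise FormatError(f"{key} must have exactly two numbers")
            data[key] = val
    if "class_overrides" in data and data["class_overrides"]:
        for cls, ov in data["class_overrides"].items():
            if "primary_window" in ov:
                ov["primary_window"] = tuple(float(x)
                                             for x in ov["primary_window"])
    return PipelineConfig(**data)
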