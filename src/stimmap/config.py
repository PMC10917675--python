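"""Analysis configuration: every threshold and seed in one place.

Defaults carry the published parameter set: 200 V/m magnitude threshold
with 50% coverage for the voxel mask, 800 V/m in >0.5% of fields for
candidate streamlines, top-1% sweet threshold, weighted peak-5%
scoring, fivefold cross-validation with 5,000 permutations, 0.5 mm
sampling step, and 2 mm / 8 mm FWHM smoothing for subthalamic and
cortical visualisation maps.

Precedence is CLI flag > config file > default, and every run writes
the fully resolved configuration next to its outputs so deterministic
stages re-run bit-identically from that file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # sweet-spot mapping
    magnitude_threshold: float = 200.0   # V/m
    coverage_fraction: float = 0.5
    # pool bilateral fields onto one hemisphere for unilateral ROIs
    mirror: bool = True
    # fiber filtering
    candidate_magnitude: float = 800.0   # V/m (0.8 V/mm)
    candidate_fraction: float = 0.005
    sweet_top_fraction: float = 0.01
    score_peak_fraction: float = 0.05
    step_mm: float = 0.5
    # validation
    k: int = 5
    n_permutations: int = 5000
    # visualisation smoothing
    fwhm_subthalamic_mm: float = 2.0
    fwhm_cortical_mm: float = 8.0
    # simulation
    voxel_mm: float = 1.0
    n_patients: int = 60
    placement_jitter_mm: float = 1.5
    effect_size: float = 15.0
    noise_fraction: float = 0.15
    target_kind: str = "spot"
    # reproducibility
    seed: int = 0
    # paths
    cohort_csv: str | None = None
    efield_manifest: str | None = None
    streamlines: str | None = None
    out_dir: str = "stimmap_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def updated(self, **overrides) -> "AnalysisConfig":
        """Copy with non-None overrides applied (CLI precedence)."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)
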