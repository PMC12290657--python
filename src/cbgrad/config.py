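"""Structured configuration for the end-to-end pipeline.

Every analysis constant lives here (no hidden defaults): gradient step count,
WM threshold, z threshold, alpha, lobule lists, phantom scenario parameters
and the master seed.  Configs load from YAML and hash deterministically for
the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["AnalysisConfig", "EffectConfig"]


@dataclass
class EffectConfig:
    condition: str
    lobule: int
    centre_intrinsic: tuple[float, float, float]
    spatial_sd_mm: float = 3.0
    amplitude_pct: float = 1.5


def _default_effects() -> list[EffectConfig]:
    # planted scenario: MCFT deeper and more medial than SUFF
    return [
        EffectConfig("MCFT", 2, (0.25, 0.8, 0.5)),
        EffectConfig("SUFF", 2, (0.75, 0.4, 0.5)),
    ]


@dataclass
class AnalysisConfig:
    # phantom scenario
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_lobules: int = 3
    fold_count: int = 4
    band_thickness_vox: float = 8.0
    fold_amplitude_vox: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 8
    n_runs: int = 4
    run_length_s: float = 300.0
    tr_s: float = 3.3
    on_s: float = 20.0
    off_s: float = 10.0
    condition_order: tuple[str, ...] = ("MCFT", "SUFF")
    effects: list[EffectConfig] = field(default_factory=_default_effects)
    noise_sigma_pct: float = 1.0
    noise_ar1_rho: float = 0.0
    subject_amplitude_jitter_sd: float = 0.15   # lognormal SD of per-subject gain

    # analysis constants
    n_steps: int = 7
    wm_threshold: float = 0.99
    z_threshold: float = 3.1
    alpha: float = 0.05
    drift_order: int = 1
    target_lobules: tuple[int, ...] = (2,)
    superior_lobules: tuple[int, ...] = (1, 2)
    inferior_lobules: tuple[int, ...] = (3,)
    gradient_metric: str = "geodesic"

    # provenance
    master_seed: int = 0
    output_dir: str = "cbgrad_out"

    def __post_init__(self):
        if not (0.0 < self.wm_threshold < 1.0):
            raise ValueError("wm_threshold must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = [e if isinstance(e, EffectConfig) else EffectConfig(**{
                **e, "centre_intrinsic": tuple(e["centre_intrinsic"])}) for e in d["effects"]]
        for key in ("grid_shape", "voxel_size_mm", "target_lobules", "superior_lobules",
                    "inferior_lobules", "condition_order"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh, sort_keys=True)
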