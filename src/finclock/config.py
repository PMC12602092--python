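"""Pipeline configuration with the published filter thresholds as defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, validated on load.

    Defaults are the published analysis constants; ``min_sites`` in
    particular is a sequencing-scale threshold (400,000 observed CpG sites
    per individual) that must be lowered for synthetic-scale data.
    """

    # QC
    snp_threshold: float = 0.05
    min_sites: int = 400_000
    presence_frac: float = 0.80
    ci_max_width: float = 0.85
    ci_min_frac: float = 0.80
    # screen
    screen_engine: str = "laplace"
    mcmc_chains: int = 4
    mcmc_iterations: int = 4000
    mask_max_width: float = 0.85
    # environment removal
    n_perm: int = 9999
    max_pcs: int = 300
    cv_reps: int = 50
    removal_fraction: float = 0.5
    alpha: float = 0.05
    max_removal_iter: int = 10
    holdout: float = 0.1
    focal_water_bodies: list[str] | None = None
    # clock
    train_frac: float = 0.8
    stratify_by_age_bin: bool = True
    top_k: int = 1000
    subset_size: int = 125
    iterations: int = 1000
    n_folds: int = 10
    n_lambda: int = 100
    cv_objective: str = "years_mae"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_threshold", "presence_frac", "ci_max_width", "ci_min_frac",
                     "removal_fraction", "alpha", "train_frac", "holdout"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be strictly inside (0, 1)")
        for name in ("min_sites",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_perm", "max_pcs", "cv_reps", "max_removal_iter", "top_k",
                     "subset_size", "iterations", "n_folds", "n_lambda",
                     "mcmc_chains", "mcmc_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.screen_engine not in ("laplace", "mcmc"):
            raise ValueError("screen_engine must be 'laplace' or 'mcmc'")
        if self.cv_objective not in ("years_mae", "ln_mae"):
            raise ValueError("cv_objective must be 'years_mae' or 'ln_mae'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of configuration keys")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
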