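"""Pipeline configuration, loadable from YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .mcmc import McmcSettings

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, reproducibly.

    ``series_paths`` are monthly (or daily) CSVs, one lake each;
    ``metadata_path`` optionally supplies coordinates and abstraction
    volumes for the cross-lake statistics.  A seed is mandatory.
    """

    series_paths: list[str]
    out_dir: str
    seed: int
    metadata_path: str | None = None
    ks: tuple[int, ...] = (0, 1, 2, 3)
    selection_threshold: float = 4.0
    coef_prior: str = "precision"
    percent_change_method: str = "exact"
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        if self.selection_threshold <= 0:
            raise ValueError("selection threshold must be positive")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if not set(self.ks).issubset({0, 1, 2, 3}):
            raise ValueError("requested K values must be within {0, 1, 2, 3}")
        if isinstance(self.mcmc, dict):
            self.mcmc = McmcSettings(**{**self.mcmc, "seed": self.mcmc.get("seed", self.seed)})

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)
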