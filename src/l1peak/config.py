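"""Run configuration: one YAML document, one master seed.

Per-stage randomness is derived from the master seed through
``numpy.random.SeedSequence`` so the whole pipeline is reproducible from a
single integer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from .synth import SimulationConfig


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "new"
    genome_length: int = 5_000_000
    gc_fraction: float = 0.41
    n_genes: int = 120
    n_KR: int = 5
    n_KNR: int = 5
    n_novel: int = 40
    germline_fraction: float = 1.0
    mosaic_fraction_low: float = 0.05
    mosaic_fraction_high: float = 0.5
    depth_per_insertion: int = 20
    duplicate_rate: float = 0.2
    base_error_rate: float = 0.002
    noise_read_fraction: float = 0.02
    peak_window: int = 64
    proximity_window: int = 500
    promoter_window: int = 500
    merge_window: int = 100
    detect_min_reads: int = 2
    truth_match_window: int = 100
    n_terms: int = 30
    include_overlap: bool = True

    def __post_init__(self) -> None:
        if self.profile not in ("original", "new"):
            raise ValueError(f"unknown filter profile {self.profile!r}")

    def stage_seeds(self) -> Dict[str, int]:
        """Stable per-stage seeds derived from the master seed."""
        names = ["genome", "annotations", "insertions", "reads", "terms"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {
            name: int(child.generate_state(1)[0])
            for name, child in zip(names, children)
        }

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            genome_length=self.genome_length,
            gc_fraction=self.gc_fraction,
            n_genes=self.n_genes,
            n_KR=self.n_KR,
            n_KNR=self.n_KNR,
            n_novel=self.n_novel,
            germline_fraction=self.germline_fraction,
            mosaic_fraction_range=(self.mosaic_fraction_low, self.mosaic_fraction_high),
            depth_per_insertion=self.depth_per_insertion,
            duplicate_rate=self.duplicate_rate,
            base_error_rate=self.base_error_rate,
            noise_read_fraction=self.noise_read_fraction,
            seed=self.stage_seeds()["reads"],
        )

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
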