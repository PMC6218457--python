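"""Structured run configuration with strict key checking."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, fields
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Flat configuration for the end-to-end pipeline.

    Unknown keys are rejected, every run echoes its effective config, and
    the same config + seed reproduces a run byte-for-byte.
    """

    # paths
    swc_dir: str = "swc"
    atlas_volume: str = "atlas.nrrd"
    ontology: str = "ontology.csv"
    output_dir: str = "out"
    ground_truth_dir: str = "ground_truth"

    # parameters
    step_um: Optional[float] = None  # None -> smallest voxel edge
    min_contra_mm: float = 1.0
    theta: float = 0.05
    jaccard_cutoff: float = 0.5
    level: Union[int, List[str]] = 1  # ontology depth or acronym list
    downsample_factors: Tuple[int, int, int] = (1, 1, 1)
    seed: int = 0
    cc_acronym: str = "cc"
    # demo population composition: regime -> neuron count
    population: Dict[str, int] = field(
        default_factory=lambda: {"mos_l5": 6, "mos_l23": 17, "pl_l23": 6, "orbm_l23": 7}
    )

    # flags
    welch: bool = False
    include_background_in_denominator: bool = True

    def __post_init__(self):
        if self.step_um is not None and self.step_um <= 0:
            raise ConfigError("step_um must be positive")
        if self.min_contra_mm < 0:
            raise ConfigError("min_contra_mm must be >= 0")
        if not (0 <= self.theta <= 1):
            raise ConfigError("theta must lie in [0, 1]")
        if not (0 <= self.jaccard_cutoff <= 1):
            raise ConfigError("jaccard_cutoff must lie in [0, 1]")
        self.downsample_factors = tuple(int(v) for v in self.downsample_factors)
        if len(self.downsample_factors) != 3 or any(v < 1 for v in self.downsample_factors):
            raise ConfigError("downsample_factors must be three integers >= 1")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["downsample_factors"] = list(self.downsample_factors)
        return d

    def dump_json(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
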