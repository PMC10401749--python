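"""YAML run configuration for the command-line interface.

All workflow constants are surfaced as named keys with their standard
defaults: the 0.70 het-SNP retention fraction, the 1:5 variant:reference
training ratio, the 0.10 validation split, the 50/100 stratification channel
coding, and the 3x3 coverage grid over {10, 20, 30}x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .fullalign import CoverageGrid
from .pipeline import Thresholds, default_thresholds
from .simdata import DEFAULT_PROFILES, PlatformErrorProfile, SimConfig


@dataclass
class RunConfig:
    """Everything a CLI run needs, with seed propagation to every stage."""

    platforms: List[str] = field(default_factory=lambda: ["illumina", "ont"])
    coverage: Dict[str, float] = field(
        default_factory=lambda: {"illumina": 30.0, "ont": 30.0})
    sim: SimConfig = field(default_factory=SimConfig)
    profiles: Dict[str, PlatformErrorProfile] = field(default_factory=dict)
    thresholds: Dict[str, Thresholds] = field(default_factory=dict)
    retain_fraction: float = 0.70
    ratio_ref_per_var: int = 5
    val_fraction: float = 0.10
    coverage_grid: Optional[List[Tuple[float, float]]] = None
    use_stratification: bool = False
    pileup_epochs: int = 30
    fullalign_epochs: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 1 <= len(self.platforms) <= 2:
            raise ValueError("calling supports exactly 1 or 2 platforms")
        for p in self.platforms:
            self.profiles.setdefault(
                p, DEFAULT_PROFILES.get(p, DEFAULT_PROFILES["illumina"]))
            self.thresholds.setdefault(p, default_thresholds(p))
            self.coverage.setdefault(p, 30.0)

    def grid(self) -> CoverageGrid:
        if self.coverage_grid is None:
            return CoverageGrid()
        return CoverageGrid(tuple(tuple(p) for p in self.coverage_grid))


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    sim_data = data.pop("sim", {})
    prof_data = data.pop("profiles", {})
    th_data = data.pop("thresholds", {})
    seed = data.get("seed", 0)
    cfg = RunConfig(
        sim=SimConfig(**{**sim_data, "seed": sim_data.get("seed", seed)}),
        profiles={k: PlatformErrorProfile(label=k, **v)
                  for k, v in prof_data.items()},
        thresholds={k: Thresholds(**v) for k, v in th_data.items()},
        **data)
    return cfg
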