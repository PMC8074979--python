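"""Pipeline-wide thresholds with their field-standard defaults.

Every analysis stage takes its tunables from a :class:`PipelineConfig` so a
whole run is reproducible from one record.  Defaults follow common practice
for low-coverage whale resequencing panels: MAF >= 0.05, sites covered in at
least half the individuals, 100-kb F_ST windows with at least 500 usable
sites, 1-Mb jackknife blocks, LD pruning within 20 kb at r^2 >= 0.5, and a
23.4-year generation time for converting coalescent population sizes into
numbers of females.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    min_maf: float = 0.05
    min_ind_fraction: float = 0.5
    window_bp: int = 100_000
    min_sites_per_window: int = 500
    block_bp: int = 1_000_000
    ld_max_kb: float = 20.0
    ld_min_weight: float = 0.5
    reticulation_tolerance: float = 0.1
    min_consensus_depth: int = 5
    min_scaffold_bp: int = 1000
    generation_time_years: float = 23.4
    # Documentation only: the mitochondrial clock rate used by time-calibrated
    # analyses outside this package (substitutions/site/Myr).
    clock_rate_subs_per_site_per_myr: float = 0.0038

    def __post_init__(self):
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0 < self.min_ind_fraction <= 1:
            raise ValueError("min_ind_fraction must be in (0, 1]")
        for name in ("window_bp", "min_sites_per_window", "block_bp",
                     "min_consensus_depth", "min_scaffold_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ld_max_kb <= 0 or not 0 <= self.ld_min_weight <= 1:
            raise ValueError("invalid LD pruning parameters")
        if self.reticulation_tolerance < 0:
            raise ValueError("reticulation_tolerance must be >= 0")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
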