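"""Run configuration: every tunable threshold in one structured document.

Defaults are the study conditions of the categorization methodology
(chain-length threshold 7, between-category 15th percentile, two
subcategorization generations, 3 MaxMin picks for categories above 5
members, 10-member miscellaneous aggregation, and the solubility/volatility
cutoffs). A resolved copy is written beside every run's outputs so
deviations are visible diffs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # categorization
    chain_threshold: int = 7
    hybrid_membership_threshold: int = 300
    min_secondary_count: int = 5
    max_chain: int = 30
    # similarity / subcategorization
    percentile: float = 15.0
    max_generations: int = 2
    split_on_tie: bool = False
    cut_fraction: float = 0.7
    # selection
    maxmin_k: int = 3
    min_category_for_maxmin: int = 5
    coverage_targets: tuple[float, ...] = (0.5, 0.8)
    # annotation
    ws_soluble_mgl: float = 0.5
    vp_volatile_mmhg: float = 75.0
    hlc_highly_volatile: float = 0.1
    # enrichment
    enrichment_or: float = 3.0
    enrichment_p: float = 0.05
    enrichment_tp: int = 3
    # classifier
    misc_min_size: int = 10
    # run
    seed: int = 0
    outdir: str = "pfascat_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "coverage_targets" in data:
            data["coverage_targets"] = tuple(data["coverage_targets"])
        return cls(**data)
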