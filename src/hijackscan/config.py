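"""Run configuration for the disruption-detection pipeline.

The defaults are the published screen's constants: ±50 bp breakpoint flank,
primary expression deviation > 2×IQR with normalized expression > 10,
recurrence in at least one additional donor at > 1×IQR, survival screen at
BH-corrected padj < 0.05, and 10% extreme-decile grouping for the
concordance stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

DISRUPTION_MODES = ("span", "anchor")
DONOR_SCOPES = ("sv_donors", "all_donors")
ANCHOR_MATCH_MODES = ("shared", "any")


@dataclass
class PipelineConfig:
    flank_bp: int = 50
    k_primary: float = 2.0
    k_recurrence: float = 1.0
    min_norm_expr: float = 10.0
    #: total donors required per candidate, the primary donor included
    min_recurrent_donors: int = 2
    padj_threshold: float = 0.05
    decile_fraction: float = 0.10
    disruption_mode: str = "span"
    stats_donor_scope: str = "sv_donors"
    #: restrict outlier calls to upregulation; two-sided by default
    directional: bool = False
    #: recurrence requires a shared disrupted PIR anchor ("shared") or any
    #: disrupted interaction of the same gene ("any")
    anchor_match: str = "shared"
    #: median-split survival donors within each cohort, then pool for log-rank
    split_by_cohort: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not (self.k_primary >= self.k_recurrence >= 0):
            raise ValueError("require k_primary >= k_recurrence >= 0")
        if self.min_norm_expr <= 0 or self.padj_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_recurrent_donors < 1:
            raise ValueError("min_recurrent_donors must be >= 1")
        if not (0 < self.decile_fraction <= 0.5):
            raise ValueError("decile_fraction must lie in (0, 0.5]")
        if self.disruption_mode not in DISRUPTION_MODES:
            raise ValueError(f"disruption_mode must be one of {DISRUPTION_MODES}")
        if self.stats_donor_scope not in DONOR_SCOPES:
            raise ValueError(f"stats_donor_scope must be one of {DONOR_SCOPES}")
        if self.anchor_match not in ANCHOR_MATCH_MODES:
            raise ValueError(f"anchor_match must be one of {ANCHOR_MATCH_MODES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
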