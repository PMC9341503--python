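"""Pipeline configuration.

Every default equals the published procedural value: 1-kb gap skipping, the
element size thresholds, majority consensus support, 100-kb proximity bins up
to 5 Mb, 1-kb control promoters, the 10% active-background exclusivity
threshold, alpha = 0.05, 2.5-kb motif windows with a 200-motif threshold, and
the relocation verdict thresholds (donor loss < 0.10, acceptor gain >= 0.50).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    # interval/consensus parameters
    merge_gap: int = 1000              # merge runs skipping gaps < 1 kb
    min_support: float = 0.5           # consensus majority support
    # element size thresholds (bp)
    bd_genomewide_min: int = 2000      # broad domain, strict >
    bd_locus_min: int = 15000          # locus broad-domain scan, inclusive
    se_genomewide_min: int = 5000      # super-enhancer, strict >
    se_locus_min: int = 2500           # locus super-enhancer, strict >
    promoter_min: int = 2500           # broad promoter, strict >
    # co-occurrence parameters
    bin_width: int = 100_000
    max_distance: int = 5_000_000
    control_width: int = 1000
    exclusivity_threshold: float = 0.10
    alpha: float = 0.05
    # motif parameters
    motif_window: int = 2500
    motif_threshold: int = 200
    motif_step: int = 2500
    strand_mode: str = "forward"
    # relocation detector thresholds
    donor_loss_threshold: float = 0.10
    acceptor_gain_threshold: float = 0.50
    neighbor_flank: int = 500_000
    # run parameters
    seed: int = 0
    template: str = "toy"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
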