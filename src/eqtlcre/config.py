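"""Pipeline configuration: every tunable named in the design, with one seed.

Unknown keys in a YAML config are rejected so silent typos cannot change an
analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # synthetic-data scale (the package's default study conditions)
    n_genes: int = 200
    n_snps_per_gene: int = 50
    n_samples: int = 200
    snp_spacing: int = 2000
    hotspot_every: int = 10
    hotspot_rate: float = 2.0
    background_recomb_rate: float = 0.1
    maf_low: float = 0.05
    maf_high: float = 0.5
    within_block_r2: float = 0.8
    eqtl_fraction: float = 0.5
    two_tier_fraction: float = 0.25
    effect_size: float = 0.7
    effect_r2: float | None = 0.15
    n_confounders: int = 3
    confounder_var_frac: float = 0.3
    noise_sd: float = 1.0
    cre_specific_fraction: float = 0.3
    cre_eqtl_enrichment: float = 3.0
    cre_background_rate: float = 0.15
    missing_fraction: float = 0.02
    n_gwas: int = 200

    # preprocessing
    pve_delta: float = 0.01
    knn_k: int = 10
    max_probe_clusters: int = 3

    # association / tiering / FDR
    prior_sigma_a: tuple = (0.05, 0.1, 0.2, 0.4)
    rate_threshold: float = 0.9
    max_tiers: int = 4
    fdr_target: float = 0.1
    n_perm: int = 1

    # replication / overlap
    replication_bf_threshold: float = 1.0
    maf_min: float = 0.05
    pad: int = 500
    n_bins: int = 30

    # classifier
    n_trees: int = 500
    cv_folds: int = 10

    # global seed: every stochastic stage derives its own stream from this
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "prior_sigma_a" in raw:
            raw["prior_sigma_a"] = tuple(raw["prior_sigma_a"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior_sigma_a"] = list(d["prior_sigma_a"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
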