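"""Pipeline configuration: every numeric threshold in one validated record.

Defaults mirror the analysis conventions the pipeline implements: 2 Mb
autosomal region floor, mean-ploidy-1.5 haploid cut, 1-SD ploidy filter,
k = 30 kNN with adaptive bandwidth at ceil(k/3), 30 principal components,
20% mitochondrial ceiling, 20 UMI/gene and 100 UMI/cell floors for the
dosage model, 0.9 assignment threshold (with per-sample overrides down to
0.5 for low-confidence samples), 0.10 log-fold-change floor, 1000-cell
visualization subsample, and a +-300 cap on the signed rank statistic.

A single global seed fans out to per-stage child seeds through a fixed
registry, so no computation path touches wall-clock or OS entropy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from math import ceil

import numpy as np
import yaml

STAGES = (
    "simulate",
    "cnv_clones",
    "pseudobulk",
    "gene_cn",
    "assign_clones",
    "phenodist",
    "subtype",
    "diffrank",
)


@dataclass
class PipelineConfig:
    region_min_bp: int = 2_000_000
    haploid_ploidy_cut: float = 1.5
    ploidy_sd_mult: float = 1.0
    min_variant_fraction: float = 0.10
    min_clone_size: int = 20
    knn_k: int = 30
    knn_ka: int | None = None  # None -> ceil(k/3)
    n_pcs: int = 30
    n_components: int = 10
    mito_max: float = 0.20
    min_gene_umi: int = 20
    min_cell_umi: int = 100
    assign_threshold: float = 0.9
    assign_threshold_overrides: dict = field(default_factory=dict)
    min_lfc: float = 0.10
    subsample_n: int = 1000
    rank_cap: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.region_min_bp >= 0, "region_min_bp must be >= 0"),
            (self.haploid_ploidy_cut > 0, "haploid_ploidy_cut must be positive"),
            (self.ploidy_sd_mult >= 0, "ploidy_sd_mult must be >= 0"),
            (0 <= self.min_variant_fraction <= 1, "min_variant_fraction in [0,1]"),
            (self.min_clone_size >= 1, "min_clone_size must be >= 1"),
            (self.knn_k >= 1, "knn_k must be >= 1"),
            (self.n_pcs >= 1, "n_pcs must be >= 1"),
            (0 < self.mito_max <= 1, "mito_max in (0,1]"),
            (0 < self.assign_threshold <= 1, "assign_threshold in (0,1]"),
            (self.min_lfc >= 0, "min_lfc must be >= 0"),
            (self.subsample_n >= 1, "subsample_n must be >= 1"),
            (self.rank_cap > 0, "rank_cap must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        for sample, t in self.assign_threshold_overrides.items():
            if not 0 < t <= 1:
                raise ValueError(f"assign threshold override for {sample!r} outside (0,1]")

    @property
    def ka(self) -> int:
        return self.knn_ka if self.knn_ka is not None else ceil(self.knn_k / 3)

    def threshold_for(self, sample: str) -> float:
        return self.assign_threshold_overrides.get(sample, self.assign_threshold)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the global seed."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([int(self.seed), STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        """Comment lines serialized verbatim into every output file."""
        items = ", ".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return [f"# occultclone config_hash={self.config_hash()}", f"# {items}"]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
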