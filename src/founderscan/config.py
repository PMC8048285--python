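"""Declarative analysis configuration.

Every threshold of the filtering and scanning pipeline is a named field;
the defaults are the canonical values the pipeline was designed around
(DP >= 5, <= 90% per-sample missingness, >= 80% call rate, minor-allele
count >= 2, exact-HWE alpha 0.05, 10,000 permutations, Z > 5 outliers,
100-kb windows, +-50-kb flanks, 30-nt minimal ORFs).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    min_depth: int = 5
    max_sample_missing: float = 0.90
    min_call_rate: float = 0.80
    maf_mode: str = "count"  # 'count' (copies >= min_minor_copies) or 'frequency'
    min_minor_copies: int = 2
    min_maf: float = 0.025
    hwe_alpha: float = 0.05
    hwe_ordering: str = "lr"
    n_permutations: int = 10_000
    randomization_unit: str = "chromosome"  # or 'snp'
    z_threshold: float = 5.0
    window_bp: int = 100_000
    flank_bp: int = 50_000
    min_orf_len: int = 30
    knn_k: int = 10
    knn_quantile: float = 0.999
    reference_population: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
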