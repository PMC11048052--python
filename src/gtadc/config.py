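"""Run configuration: every tunable constant of the pipeline with its default.

The config is a flat dataclass serialized verbatim into the run manifest, so
a finished run documents exactly which knobs produced it. A YAML file with a
subset of keys overrides the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .gat import GATConfig


@dataclass
class RunConfig:
    # io / preprocessing
    min_rate: float = 0.20           # QC: min per-type detection rate to keep a gene
    target_sum: float = 1e4          # counts-per-10k row normalization
    log1p: bool = True

    # marker selection
    t: int = 20                      # markers kept per type after silhouette re-ranking
    l: int | None = None             # top-mean cut; None → min(s, 1000)
    e: float = 1.0                   # dispersion rate-term exponent
    per_type_candidates: int | None = None   # None → 3·t
    min_genes: int = 200             # threshold-filter fallback floor
    max_cells_per_type: int = 500    # silhouette subsample cap

    # pseudo-spots
    n_pseudo_spots: int | None = None  # None → 5 × number of real spots
    min_cells: int = 2
    max_cells: int = 8

    # integration
    use_integration: bool = True
    d: int = 30
    n_neighbors: int = 15
    feature_space: str = "embedding"   # or "expression": corrected marker expression

    # graph
    n_trees: int = 10
    leaf_size: int = 40

    # GAT
    gat: GATConfig = field(default_factory=GATConfig)

    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.gat, dict):
            self.gat = GATConfig(**self.gat)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
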