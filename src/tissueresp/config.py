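"""Pipeline configuration: a flat, validated key-value structure.

Loaded from YAML; unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import DEFAULT_TISSUES


@dataclass
class PipelineConfig:
    # design
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    focal_tissue: str = "intestine"
    # expression filter
    min_rpkm: float = 1.0
    min_reads: int = 5
    # responder thresholds
    sr_threshold: float = 1.0
    min_tissues: int = 4
    min_focal_sr: float = 2.0
    dominance_ratio: float = 2.0
    # enrichment
    p_cut: float = 0.05
    q_cut: float = 0.05
    background: str = "annotated"  # annotated | all
    # clustering
    top_n: int = 400
    metric: str = "uncentered-correlation"
    linkage: str = "average"
    k_clusters: int = 5
    mean_center_rows: bool = False
    # inputs / outputs
    gtf: str | None = None
    counts: str | None = None
    totals: str | None = None
    rpkm: str | None = None
    orthologs: str | None = None
    gene2ensembl: str | None = None
    gene2go: str | None = None
    out_dir: str = "results"
    # misc
    seed: int = 0
    quiet: bool = False

    def __post_init__(self):
        self.tissues = tuple(self.tissues)
        checks = [
            (self.min_rpkm >= 0, "min_rpkm must be >= 0"),
            (self.min_reads >= 0, "min_reads must be >= 0"),
            (self.sr_threshold > 0, "sr_threshold must be > 0"),
            (1 <= self.min_tissues <= len(self.tissues),
             "min_tissues must be within the tissue count"),
            (self.min_focal_sr > 0, "min_focal_sr must be > 0"),
            (self.dominance_ratio >= 1, "dominance_ratio must be >= 1"),
            (0 < self.p_cut <= 1, "p_cut must be in (0, 1]"),
            (0 < self.q_cut <= 1, "q_cut must be in (0, 1]"),
            (self.background in ("annotated", "all"),
             "background must be 'annotated' or 'all'"),
            (self.top_n >= 2, "top_n must be >= 2"),
            (self.metric in ("uncentered-correlation",
                             "centered-correlation", "euclidean"),
             f"unknown metric {self.metric!r}"),
            (self.linkage == "average", "only average linkage is supported"),
            (self.k_clusters >= 1, "k_clusters must be >= 1"),
            (self.focal_tissue in self.tissues,
             f"focal_tissue {self.focal_tissue!r} not in tissues"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out
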