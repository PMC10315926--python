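"""Pipeline configuration and logging setup.

PipelineConfig gathers every tunable of the end-to-end analysis with the
study's printed settings as defaults (alpha = 0.05, fold-change threshold
1.3, >= 2 replicates, enrichment p < 0.05 and factor > 1.5, network
membership in >= 2 mutants).  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("tmtpanel")


def setup_logging(verbose: bool = False, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        Path(logfile).parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(logfile, mode="w"))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis."""

    # inputs (None -> simulate them)
    protein_groups: list[str] = field(default_factory=list)
    design: str | None = None
    annotation: str | None = None
    prm: str | None = None
    protein_ratio: float = 1.5  # Western-derived total-protein ratio A/B

    # statistical settings (study defaults)
    alpha: float = 0.05
    fc_threshold: float | None = 1.3  # None -> derive from target_fdr
    target_fdr: float = 0.045
    min_replicates: int = 2
    min_mutants: int = 2
    enrich_alpha: float = 0.05
    enrich_min_ef: float = 1.5

    # method switches
    aggregate: str = "mean"  # mean | median replicate aggregation
    zscore_axis: str = "protein"
    correlation_on: str = "log_intensity"
    linkage_rule: str = "average"
    cluster_distance: str = "euclidean"
    bh: bool = False
    cluster_on_deps: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold is not None and self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if not (0.0 < self.target_fdr < 1.0):
            raise ValueError("target_fdr must lie in (0, 1)")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be at least 1")
        if self.min_mutants < 1:
            raise ValueError("min_mutants must be at least 1")
        if not (0.0 < self.enrich_alpha < 1.0):
            raise ValueError("enrich_alpha must lie in (0, 1)")
        if self.enrich_min_ef < 0:
            raise ValueError("enrich_min_ef must be non-negative")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
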