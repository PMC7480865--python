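"""Pipeline configuration: defaults, YAML loading, and provenance hashing.

Defaults equal the study design this pipeline implements: 50 replicates of
80/20 stratified splits per algorithm, quality gates AUC >= 0.8 and
TSS >= 0.7, AUC-weighted mean combination, 2,000-km spatial blocks in 5
folds, and threshold optimisation by the sensitivity/specificity trade-off.
Any override is echoed to the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import yaml

logger = logging.getLogger("podomap")

DEFAULT_ALGORITHMS = ["GLM", "GAM", "GBM", "ANN", "MARS", "RF"]


@dataclass
class PipelineConfig:
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_ALGORITHMS))
    n_reps: int = 50
    train_fraction: float = 0.8
    auc_min: float = 0.8
    tss_min: float = 0.7
    block_km: float = 2000.0
    k_folds: int = 5
    threshold: str | float = "optimise"
    min_fraction: float = 0.0
    evidence_floor: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config (if given) and apply keyword overrides on top of
    the baked-in defaults; every deviation from a default is logged."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        default = getattr(cfg, key)
        if value != default:
            logger.info("config override: %s = %r (default %r)", key, value, default)
        setattr(cfg, key, value)
    return cfg
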