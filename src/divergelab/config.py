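"""Run configuration and seed management.

A single YAML file with per-stage sections drives the full pipeline.
Every stochastic stage receives its own seed derived deterministically
from the global seed and the stage name, so reruns are byte-identical
and stages are decoupled.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "derive_seed", "load_config", "save_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (kept below 2**31)."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full synthetic-study run."""

    seed: int = 0
    # eco-evolutionary simulation
    tradeoff_p: float = 0.5
    days: int = 400
    treatments: tuple[str, ...] = ("fructose", "galactose", "mix")
    mutation_sd: float = 0.06
    # growth-rate estimation
    window: int = 5
    min_od: float = 0.16
    n_replicates: int = 3
    noise_sd: float = 0.01
    # clustering
    k_max: int = 3
    # variant filtering
    min_strains: int = 5
    min_variants: int = 5
    strict_exclusive: bool = False
    # CNV calling
    mean_depth: float = 300.0
    bin_size: int = 100
    dup_ratio: float = 1.5
    del_ratio: float = 0.5
    min_bins: int = 3
    genome_len: int = 200_000
    extra: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    if "treatments" in known:
        known["treatments"] = tuple(known["treatments"])
    cfg = RunConfig(**known)
    cfg.extra = {k: v for k, v in data.items() if k not in RunConfig.__dataclass_fields__}
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    data["treatments"] = list(data["treatments"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
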