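"""Pipeline configuration: YAML-backed blocks with per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocessing import AssayConstants

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and stage name."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PreprocessBlock:
    low_expr_mad_k: float = 3.0
    min_valid_cells: int = 20
    impute_with_poisson: bool = False


@dataclass
class EntropyBlock:
    scale: str = "counts"  # or "log"
    n_iter: int = 1000
    frac: float = 0.85
    alpha: float = 0.05
    paired: bool = True


@dataclass
class NetworkBlock:
    frac: float = 0.85
    n_iter: int = 10000
    alpha: float = 0.05
    bonferroni: bool = True
    method: str = "spearman"
    delta_band: float = 0.4
    top_k: int = 3


@dataclass
class DnbBlock:
    t0: float | None = None  # default: first two time-points
    t1: float | None = None
    corr_threshold: float = 0.5
    select_method: str = "spearman"
    score_method: str = "pearson"
    absolute: bool = False
    include_diagonal: bool = True


@dataclass
class WavesBlock:
    n_boot: int = 1000
    support_threshold: float = 0.9
    alpha: float = 0.05
    enabled: bool = True


@dataclass
class SimulationBlock:
    scenario: str = "entropy_surge"
    n_genes: int = 90
    n_cells_per_time: int = 60
    mode: str = "stationary"


@dataclass
class PipelineConfig:
    """Validated configuration for an end-to-end run."""

    input_cq_csv: str | None = None
    input_molecules_tsv: str | None = None
    seed: int = 0
    constants: AssayConstants = field(default_factory=AssayConstants)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    entropy: EntropyBlock = field(default_factory=EntropyBlock)
    network: NetworkBlock = field(default_factory=NetworkBlock)
    dnb: DnbBlock = field(default_factory=DnbBlock)
    waves: WavesBlock = field(default_factory=WavesBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, frac in (("entropy.frac", self.entropy.frac), ("network.frac", self.network.frac)):
            if not 0 < frac <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {frac}")
        for name, a in (("entropy.alpha", self.entropy.alpha), ("network.alpha", self.network.alpha), ("waves.alpha", self.waves.alpha)):
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.entropy.scale not in ("counts", "log"):
            raise ValueError("entropy.scale must be 'counts' or 'log'")
        if self.network.method not in ("spearman", "pearson"):
            raise ValueError("network.method must be 'spearman' or 'pearson'")
        for name, n in (("entropy.n_iter", self.entropy.n_iter), ("network.n_iter", self.network.n_iter), ("waves.n_boot", self.waves.n_boot)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.waves.support_threshold < 1:
            raise ValueError("waves.support_threshold must be in (0, 1)")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        kwargs = {}
        for key, sub in (
            ("constants", AssayConstants),
            ("preprocess", PreprocessBlock),
            ("entropy", EntropyBlock),
            ("network", NetworkBlock),
            ("dnb", DnbBlock),
            ("waves", WavesBlock),
            ("simulation", SimulationBlock),
        ):
            if key in doc:
                block = doc.pop(key)
                if not isinstance(block, dict):
                    raise ValueError(f"config block {key!r} must be a mapping")
                unknown = set(block) - set(sub.__dataclass_fields__)
                if unknown:
                    raise ValueError(f"unknown keys in config block {key!r}: {sorted(unknown)}")
                kwargs[key] = sub(**block)
        unknown = set(doc) - {"input_cq_csv", "input_molecules_tsv", "seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(doc)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)
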