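"""Structured run configuration: one serialisable object drives all stages."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import yaml

from .clumo import CluMoConfig
from .twin import TwinParameters


@dataclasses.dataclass
class PoolConfig:
    n: int = 12000
    gc_mode: str = "GCall"
    insert_length: int = 108
    seed: Optional[int] = None


@dataclasses.dataclass
class FitConfig:
    min_runs: int = 2
    label_fraction: float = 0.02
    include_dropouts: bool = False


@dataclasses.dataclass
class TrainConfig:
    arch: str = "cnn_pe"
    d: int = 64
    epochs: int = 30
    search_iters: int = 0  # 0: use the default configuration without search
    test_fraction: float = 0.2
    seed: Optional[int] = None


@dataclasses.dataclass
class ScreenConfig:
    gc_range: tuple[float, float] = (0.40, 0.60)
    homopolymer_max: int = 4
    dg_min_kcal_per_mol: float = -15.0
    depths_per_design: tuple[float, ...] = (0.5, 1, 2, 5, 10, 20, 50)
    n_replicates: int = 30
    recovery_target: float = 0.99


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    pool: PoolConfig = dataclasses.field(default_factory=PoolConfig)
    twin: TwinParameters = dataclasses.field(default_factory=TwinParameters)
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    clumo: CluMoConfig = dataclasses.field(default_factory=CluMoConfig)
    screen: ScreenConfig = dataclasses.field(default_factory=ScreenConfig)

    def validate(self) -> "RunConfig":
        if self.seed is None:
            raise ValueError("a global seed is required for reproducibility")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, d):
            if d is None:
                return klass()
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for key, value in d.items():
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r} for {klass.__name__}")
                ftype = fields[key].type
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
            return klass(**kwargs)

        return cls(
            seed=data.get("seed", 0),
            pool=build(PoolConfig, data.get("pool")),
            twin=build(TwinParameters, data.get("twin")),
            fit=build(FitConfig, data.get("fit")),
            train=build(TrainConfig, data.get("train")),
            clumo=build(CluMoConfig, data.get("clumo")),
            screen=build(ScreenConfig, data.get("screen")),
        ).validate()

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
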