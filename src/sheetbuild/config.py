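"""Run configuration: one object bundling every stage's parameters.

Defaults are the method's typical operating values (connectivity ratio
cuts 0.5/0.75, pairing at 4.5 ± 2.0 Å with |cos| >= 0.5, tube correlation
threshold 0.5, period 6.7 Å with 1/12-period phase tolerance, assembly at
1 Å overlap / 4-residue minimum, multi-resolution merge at 2.5, 3 and 4 Å).
The config round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assembly import AssemblyParams
from .register import RegisterParams
from .ridgelines import ConnectionParams, PairParams


@dataclass
class TubeParams:
    """Ridge-point detection settings ([tubes] section, with the
    connection and pairing thresholds)."""

    spacing: float = 2.0
    density_floor: float = 1.0
    connection: ConnectionParams = field(default_factory=ConnectionParams)
    pairing: PairParams = field(default_factory=PairParams)


@dataclass
class RunConfig:
    tubes: TubeParams = field(default_factory=TubeParams)
    register: RegisterParams = field(default_factory=RegisterParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    rng_seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        tubes = dict(data.get("tubes", {}))
        conn = tubes.pop("connection", {})
        pair = tubes.pop("pairing", {})
        cfg.tubes = TubeParams(
            **tubes,
            connection=ConnectionParams(**conn),
            pairing=PairParams(**pair),
        )
        cfg.register = RegisterParams(**data.get("register", {}))
        cfg.assembly = AssemblyParams(**data.get("assembly", {}))
        cfg.rng_seed = int(data.get("rng_seed", 0))
        cfg.verbosity = int(data.get("verbosity", 1))
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
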