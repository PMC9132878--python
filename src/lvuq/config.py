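"""Declarative run configuration (YAML) with schema validation.

A run's config is archived beside its outputs so every report row is
traceable to the seeds and sizes that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forward import GeometryFibreSpec

__all__ = ["RunConfig"]


def _expect(cond: bool, msg: str):
    if not cond:
        raise ValueError(f"invalid config: {msg}")


@dataclass
class RunConfig:
    """All knobs of the SA and I-UQ pipelines, fully serializable."""

    # seeds, one per randomness source
    seed_design: int = 0
    seed_noise: int = 1
    seed_gp: int = 2
    seed_mcmc: int = 3
    seed_layout: int = 0

    # geometry
    geometry: dict = field(default_factory=dict)

    # design sizes
    n_train: int = 2000
    n_test: int = 100

    # emulator settings
    gp_restarts: int = 5
    gp_max_opt_subset: int = 512
    gp_nugget_floor: float = 1e-6
    q2_gate: float = 0.9

    # sensitivity settings
    sa_n_base: int = 4096
    sa_gp_samples: int = 250

    # inference settings
    mcmc_chains: int = 5
    mcmc_warmup: int = 1000
    mcmc_draws: int = 2000
    mcmc_max_treedepth: int = 8

    # battery settings
    battery_cases: int = 100
    battery_edps: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    sigma0: float = 5.0
    sigma_strain: float = 0.03

    outdir: str = "lvuq_out"

    def __post_init__(self):
        _expect(self.n_train >= 10, "n_train must be >= 10")
        _expect(self.n_test >= 2, "n_test must be >= 2")
        _expect(self.sa_n_base >= 2, "sa_n_base must be >= 2")
        _expect(self.sa_gp_samples >= 1, "sa_gp_samples must be >= 1")
        _expect(self.mcmc_chains >= 2, "need >= 2 chains for PSRF")
        _expect(self.mcmc_warmup >= 10 and self.mcmc_draws >= 10,
                "warmup/draws too small")
        _expect(self.battery_cases >= 1, "battery_cases must be >= 1")
        _expect(self.sigma0 >= 0 and self.sigma_strain >= 0,
                "noise SDs must be non-negative")
        _expect(0.0 <= self.q2_gate <= 1.0, "q2_gate must be in [0, 1]")
        self.geometry_spec  # validate geometry keys eagerly

    @property
    def geometry_spec(self) -> GeometryFibreSpec:
        return GeometryFibreSpec(**self.geometry)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        _expect(not unknown, f"unknown keys {sorted(unknown)}")
        if "battery_edps" in data:
            data["battery_edps"] = tuple(float(v) for v in data["battery_edps"])
        return cls(**data)

    def to_yaml(self, path):
        d = asdict(self)
        d["battery_edps"] = list(self.battery_edps)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
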