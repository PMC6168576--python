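"""Run configuration: one YAML file with substrate, shell, sim and analysis blocks.

All randomness flows from a single global seed; the substrate generator
uses it directly (named sub-streams would matter only if more stochastic
components existed).  A fully resolved copy of the configuration — every
default materialised — is written next to every run's outputs so that any
artifact can be reproduced from its config alone.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .substrate import PapillaConfig
from .shell import ShellParams
from .simulate import SimConfig

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "resolve_h_max"]


@dataclass
class AnalysisConfig:
    """Parameters of the statistics stage."""

    tau: float = 0.4  # trough height threshold, fraction of the papilla amplitude
    branch_arc_length: float | None = None  # cracks: default 2 mesh edge lengths
    trough_branch_arc_length: float | None = None  # trough lines: default 0.2 spacing
    n_bootstrap: int = 1000
    interior_margin: float | None = None  # mm; junctions closer to the border are dropped

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be positive")


@dataclass
class RunConfig:
    """Top-level configuration of one experiment."""

    substrate: PapillaConfig = field(default_factory=PapillaConfig)
    mesh_path: str | None = None  # use an external mesh instead of the generator
    shell: ShellParams = field(default_factory=ShellParams)
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "pachyshell-out"
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed drives the substrate unless one was set explicitly
        if self.substrate.seed == 0 and self.seed != 0:
            self.substrate = dataclasses.replace(self.substrate, seed=self.seed)
        if self.sim.seed == 0 and self.seed != 0:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "substrate": asdict(self.substrate),
            "mesh_path": self.mesh_path,
            "shell": asdict(self.shell),
            "sim": asdict(self.sim),
            "analysis": asdict(self.analysis),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        d["substrate"]["domain_size"] = list(self.substrate.domain_size)
        return d

    def write_resolved(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sub = dict(d.get("substrate", {}))
        if "domain_size" in sub:
            sub["domain_size"] = tuple(sub["domain_size"])
        return cls(
            substrate=PapillaConfig(**sub),
            mesh_path=d.get("mesh_path"),
            shell=ShellParams(**d.get("shell", {})),
            sim=SimConfig(**d.get("sim", {})),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            output_dir=d.get("output_dir", "pachyshell-out"),
            seed=int(d.get("seed", 0)),
        )


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration (validation precedes any work)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def resolve_h_max(config: RunConfig) -> SimConfig:
    """Materialise the growth ceiling: default h_max is spacing / 6."""
    sim = config.sim
    if sim.h_max is None:
        sim = dataclasses.replace(sim, h_max=config.substrate.mean_spacing / 6.0)
    return sim
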