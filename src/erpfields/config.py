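"""Run configuration: a JSON-serializable record of every stage's settings
and seeds, so a pipeline run is reproducible from its config alone."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

from .calibration.hmc import MCMCConfig

__all__ = ["RunConfig", "load_config", "save_config", "paper_headline_config"]


@dataclass
class RunConfig:
    # paths
    output_dir: str = "runs/out"
    mesh_path: Optional[str] = None           # None: use the sphere fixture
    observations_csv: Optional[str] = None    # None: synthesize from ground truth
    surrogates_json: Optional[str] = None     # None: fit from a fresh table
    # fixture mesh (used when mesh_path is None)
    fixture_kind: str = "sphere"
    fixture_scale_mm: float = 25.0
    fixture_edge_mm: float = 1.7
    # protocol / surrogate training
    s1_interval: float = 600.0
    s2_interval: float = 300.0
    n_s1: int = 8
    design_size: int = 100
    design_seed: int = 7
    # eigenbasis / GP
    n_eigenfunctions: int = 256
    calibration_K: int = 24
    kernel_family: str = "rbf"
    # ground truth + observations
    truth_lengthscale: float = 30.0
    truth_seed: int = 11
    n_observation_sites: int = 10
    site_seed: int = 2
    observation_resolution: float = 10.0
    boundary_exclusion_mm: float = 6.0
    # MCMC
    mcmc_iterations: int = 5000
    mcmc_chains: int = 8
    mcmc_thin: int = 100
    mcmc_seed: int = 0
    bracket_pad: float = 0.0

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            iterations=self.mcmc_iterations,
            chains=self.mcmc_chains,
            thin=self.mcmc_thin,
            seed=self.mcmc_seed,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def paper_headline_config(**overrides) -> RunConfig:
    """The headline synthetic-experiment profile: 10 sites, 10 ms resolution,
    K=24, 5000 iterations x 8 chains thinned to 200 draws."""
    return RunConfig(**overrides)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.to_json())


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig(**data)
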