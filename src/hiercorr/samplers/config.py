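"""MCMC run configuration."""

from __future__ import annotations

from dataclasses import dataclass

import yaml


@dataclass
class ChainConfig:
    """Settings for one posterior fit.

    The default budget (1000 burn-in, 3000 retained) matches the per-run
    budget used throughout the simulation studies; ``n_chains`` defaults to
    1 for replicate sweeps and should be raised to 4 for runs feeding
    convergence diagnostics.

    ``n_scans`` is the number of Metropolis sweeps over the correlation and
    scale blocks per Gibbs iteration (LKJ sampler only); extra scans are
    cheap relative to the conjugate updates and improve mixing.
    ``target_accept`` defaults to 0.44, the classic optimum for
    one-coordinate random-walk updates.
    ``prior_only`` disables every data contribution, so the chain targets
    the prior — used to validate that each sampler reproduces its prior
    marginals.
    """

    n_burn: int = 1000
    n_keep: int = 3000
    n_chains: int = 1
    seed: int = 0
    target_accept: float = 0.44
    n_scans: int = 4
    init_step: float = 0.3
    prior_only: bool = False
    store_theta: bool = False

    def __post_init__(self):
        if self.n_burn <= 0 or self.n_keep <= 0:
            raise ValueError("n_burn and n_keep must be positive")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ChainConfig":
        return cls(**yaml.safe_load(text))
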