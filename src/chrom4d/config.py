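"""Simulation configuration: integrator, thermostat, box, schedule, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimulationConfig:
    """Langevin MD run parameters in reduced units.

    The defaults are the standard choices for bead-spring chromatin models:
    timestep ``dt = 0.01``, friction ``zeta = 0.5``, temperature ``T = 1``
    (kBT units), cubic periodic box of edge ``box_L = 50`` sigma.

    ``sample_interval`` is the frame spacing in MD steps; the coarse default
    (5e4) matches equilibrium-ensemble sampling, the fine mode (1e3) is used
    for contact-time dynamics.  ``binder_counts`` maps binder type index to
    the number of diffusing binders of that type; if empty, the engine fills
    it with the documented default fraction of cognate bead counts.
    """

    dt: float = 0.01
    zeta: float = 0.5
    T: float = 1.0
    box_L: float = 50.0
    n_equil_steps: int = 50_000
    n_production_steps: int = 100_000
    sample_interval: int = 50_000
    n_replicas: int = 1
    rng_seed: int = 0
    binder_counts: dict[int, int] = field(default_factory=dict)
    store_binders: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.box_L <= 2 * 1.6:
            raise ValueError("box_L must exceed twice the FENE maximum length")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.T < 0 or self.zeta < 0:
            raise ValueError("T and zeta must be nonnegative")

    def replica_seeds(self) -> list[int]:
        """Distinct per-replica seeds derived from ``rng_seed``."""
        return [(self.rng_seed + 7919 * k) % (2**31) for k in range(self.n_replicas)]
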