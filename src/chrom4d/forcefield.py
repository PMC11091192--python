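"""Force field for the bead-spring chromatin polymer with diffusing binders.

All quantities are in reduced Lennard-Jones units: length in units of the
particle diameter sigma, energy in units of kB*T, mass m = 1.  Beads and
binders share the same diameter.

The force field has three ingredients:

* FENE bonds between consecutive polymer beads (maximum extension ``R0``,
  spring constant ``K_FENE``),
* a truncated, purely repulsive Lennard-Jones core (WCA) between every
  particle pair, giving all beads and binders excluded volume,
* a truncated-and-shifted attractive Lennard-Jones well between binders and
  their cognate binding sites, of depth parameter ``epsilon`` and cutoff
  ``r_int``; the potential is shifted so it is exactly zero at and beyond
  the cutoff.

Because published affinities refer to the depth of the shifted well (the
value of the potential at its minimum) rather than to the bare LJ
``epsilon``, this module also provides the exact linear conversion between
the two (:func:`epsilon_to_affinity` / :func:`affinity_to_epsilon`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceField",
    "pair_potential",
    "wca_potential",
    "fene_energy",
    "fene_force",
    "epsilon_to_affinity",
    "affinity_to_epsilon",
    "R_MIN",
]

#: location of the Lennard-Jones minimum, 2**(1/6) sigma
R_MIN: float = 2.0 ** (1.0 / 6.0)


@dataclass
class ForceField:
    """Force-field constants in reduced units.

    Parameters
    ----------
    R0 : float
        FENE maximum bond length (sigma).
    K_FENE : float
        FENE spring constant (kBT / sigma^2).
    eps_matrix : ndarray, shape (n_binder_types, n_bead_types)
        Attractive LJ depth parameters epsilon (kBT) between each binder
        type and each bead type; 0 means purely repulsive contact.
    r_int : float
        Cutoff of the attractive wells (sigma); the shifted potential
        vanishes identically for r >= r_int.
    """

    R0: float = 1.6
    K_FENE: float = 30.0
    eps_matrix: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    r_int: float = 1.3
    sigma: float = 1.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.eps_matrix = np.asarray(self.eps_matrix, dtype=float)
        if self.R0 <= self.sigma:
            raise ValueError(f"R0 must exceed sigma, got R0={self.R0}")
        if self.K_FENE <= 0:
            raise ValueError("K_FENE must be positive")
        if self.r_int <= self.sigma:
            raise ValueError(f"r_int must exceed sigma, got r_int={self.r_int}")
        if np.any(self.eps_matrix < 0):
            raise ValueError("all epsilon entries must be nonnegative")


def pair_potential(r, epsilon: float, r_int: float):
    """Truncated-and-shifted Lennard-Jones potential (kBT).

    ``V(r) = 4 eps [ (1/r)^12 - (1/r)^6 - (1/r_int)^12 + (1/r_int)^6 ]``
    for ``r < r_int`` and exactly 0 otherwise.  Continuous at the cutoff.
    Accepts scalars or arrays of distances (sigma units).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    shift = (1.0 / r_int) ** 12 - (1.0 / r_int) ** 6
    inv6 = (1.0 / r) ** 6
    v = 4.0 * epsilon * (inv6 * inv6 - inv6 - shift)
    out = np.where(r < r_int, v, 0.0)
    return float(out) if out.ndim == 0 else out


def wca_potential(r):
    """Purely repulsive LJ core (WCA): truncated-shifted LJ with eps=1 and
    cutoff at the minimum, 2^(1/6) sigma."""
    return pair_potential(r, 1.0, R_MIN)


def fene_energy(r, R0: float = 1.6, K: float = 30.0):
    """FENE bond energy ``-K R0^2/2 ln(1 - (r/R0)^2)`` (kBT).

    Strictly increasing on [0, R0) and divergent as r -> R0.  Raises if the
    bond length reaches or exceeds R0 (a broken bond: integration must
    never get there).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be nonnegative")
    if np.any(r >= R0):
        raise ValueError(f"FENE bond length {np.max(r):.4f} >= R0={R0}: bond broken")
    out = -0.5 * K * R0 * R0 * np.log1p(-((r / R0) ** 2))
    return float(out) if out.ndim == 0 else out


def fene_force(r, R0: float = 1.6, K: float = 30.0):
    """Magnitude of the attractive FENE force, ``K r / (1 - (r/R0)^2)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= R0):
        raise ValueError("FENE bond broken")
    out = K * r / (1.0 - (r / R0) ** 2)
    return float(out) if out.ndim == 0 else out


def epsilon_to_affinity(epsilon: float, r_int: float) -> float:
    """Binding affinity (kBT): depth of the truncated-shifted LJ well.

    The affinity is ``|min_r V(r)|``; for ``r_int > 2^(1/6)`` the minimum
    sits at ``2^(1/6) sigma`` and the affinity is linear in epsilon.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if epsilon == 0:
        return 0.0
    if r_int <= R_MIN:
        # well truncated before its minimum: infimum approached at cutoff is 0
        return 0.0
    return -pair_potential(R_MIN, epsilon, r_int)


def affinity_to_epsilon(affinity: float, r_int: float) -> float:
    """Inverse of :func:`epsilon_to_affinity` (affinity is linear in eps)."""
    if affinity < 0:
        raise ValueError("affinity must be nonnegative")
    if affinity == 0:
        return 0.0
    unit = epsilon_to_affinity(1.0, r_int)
    if unit <= 0:
        raise ValueError(f"r_int={r_int} <= 2^(1/6): well has no minimum")
    return affinity / unit
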