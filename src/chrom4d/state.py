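"""Conformations, trajectories and ensembles of the polymer + binder system.

Polymer coordinates are stored *unwrapped* (continuous across the periodic
box) because shape descriptors, distances and convex-hull volumes are only
meaningful on unwrapped chains; forces always use the minimum-image
convention so wrapping is irrelevant to the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Conformation:
    """A snapshot of the system: bead and binder positions (sigma units)."""

    beads: np.ndarray                     # (n_beads, 3), unwrapped
    binders: np.ndarray | None = None     # (n_binders, 3)
    velocities: np.ndarray | None = None  # (n_beads + n_binders, 3)
    box_L: float = 50.0
    time: int = 0                         # MD steps
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError("beads must be an (n, 3) array")

    @property
    def n_beads(self) -> int:
        return self.beads.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.beads, axis=0), axis=1)

    def check_fene(self, R0: float = 1.6) -> None:
        """Raise if any consecutive-bead distance reached R0 (broken bond)."""
        if self.n_beads > 1:
            m = float(self.bond_lengths().max())
            if m >= R0:
                raise RuntimeError(f"FENE invariant violated: bond {m:.4f} >= R0={R0}")


@dataclass
class Trajectory:
    """Time-ordered conformations of one replica at fixed frame spacing."""

    frames: list[Conformation]
    replica_id: int = 0
    sample_interval: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        """Bead coordinates stacked as (n_frames, n_beads, 3)."""
        return np.stack([f.beads for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class Ensemble:
    """A set of replica trajectories produced under one parameter setting."""

    trajectories: list[Trajectory]
    failed_replicas: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.failed_replicas:
            import warnings

            warnings.warn(
                f"partial ensemble: {len(self.failed_replicas)} replica(s) failed: "
                + "; ".join(f"#{i}: {msg}" for i, msg in self.failed_replicas),
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def is_partial(self) -> bool:
        return bool(self.failed_replicas)

    def all_frames(self) -> np.ndarray:
        """All bead coordinates of all replicas, (total_frames, n_beads, 3).

        Replicas are weighted equally by construction here only when frame
        counts match; aggregation helpers in :mod:`chrom4d.maps` average
        per replica first.
        """
        return np.concatenate([t.positions() for t in self.trajectories])
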