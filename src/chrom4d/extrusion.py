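"""Loop-extruding factors as mobile harmonic springs on the polymer.

An extruder holds two legs (i, j), i < j, bridged by a harmonic spring
(K_spring = 10 kBT/sigma^2, r_eq = 1.1 sigma).  Every ``step_interval`` MD
steps each non-halted leg slides one bead outward, (i, j) -> (i-1, j+1).
A leg halts when it would enter a bead occupied by another extruder's leg
(no pass-through), when it reaches the polymer end, or permanently when it
meets an engaged anchor whose orientation opposes its travel direction.
Orientation convention: a *forward* ("+") anchor blocks legs travelling
leftward into it, a *reverse* ("-") anchor blocks rightward travel, so a
convergent forward/reverse pair encloses a domain; *bidirectional* anchors
block both.  Whether an anchor engages a given extruder is drawn once per
extruder-anchor encounter with the anchor's probability p and remembered
until that extruder detaches.

Extruders detach stochastically with rate ``k_off`` (per update the
probability is 1 - exp(-k_off)) and are immediately re-seeded at a random
free position, keeping the total number constant.  The processivity --
the mean genomic length of an extruded loop -- is proc = 2 g / k_off with
g the genomic content per bead, since a free extruder grows its loop by
2 g per update and survives on average 1/k_off updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FORWARD = 1
REVERSE = -1
BIDIRECTIONAL = 0

_STRAND_TO_ORIENT = {"+": FORWARD, "-": REVERSE, ".": BIDIRECTIONAL}
_ORIENT_TO_STRAND = {FORWARD: "+", REVERSE: "-", BIDIRECTIONAL: "."}


@dataclass
class Extruder:
    """One loop-extruding factor: legs (i, j) with per-leg halted flags."""

    i: int
    j: int
    halted_left: bool = False
    halted_right: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError(f"extruder legs must satisfy 0 <= i < j, got ({self.i}, {self.j})")


@dataclass
class AnchorSet:
    """Oriented stochastic anchor points for extruder legs."""

    beads: np.ndarray                      # int bead indices
    orientations: np.ndarray               # FORWARD / REVERSE / BIDIRECTIONAL
    probabilities: np.ndarray              # engagement probability in [0, 1]

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=int)
        self.orientations = np.asarray(self.orientations, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not (len(self.beads) == len(self.orientations) == len(self.probabilities)):
            raise ValueError("anchor arrays must have equal length")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("anchor probabilities must lie in [0, 1]")
        if np.any(self.beads < 0):
            raise ValueError("anchor bead indices must be nonnegative")

    def __len__(self) -> int:
        return len(self.beads)

    @classmethod
    def empty(cls) -> "AnchorSet":
        return cls(np.array([], dtype=int), np.array([], dtype=int), np.array([]))

    @classmethod
    def regular(cls, n_beads: int, spacing: int, p: float = 0.5) -> "AnchorSet":
        """Bidirectional anchors every ``spacing`` beads starting at 0."""
        beads = np.arange(0, n_beads, spacing)
        return cls(beads, np.full(len(beads), BIDIRECTIONAL), np.full(len(beads), p))


@dataclass
class ExtrusionParams:
    """Extruder population parameters.

    Either ``n_extruders`` or ``separation_kb`` (mean genomic distance
    between extruders) must be given; either ``k_off`` (detachment rate per
    update) or ``processivity_kb`` likewise.  Conversions use the model's
    genomic content per bead g:  n = N*g / separation,  proc = 2g / k_off.
    """

    n_extruders: int | None = None
    separation_kb: float | None = None
    k_off: float | None = None
    processivity_kb: float | None = None
    step_interval: int = 500
    K_spring: float = 10.0
    r_eq: float = 1.1
    one_sided_continuation: bool = True

    def resolve_n(self, n_beads: int, g_bp: float) -> int:
        if self.n_extruders is not None:
            return int(self.n_extruders)
        if self.separation_kb is None:
            raise ValueError("need n_extruders or separation_kb")
        n = int(round(n_beads * (g_bp / 1000.0) / self.separation_kb))
        return max(n, 0)

    def resolve_k_off(self, g_bp: float) -> float:
        if self.k_off is not None:
            return float(self.k_off)
        if self.processivity_kb is None:
            return 0.0
        if self.processivity_kb <= 0:
            raise ValueError("processivity must be positive")
        return 2.0 * (g_bp / 1000.0) / self.processivity_kb


def seed_extruders(n_extruders: int, n_beads: int, rng: np.random.Generator) -> list[Extruder]:
    """Place extruders at uniformly random non-overlapping (k, k+1) leg pairs."""
    if n_beads < 2:
        raise ValueError("polymer too short for extruders")
    if n_extruders > n_beads // 2:
        raise ValueError(
            f"cannot place {n_extruders} non-overlapping extruders on {n_beads} beads"
        )
    occupied: set[int] = set()
    out: list[Extruder] = []
    for _ in range(n_extruders):
        out.append(_seed_one(n_beads, occupied, rng))
    return out


def _seed_one(n_beads: int, occupied: set[int], rng: np.random.Generator) -> Extruder:
    """Draw one free (k, k+1) site uniformly; updates ``occupied`` in place."""
    free = [k for k in range(n_beads - 1) if k not in occupied and k + 1 not in occupied]
    if not free:
        raise RuntimeError("no free site to seed an extruder")
    k = free[rng.integers(len(free))]
    occupied.add(k)
    occupied.add(k + 1)
    return Extruder(k, k + 1)


class ExtruderSystem:
    """Mutable extruder population coupled to the MD engine.

    Tracks leg occupancy, per-(extruder, anchor) engagement draws, and
    exposes the current spring endpoints for the force kernel.
    """

    def __init__(
        self,
        params: ExtrusionParams,
        n_beads: int,
        anchors: AnchorSet | None,
        g_bp: float,
        rng: np.random.Generator,
    ) -> None:
        self.params = params
        self.n_beads = int(n_beads)
        self.anchors = anchors if anchors is not None else AnchorSet.empty()
        if len(self.anchors) and self.anchors.beads.max() >= self.n_beads:
            raise ValueError("anchor bead index outside polymer")
        self.g_bp = float(g_bp)
        self.rng = rng
        self.k_off = params.resolve_k_off(g_bp)
        n = params.resolve_n(n_beads, g_bp)
        self.extruders: list[Extruder] = seed_extruders(n, n_beads, rng)
        # engagement[(extruder_idx, anchor_idx)] -> bool, cleared on rebind
        self._engagement: dict[tuple[int, int], bool] = {}
        self._anchor_at: dict[int, int] = {int(b): a for a, b in enumerate(self.anchors.beads)}

    # ------------------------------------------------------------------
    def spring_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        i = np.array([e.i for e in self.extruders], dtype=np.int64)
        j = np.array([e.j for e in self.extruders], dtype=np.int64)
        return i, j

    def _occupancy(self) -> set[int]:
        occ: set[int] = set()
        for e in self.extruders:
            occ.add(e.i)
            occ.add(e.j)
        return occ

    def _engaged(self, ext_idx: int, anchor_idx: int) -> bool:
        key = (ext_idx, anchor_idx)
        if key not in self._engagement:
            p = self.anchors.probabilities[anchor_idx]
            self._engagement[key] = bool(self.rng.random() < p)
        return self._engagement[key]

    def _blocks(self, ext_idx: int, bead: int, direction: int) -> bool:
        """Does an anchor at ``bead`` block a leg travelling ``direction``
        (-1 leftward, +1 rightward) for this extruder?"""
        a = self._anchor_at.get(bead)
        if a is None:
            return False
        orient = self.anchors.orientations[a]
        opposes = (
            orient == BIDIRECTIONAL
            or (orient == FORWARD and direction < 0)
            or (orient == REVERSE and direction > 0)
        )
        return opposes and self._engaged(ext_idx, a)

    # ------------------------------------------------------------------
    def extrusion_step(self) -> None:
        """Advance every non-halted leg one bead outward.

        Extruders update synchronously in a randomised order each call to
        break ties at contested beads; a halted leg's partner continues by
        default (one-sided continuation).
        """
        occ = self._occupancy()
        order = self.rng.permutation(len(self.extruders))
        for idx in order:
            e = self.extruders[idx]
            if not self.params.one_sided_continuation and (e.halted_left or e.halted_right):
                continue
            # left leg
            if not e.halted_left:
                tgt = e.i - 1
                if tgt < 0:
                    e.halted_left = True
                elif tgt in occ:
                    pass  # contested this update; try again next time
                else:
                    occ.discard(e.i)
                    e.i = tgt
                    occ.add(tgt)
                    if self._blocks(idx, tgt, -1):
                        # came to rest on an opposing engaged anchor
                        e.halted_left = True
            # right leg
            if not e.halted_right:
                tgt = e.j + 1
                if tgt >= self.n_beads:
                    e.halted_right = True
                elif tgt in occ:
                    pass
                else:
                    occ.discard(e.j)
                    e.j = tgt
                    occ.add(tgt)
                    if self._blocks(idx, tgt, +1):
                        e.halted_right = True

    def detach_rebind(self) -> list[int]:
        """Detach each extruder with probability 1 - exp(-k_off); re-seed
        detached ones at random free positions.  Returns the extruded loop
        lengths (in beads) of the detached extruders."""
        if self.k_off <= 0:
            return []
        p_detach = 1.0 - np.exp(-self.k_off)
        loops: list[int] = []
        occ = self._occupancy()
        for idx, e in enumerate(self.extruders):
            if self.rng.random() < p_detach:
                loops.append(e.j - e.i)
                occ.discard(e.i)
                occ.discard(e.j)
                fresh = _seed_one(self.n_beads, occ, self.rng)
                self.extruders[idx] = fresh
                self._engagement = {
                    k: v for k, v in self._engagement.items() if k[0] != idx
                }
        return loops

    def update(self) -> tuple[np.ndarray, np.ndarray]:
        """One extrusion update: slide legs, then apply turnover."""
        self.extrusion_step()
        self.detach_rebind()
        return self.spring_arrays()


def anchors_from_signal(
    signal: np.ndarray,
    orientations: np.ndarray | list[str] | None = None,
    normalization: str = "max",
    scale: float = 1.0,
) -> AnchorSet:
    """Build an AnchorSet from a binned occupancy signal (e.g. CTCF).

    The engagement probability of bin k is ``signal_k / max(signal)``
    (``normalization="max"``) or ``signal_k * scale`` clipped to [0, 1]
    (``normalization="global"``).  Zero-signal bins produce no anchor.
    ``orientations`` gives per-bin strands ("+", "-", ".") or orientation
    codes; default bidirectional.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be nonnegative")
    if signal.max() == 0:
        warnings.warn("all-zero signal: empty anchor set", stacklevel=2)
        return AnchorSet.empty()
    if normalization == "max":
        p = signal / signal.max()
    elif normalization == "global":
        p = np.clip(signal * scale, 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    beads = np.nonzero(signal > 0)[0]
    if orientations is None:
        orient = np.full(len(beads), BIDIRECTIONAL)
    else:
        if isinstance(orientations[0], str):
            codes = np.array([_STRAND_TO_ORIENT[s] for s in orientations])
        else:
            codes = np.asarray(orientations, dtype=int)
        if len(codes) != len(signal):
            raise ValueError("orientations must match signal length")
        orient = codes[beads]
    return AnchorSet(beads, orient, p[beads])
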