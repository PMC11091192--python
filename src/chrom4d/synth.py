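"""Synthetic inputs with planted structure for every pipeline stage.

These generators emulate the statistical structure of binned Hi-C maps and
ChIP-seq tracks so the whole analysis layer is testable without external
data: checkerboard compartment maps with tunable A/B strength on a
power-law distance decay, locus maps generated by the binding-site forward
model with corner loops at anchor pairs, and epigenetic tracks with a
planted correlation to a binding profile.  Noise is multiplicative
log-normal on map entries (Hi-C-like overdispersion).  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extrusion import AnchorSet
from .maps import ContactMap
from .prismr import BindingProfile, predicted_map
from .epi import EpiTrack

__all__ = ["SyntheticSpec", "synth_compartment_map", "synth_locus_map",
           "synth_tracks"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators.

    ``decay_exponent`` is the P(s) power-law slope (default 1.0,
    crumpled-globule-like); ``compartment_strength`` scales the
    checkerboard modulation; ``a_weakening`` < 1 scales down A-A contacts
    to mimic the infected condition; ``noise`` is the standard deviation
    of the log-normal multiplicative noise.
    """

    n_bins: int = 200
    bin_bp: float = 100_000.0
    block_size: int = 25
    compartment_strength: float = 0.4
    a_weakening: float = 1.0
    decay_exponent: float = 1.0
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compartment_strength < 0 or self.noise < 0:
            raise ValueError("strength and noise must be nonnegative")


def _decay(n: int, exponent: float) -> np.ndarray:
    s = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return (1.0 / (1.0 + s)) ** exponent


def _lognormal_noise(n: int, level: float, rng: np.random.Generator) -> np.ndarray:
    if level <= 0:
        return np.ones((n, n))
    z = rng.normal(0.0, level, size=(n, n))
    z = 0.5 * (z + z.T)
    return np.exp(z)


def synth_compartment_map(spec: SyntheticSpec) -> tuple[ContactMap, np.ndarray]:
    """Checkerboard compartment map plus the planted E1 labels (+-1).

    Contact frequencies are a power-law distance decay modulated by
    ``1 + strength * s_i * s_j`` with planted block labels s = +-1 (A = +1);
    A-A cells are additionally multiplied by ``a_weakening`` to mimic the
    weakened A compartment of the infected condition.  Symmetric, unit
    diagonal, entries clipped to [0, 1].
    """
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed)
    labels = np.where((np.arange(n) // spec.block_size) % 2 == 0, 1.0, -1.0)
    checker = 1.0 + spec.compartment_strength * np.outer(labels, labels)
    aa = np.outer(labels > 0, labels > 0)
    checker = np.where(aa, checker * spec.a_weakening, checker)
    m = _decay(n, spec.decay_exponent) * checker * _lognormal_noise(n, spec.noise, rng)
    m = np.clip(0.5 * (m + m.T), 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m, bin_bp=spec.bin_bp, threshold=0.0), labels


def synth_locus_map(profile: BindingProfile, anchors: AnchorSet | None,
                    spec: SyntheticSpec, loop_strength: float = 0.3,
                    loop_width: int = 1) -> ContactMap:
    """Locus map from the binding-site forward model plus corner loops.

    Starts from ``predicted_map(profile)``, adds a local enrichment of
    ``loop_strength`` at every ordered anchor pair (a, b) (a Gaussian bump
    of half-width ``loop_width`` bins), then applies log-normal noise.
    Anchors must live on the profile's bin grid.
    """
    n = profile.n_beads
    if anchors is not None and len(anchors) and anchors.beads.max() >= n:
        raise ValueError("anchor index outside the profile grid")
    rng = np.random.default_rng(spec.seed)
    m = predicted_map(profile).matrix.copy()
    if anchors is not None and len(anchors) >= 2:
        beads = np.sort(anchors.beads)
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        for a_i in range(len(beads) - 1):
            for b_i in range(a_i + 1, len(beads)):
                a, b = int(beads[a_i]), int(beads[b_i])
                bump = np.exp(-(((ii - a) ** 2 + (jj - b) ** 2)
                                / (2.0 * max(loop_width, 1) ** 2)))
                m = m + loop_strength * (bump + bump.T)
    m = m * _lognormal_noise(n, spec.noise, rng)
    m = np.clip(0.5 * (m + m.T), 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m, bin_bp=profile.bin_bp, threshold=0.0)


def synth_tracks(profile: BindingProfile, rho_per_mark: dict[str, float] | list[float],
                 seed: int = 0, type_index: int | None = None,
                 condition: str = "") -> list[EpiTrack]:
    """Epigenetic tracks with a planted correlation to a profile row.

    Each track is ``rho * z(profile row) + sqrt(1 - rho^2) * noise``
    (z = standardised), shifted and scaled to a nonnegative signal; the
    realised Pearson correlation with the profile row approaches rho as
    the number of bins grows.  Mark k draws its planted row from type
    ``type_index`` (default: mark index modulo n_types).
    """
    if isinstance(rho_per_mark, dict):
        items = list(rho_per_mark.items())
    else:
        items = [(f"mark{k}", r) for k, r in enumerate(rho_per_mark)]
    rng = np.random.default_rng(seed)
    n = profile.n_beads
    tracks: list[EpiTrack] = []
    for k, (mark, rho) in enumerate(items):
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {rho}")
        t = type_index if type_index is not None else k % profile.n_types
        row = profile.counts[t].astype(float)
        sd = row.std()
        z = (row - row.mean()) / sd if sd > 0 else np.zeros(n)
        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std()
        y = rho * z + np.sqrt(max(1.0 - rho * rho, 0.0)) * noise
        y = y - y.min()  # shift to nonnegative; affine, so correlation kept
        tracks.append(EpiTrack(values=y, bin_bp=profile.bin_bp, mark=mark,
                               condition=condition))
    return tracks
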