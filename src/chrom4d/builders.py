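"""Builders for polymer models at compartment, TAD and locus scale.

A :class:`PolymerModel` is a typed bead chain: each bead carries a type
(A/B compartment labels, inferred binding-site colours, or an inert type
with no attractive interactions), a genomic content ``g_bp`` per bead, an
affinity matrix between binder types and bead types, and optionally an
anchor set plus extrusion parameters for the loop-extrusion layer.

Affinities are quoted as binding energies in kBT -- the depth of the
truncated-shifted LJ well -- and converted to the bare LJ epsilon by the
engine.  Micro-phase separation of a block copolymer requires homo-typic
affinities to exceed the hetero-typic one (E_AA > E_AB and E_BB > E_AB),
which the compartment builders enforce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .extrusion import AnchorSet, ExtrusionParams, BIDIRECTIONAL

__all__ = [
    "PolymerModel",
    "build_compartment_model",
    "build_from_eigenvector",
    "build_tad_model",
    "build_locus_model",
    "infected_variant",
]


@dataclass
class PolymerModel:
    """Typed bead-spring chromatin model.

    ``affinity_matrix[t, c]`` is the binding affinity (kBT) between binder
    type ``t`` and bead type ``c``; a zero row/column makes a type inert.
    """

    bead_types: np.ndarray                       # (N,) int type codes
    type_labels: list[str]                       # code -> label
    g_bp: float                                  # genomic content per bead
    affinity_matrix: np.ndarray                  # (n_binder_types, n_bead_types)
    r_int: float = 1.3
    anchors: AnchorSet | None = None
    extrusion: ExtrusionParams | None = None
    n_tail: int = 0                              # inert tail beads on each side
    name: str = "model"

    def __post_init__(self) -> None:
        self.bead_types = np.asarray(self.bead_types, dtype=int)
        self.affinity_matrix = np.atleast_2d(np.asarray(self.affinity_matrix, dtype=float))
        if self.bead_types.min(initial=0) < 0:
            raise ValueError("bead type codes must be nonnegative")
        if self.bead_types.size and self.bead_types.max() >= self.affinity_matrix.shape[1]:
            raise ValueError("bead type code outside affinity matrix")
        if np.any(self.affinity_matrix < 0):
            raise ValueError("affinities must be nonnegative")
        if self.anchors is not None and len(self.anchors):
            if self.anchors.beads.max() >= self.n_beads:
                raise ValueError("anchor bead index outside polymer")

    @property
    def n_beads(self) -> int:
        return int(self.bead_types.size)

    @property
    def n_binder_types(self) -> int:
        return int(self.affinity_matrix.shape[0])

    @property
    def genomic_span_bp(self) -> float:
        """Total genomic span = N * g."""
        return self.n_beads * self.g_bp

    def default_binder_counts(self, fraction: float = 0.5) -> dict[int, int]:
        """Binder count per type: a fixed fraction of cognate bead counts.

        The default fraction (0.5 binders per cognate bead) was calibrated
        once against the coil-globule transition -- it keeps a homopolymer
        collapsed at affinities >= 3.1 kBT -- and is then held fixed.
        """
        counts: dict[int, int] = {}
        for t in range(self.n_binder_types):
            cognate = np.isin(self.bead_types, np.nonzero(self.affinity_matrix[t] > 0)[0])
            counts[t] = max(int(round(fraction * cognate.sum())), 0)
        return counts


def _check_phase_separation(E_AA: float, E_BB: float, E_AB: float) -> None:
    if E_AA <= E_AB or E_BB <= E_AB:
        raise ValueError(
            f"micro-phase separation requires homo-typic affinities above the "
            f"hetero-typic one: got E_AA={E_AA}, E_BB={E_BB}, E_AB={E_AB}"
        )


def build_compartment_model(
    n_beads: int = 1000,
    block_size: int = 75,
    E_AA: float = 3.3,
    E_BB: float = 3.3,
    E_AB: float = 3.1,
    g_bp: float = 100_000.0,
) -> PolymerModel:
    """Alternating A/B block copolymer for compartment-scale simulations.

    Defaults give a 1000-bead, 100 kb/bead chain (100 Mb) in blocks of 75
    beads (7.5 Mb per compartment).  When ``block_size`` does not divide
    ``n_beads`` the trailing remainder is truncated from the typed pattern
    (the last partial block keeps its colour), with a warning.
    """
    if n_beads < 1 or block_size < 1:
        raise ValueError("n_beads and block_size must be positive")
    _check_phase_separation(E_AA, E_BB, E_AB)
    if n_beads % block_size:
        warnings.warn(
            f"block_size {block_size} does not divide n_beads {n_beads}; "
            f"last block truncated to {n_beads % block_size} beads",
            stacklevel=2,
        )
    types = (np.arange(n_beads) // block_size) % 2
    aff = np.array([[E_AA, E_AB], [E_AB, E_BB]])
    return PolymerModel(
        bead_types=types,
        type_labels=["A", "B"],
        g_bp=g_bp,
        affinity_matrix=aff,
        r_int=1.3,
        name=f"compartment_{E_AA}_{E_BB}_{E_AB}",
    )


def build_from_eigenvector(
    e1: np.ndarray,
    g_bp: float = 100_000.0,
    E_AA: float = 3.3,
    E_BB: float = 3.3,
    E_AB: float = 3.1,
) -> PolymerModel:
    """Polymer model from a compartment eigenvector with possible gaps.

    Bead type is A where e1 > 0 and B where e1 < 0 (the sign convention --
    A positive -- must already be oriented, e.g. against GC content).
    Undefined bins (NaN) are filled by linear interpolation of e1 and then
    thresholded; the tie e1 == 0 is assigned to A.
    """
    e1 = np.asarray(e1, dtype=float)
    good = np.isfinite(e1)
    if not good.any():
        raise ValueError("eigenvector entirely undefined")
    if not good.all():
        idx = np.arange(e1.size)
        e1 = np.interp(idx, idx[good], e1[good])
    _check_phase_separation(E_AA, E_BB, E_AB)
    types = np.where(e1 >= 0, 0, 1)
    aff = np.array([[E_AA, E_AB], [E_AB, E_BB]])
    return PolymerModel(
        bead_types=types,
        type_labels=["A", "B"],
        g_bp=g_bp,
        affinity_matrix=aff,
        r_int=1.3,
        name="eigenvector_model",
    )


def build_tad_model(
    kind: str = "plain",
    affinity: float = 3.5,
    anchor_spacing: int = 120,
    anchor_p: float = 0.5,
    separation_kb: float = 120.0,
    processivity_kb: float = 500.0,
    n_beads: int = 1000,
    E_AA: float = 3.3,
    E_BB: float = 3.3,
    E_AB: float = 3.1,
) -> PolymerModel:
    """TAD-scale templates with loop extrusion.

    ``kind="plain"``: homopolymer of 1000 beads at 5 kb/bead with a single
    binder type (affinity 3.1-3.8 kBT) and bidirectional anchors every 120
    beads at p = 0.5, i.e. a mean TAD size of 600 kb; extruder separation
    60-500 kb, processivity 500 kb.

    ``kind="with_compartments"``: 1000 beads at 10 kb/bead, four A-B-A-B
    compartment blocks of 250 beads, each containing 5 TADs of 50 beads
    (anchors every 50 beads); separation 100-1000 kb.
    """
    if kind == "plain":
        g_bp = 5000.0
        if not 3.1 <= affinity <= 3.8:
            warnings.warn(f"affinity {affinity} outside the usual 3.1-3.8 kBT range", stacklevel=2)
        if not 60 <= separation_kb <= 500:
            warnings.warn(f"separation {separation_kb} kb outside 60-500 kb", stacklevel=2)
        types = np.zeros(n_beads, dtype=int)
        aff = np.array([[affinity]])
        labels = ["U"]
        anchors = AnchorSet.regular(n_beads, anchor_spacing, anchor_p)
        name = "tad_plain"
    elif kind == "with_compartments":
        g_bp = 10_000.0
        if not 100 <= separation_kb <= 1000:
            warnings.warn(f"separation {separation_kb} kb outside 100-1000 kb", stacklevel=2)
        _check_phase_separation(E_AA, E_BB, E_AB)
        block = n_beads // 4
        tad = block // 5
        types = (np.arange(n_beads) // block) % 2
        aff = np.array([[E_AA, E_AB], [E_AB, E_BB]])
        labels = ["A", "B"]
        anchors = AnchorSet.regular(n_beads, tad, anchor_p)
        name = "tad_with_compartments"
    else:
        raise ValueError(f"unknown TAD template kind {kind!r}")
    ext = ExtrusionParams(separation_kb=separation_kb, processivity_kb=processivity_kb)
    return PolymerModel(
        bead_types=types,
        type_labels=labels,
        g_bp=g_bp,
        affinity_matrix=aff,
        r_int=1.3,
        anchors=anchors,
        extrusion=ext,
        name=name,
    )


def build_locus_model(
    profile: np.ndarray,
    anchors: AnchorSet | None = None,
    g_bp: float = 500.0,
    n_tail: int = 50,
    affinity: float = 2.9,
    hetero_affinity: float = 0.0,
    separation_kb: float = 50.0,
    processivity_kb: float = 300.0,
    name: str = "locus",
) -> PolymerModel:
    """Locus-scale model from an inferred binding-site profile.

    ``profile`` is an (n_types, n_bins) nonnegative occupancy matrix (the
    output of the binding-site inference); each bin becomes a bead whose
    type is the profile row with the largest count there (inert where all
    rows are zero).  Inert tails of ``n_tail`` beads are added on both
    sides to control boundary effects.  The attraction cutoff for locus
    models is r_int = 2.5 sigma and homo-typic affinities are in the
    2.3-2.9 kBT range; anchors shift by ``n_tail`` to stay aligned.
    """
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    n_types, n_bins = profile.shape
    if np.any(profile < 0):
        raise ValueError("binding profile must be nonnegative")
    if not 2.3 <= affinity <= 2.9:
        warnings.warn(f"affinity {affinity} outside the usual 2.3-2.9 kBT range", stacklevel=2)
    if anchors is not None and len(anchors) and anchors.beads.max() >= n_bins:
        raise ValueError(
            f"anchor index {anchors.beads.max()} outside the {n_bins}-bin profile"
        )
    # bead type = argmax row where any site present, else inert (last code)
    inert = n_types
    body = np.where(profile.sum(axis=0) > 0, profile.argmax(axis=0), inert)
    types = np.concatenate([np.full(n_tail, inert), body, np.full(n_tail, inert)])
    aff = np.full((n_types, n_types + 1), hetero_affinity)
    np.fill_diagonal(aff[:, :n_types], affinity)
    aff[:, inert] = 0.0
    shifted = None
    if anchors is not None and len(anchors):
        shifted = AnchorSet(anchors.beads + n_tail, anchors.orientations, anchors.probabilities)
    ext = ExtrusionParams(separation_kb=separation_kb, processivity_kb=processivity_kb)
    if not 50 <= separation_kb <= 100:
        warnings.warn(f"separation {separation_kb} kb outside 50-100 kb", stacklevel=2)
    if not 150 <= processivity_kb <= 400:
        warnings.warn(f"processivity {processivity_kb} kb outside 150-400 kb", stacklevel=2)
    return PolymerModel(
        bead_types=types,
        type_labels=[f"type{t}" for t in range(n_types)] + ["inert"],
        g_bp=g_bp,
        affinity_matrix=aff,
        r_int=2.5,
        anchors=shifted,
        extrusion=ext,
        n_tail=n_tail,
        name=name,
    )


def infected_variant(
    model: PolymerModel,
    affinity_reduction: float = 0.175,
    density_factor: float = 0.5,
) -> PolymerModel:
    """Infected-condition transform of a control locus model.

    Halves the extruder density (separation doubled by default) and reduces
    all attractive affinities by ``affinity_reduction`` (default 17.5%, the
    midpoint of the 15-20% range), leaving everything else untouched, so
    control-vs-infected comparisons are parameterised rather than
    hand-edited.
    """
    if not 0 < affinity_reduction < 1:
        raise ValueError("affinity_reduction must be in (0, 1)")
    if model.extrusion is None:
        ext = None
    else:
        ext = replace(model.extrusion)
        if ext.separation_kb is not None:
            ext.separation_kb = ext.separation_kb / density_factor
        elif ext.n_extruders is not None:
            ext.n_extruders = max(int(round(ext.n_extruders * density_factor)), 0)
    return replace(
        model,
        affinity_matrix=model.affinity_matrix * (1.0 - affinity_reduction),
        extrusion=ext,
        name=model.name + "_infected",
    )
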