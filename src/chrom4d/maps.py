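"""Contact maps, contact probability P(s), fold changes and triplet contacts.

A contact between beads i, j is declared in a single conformation when
their Euclidean distance is below a threshold A (in sigma; A is taken in
the 2-3.5 range, default 3 for compartment/TAD models).  Per-conformation
boolean maps are averaged, replicas weighted equally regardless of their
frame counts, giving a symmetric frequency matrix with unit diagonal.

Triplet contacts generalise this: fixing a viewpoint bead i, the triple
(i, j, k) is in contact when all three mutual distances are below the
triplet threshold (default 5 sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .state import Ensemble, Trajectory

__all__ = [
    "ContactMap",
    "TripletMatrix",
    "contact_map",
    "contact_probability",
    "average_submatrices",
    "log2_fold_change",
    "triplet_matrix",
    "triplet_significance",
]


@dataclass
class ContactMap:
    """Symmetric bead-by-bead contact-frequency matrix with metadata."""

    matrix: np.ndarray
    bin_bp: float = 0.0
    threshold: float = 3.0
    n_conformations: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact map must be symmetric")
        if m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9):
            raise ValueError("contact frequencies must lie in [0, 1]")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TripletMatrix:
    """Triple-contact frequencies (i, j, k) for a fixed viewpoint i."""

    matrix: np.ndarray
    viewpoint: int
    threshold: float = 5.0
    n_conformations: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("triplet matrix must be symmetric in (j, k)")
        self.matrix = m


def _frames_of(ensemble) -> list[np.ndarray]:
    """Per-replica stacks of bead coordinates."""
    if isinstance(ensemble, Ensemble):
        return [t.positions() for t in ensemble]
    if isinstance(ensemble, Trajectory):
        return [ensemble.positions()]
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return [arr]


def _bool_map(pos: np.ndarray, threshold: float) -> np.ndarray:
    """Mean over frames of the boolean contact map of one replica."""
    n = pos.shape[1]
    acc = np.zeros((n, n))
    for frame in pos:
        d = squareform(pdist(frame))
        acc += d < threshold
    return acc / pos.shape[0]


def contact_map(ensemble, threshold: float = 3.0, bin_bp: float = 0.0) -> ContactMap:
    """Ensemble-averaged contact map at distance threshold A (sigma).

    Accepts an :class:`Ensemble`, a :class:`Trajectory`, or a raw
    (n_frames, n_beads, 3) / (n_beads, 3) coordinate array.  Replicas are
    weighted equally: the per-replica frame averages are averaged.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    reps = _frames_of(ensemble)
    if not reps or reps[0].shape[0] == 0:
        raise ValueError("need at least one conformation")
    mats = [_bool_map(r, threshold) for r in reps]
    mean = np.mean(mats, axis=0)
    np.fill_diagonal(mean, 1.0)
    n_conf = sum(r.shape[0] for r in reps)
    return ContactMap(matrix=mean, bin_bp=bin_bp, threshold=threshold,
                      n_conformations=n_conf)


def contact_probability(cmap: ContactMap | np.ndarray, scale: float = 1.0) -> np.ndarray:
    """P(s): mean contact frequency of each diagonal, s = 0 .. n-1.

    ``scale`` is an optional global multiplicative coefficient applied
    identically across conditions when mapping onto an experimental range.
    """
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    n = m.shape[0]
    return np.array([m.diagonal(s).mean() for s in range(n)]) * scale


def average_submatrices(cmap: ContactMap, k: int) -> ContactMap:
    """Element-wise mean of k equal consecutive diagonal blocks.

    Used for presentation: a map built from k statistically identical
    blocks is shown as their average.  A remainder that does not fit the
    blocking is dropped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = cmap.matrix
    n = m.shape[0]
    b = n // k
    if b == 0:
        raise ValueError(f"map of size {n} cannot be split into {k} blocks")
    if n % k:
        import warnings

        warnings.warn(f"dropping remainder of {n % k} bins", stacklevel=2)
    blocks = [m[i * b:(i + 1) * b, i * b:(i + 1) * b] for i in range(k)]
    return ContactMap(matrix=np.mean(blocks, axis=0), bin_bp=cmap.bin_bp,
                      threshold=cmap.threshold, n_conformations=cmap.n_conformations)


def log2_fold_change(map_a: ContactMap | np.ndarray, map_b: ContactMap | np.ndarray,
                     pseudocount: float | None = None) -> np.ndarray:
    """log2((a + pc) / (b + pc)) entry-wise.

    The default pseudocount is 1e-2 times the smallest nonzero entry of
    either map, which keeps zero cells finite without distorting the bulk.
    """
    a = map_a.matrix if isinstance(map_a, ContactMap) else np.asarray(map_a, dtype=float)
    b = map_b.matrix if isinstance(map_b, ContactMap) else np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if pseudocount is None:
        nz = np.concatenate([a[a > 0].ravel(), b[b > 0].ravel()])
        pseudocount = 1e-2 * nz.min() if nz.size else 1e-6
    return np.log2((a + pseudocount) / (b + pseudocount))


def triplet_matrix(ensemble, viewpoint: int, threshold: float = 5.0) -> TripletMatrix:
    """Triple-contact frequency matrix for a fixed viewpoint bead.

    For each conformation, cell (j, k) is 1 when d(i,j), d(j,k) and d(k,i)
    are all below the threshold; frequencies average these indicators over
    the ensemble.  Symmetric in (j, k) by construction.
    """
    reps = _frames_of(ensemble)
    n = reps[0].shape[1]
    if not 0 <= viewpoint < n:
        raise ValueError(f"viewpoint {viewpoint} outside polymer of {n} beads")
    mats = []
    for pos in reps:
        acc = np.zeros((n, n))
        for frame in pos:
            d = squareform(pdist(frame))
            near_i = d[viewpoint] < threshold
            near_i[viewpoint] = True
            sub = np.outer(near_i, near_i) & (d < threshold)
            acc += sub
        mats.append(acc / pos.shape[0])
    mean = np.mean(mats, axis=0)
    n_conf = sum(r.shape[0] for r in reps)
    return TripletMatrix(matrix=mean, viewpoint=viewpoint, threshold=threshold,
                         n_conformations=n_conf)


def _triple_indicator(pos: np.ndarray, triple: tuple[int, int, int],
                      threshold: float) -> np.ndarray:
    i, j, k = triple
    dij = np.linalg.norm(pos[:, i] - pos[:, j], axis=1)
    djk = np.linalg.norm(pos[:, j] - pos[:, k], axis=1)
    dki = np.linalg.norm(pos[:, k] - pos[:, i], axis=1)
    return ((dij < threshold) & (djk < threshold) & (dki < threshold)).astype(float)


def triplet_significance(ensemble, triple: tuple[int, int, int],
                         control_offset_bp: float = 100_000.0,
                         bin_bp: float = 500.0,
                         threshold: float = 5.0) -> float:
    """One-sided p-value that a triple is in contact more often than a
    control triple shifted downstream by ``control_offset_bp`` (preserving
    the relative genomic distances).

    Per-conformation binary triple-contact indicators of target and control
    are compared with a one-sided Mann-Whitney U test.
    """
    reps = _frames_of(ensemble)
    if not reps or reps[0].shape[0] == 0:
        raise ValueError("empty ensemble")
    n = reps[0].shape[1]
    offset = int(round(control_offset_bp / bin_bp))
    control = tuple(b + offset for b in triple)
    if max(control) >= n:
        raise ValueError(
            f"control triple {control} exceeds polymer of {n} beads"
        )
    target = np.concatenate([_triple_indicator(p, triple, threshold) for p in reps])
    ctrl = np.concatenate([_triple_indicator(p, control, threshold) for p in reps])
    if offset == 0:
        return 0.5  # identical samples: by construction never significant
    if target.std() == 0 and ctrl.std() == 0 and target.mean() == ctrl.mean():
        return 0.5
    return float(mannwhitneyu(target, ctrl, alternative="greater").pvalue)
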