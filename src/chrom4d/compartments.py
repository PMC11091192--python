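"""Compartment eigenvector (E1), saddle plots and compartment strength.

The pipeline mirrors the standard Hi-C compartment analysis: divide each
diagonal of the contact map by its mean (observed/expected), take the
Pearson correlation matrix of the result, and use its leading eigenvector
E1; the sign is oriented so that E1 correlates positively with a supplied
orientation track (any signal higher in A, e.g. GC content).  Saddle plots
average observed/expected contacts between quantile bins of ranked E1
(equal occupancy, default 50 bins); compartment strength is the ratio of
the homo-typic corner means to the hetero-typic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import ContactMap

__all__ = ["SaddlePlot", "observed_expected", "compute_e1", "saddle_plot",
           "compartment_strength"]

#: diagonals with fewer entries than this are excluded from the expected
#: estimate (their O/E is set to 1)
MIN_DIAG_ENTRIES = 10


@dataclass
class SaddlePlot:
    """b-by-b matrix of mean O/E contacts ordered by ranked E1 (ascending:
    strongest B first, strongest A last)."""

    matrix: np.ndarray
    e1: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.n_bins < 2:
            raise ValueError("saddle needs at least 2 bins")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("saddle entries must be finite")


def _as_matrix(cmap) -> np.ndarray:
    return cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)


def observed_expected(cmap) -> np.ndarray:
    """O/E transform: each diagonal divided by its mean.

    Diagonals with fewer than ``MIN_DIAG_ENTRIES`` entries (the far corner)
    or a zero mean are set to 1 rather than contributing noise.
    """
    m = _as_matrix(cmap)
    n = m.shape[0]
    oe = np.ones_like(m)
    for s in range(n):
        d = m.diagonal(s)
        if d.size < MIN_DIAG_ENTRIES and s > 0:
            continue
        mu = d.mean()
        if mu > 0:
            vals = d / mu
            idx = np.arange(n - s)
            oe[idx, idx + s] = vals
            oe[idx + s, idx] = vals
    return oe


def compute_e1(cmap, orientation_track: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the O/E Pearson-correlation matrix.

    The sign is flipped if needed so that corr(E1, orientation_track) >= 0.
    Raises on maps too small or degenerate for the O/E + PCA pipeline.
    """
    m = _as_matrix(cmap)
    n = m.shape[0]
    track = np.asarray(orientation_track, dtype=float)
    if track.size != n:
        raise ValueError("orientation track length must match the map")
    if n <= MIN_DIAG_ENTRIES:
        raise ValueError(f"map of size {n} too small for O/E + PCA")
    oe = observed_expected(m)
    if np.allclose(oe.std(axis=0), 0):
        raise ValueError("degenerate (constant) map: no compartment signal")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    w, v = np.linalg.eigh(corr)
    e1 = v[:, -1]
    c = np.corrcoef(e1, track)[0, 1]
    if np.isfinite(c) and c < 0:
        e1 = -e1
    return e1


def saddle_plot(cmap, e1: np.ndarray, n_bins: int = 50) -> SaddlePlot:
    """Mean O/E contact between equal-occupancy quantile bins of ranked E1."""
    m = _as_matrix(cmap)
    n = m.shape[0]
    e1 = np.asarray(e1, dtype=float)
    if e1.size != n:
        raise ValueError("e1 length must match the map")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds map size {n}")
    oe = observed_expected(m)
    order = np.argsort(e1, kind="stable")
    # equal-occupancy assignment: rank r goes to bin floor(r * b / n)
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = (np.arange(n) * n_bins) // n
    sad = np.zeros((n_bins, n_bins))
    cnt = np.zeros((n_bins, n_bins))
    np.add.at(sad, (bin_of[:, None].repeat(n, 1), bin_of[None, :].repeat(n, 0)), oe)
    np.add.at(cnt, (bin_of[:, None].repeat(n, 1), bin_of[None, :].repeat(n, 0)), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, sad / np.maximum(cnt, 1), 1.0)
    return SaddlePlot(matrix=out, e1=e1, n_bins=n_bins)


def compartment_strength(saddle: SaddlePlot, corner_fraction: float = 0.2) -> float:
    """(mean BB corner + mean AA corner) / (2 * mean AB corner).

    Corners are the top/bottom ``corner_fraction`` of the ranked-E1 bins:
    BB is the low-E1 x low-E1 corner, AA the high x high corner, AB the
    off-diagonal corner.  A flat saddle gives exactly 1.
    """
    b = saddle.n_bins
    k = max(int(round(corner_fraction * b)), 1)
    m = saddle.matrix
    bb = m[:k, :k].mean()
    aa = m[-k:, -k:].mean()
    ab = 0.5 * (m[:k, -k:].mean() + m[-k:, :k].mean())
    if ab == 0:
        raise ValueError("hetero-typic corner mean is zero")
    return float((aa + bb) / (2.0 * ab))


def corner_means(saddle: SaddlePlot, corner_fraction: float = 0.2) -> tuple[float, float, float]:
    """(BB, AA, AB) corner means -- used for asymmetric-compartment tests."""
    b = saddle.n_bins
    k = max(int(round(corner_fraction * b)), 1)
    m = saddle.matrix
    bb = float(m[:k, :k].mean())
    aa = float(m[-k:, -k:].mean())
    ab = float(0.5 * (m[:k, -k:].mean() + m[-k:, :k].mean()))
    return bb, aa, ab
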