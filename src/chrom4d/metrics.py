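"""Shape descriptors, physical-unit mapping and contact-time dynamics.

Shape of a conformation comes from the gyration tensor

    G_ab = (1/N) sum_i (x_{a,i} - x_{a,CM}) (x_{b,i} - x_{b,CM}),

with eigenvalues l1 <= l2 <= l3.  Anisotropy is
``1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2`` (0 for a sphere, 1
for a rod).  Asphericity is implemented as ``l3 - (l1 + l2)/2``, i.e. the
deviation of the *largest* eigenvalue from the mean of the other two, so a
sphere gives 0 and a rod a positive value; with ascending eigenvalue
ordering the same expression on the smallest eigenvalue would be negative
for elongated chains, so the orientation towards the largest eigenvalue is
the documented convention here.

Reduced units map to physical ones via sigma = (g/G)^(1/3) * D with D the
nuclear diameter (7 um) and G the genome size (6.6 Gbp): 500 bp per bead
gives sigma ~ 30 nm.  The Brownian time tau = eta * 6 pi sigma^3 / kBT is
evaluated exactly as written; see the methods note about the magnitude of
this estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.constants as const
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull, QhullError

from .state import Trajectory

__all__ = [
    "ShapeStats",
    "ContactTimeSeries",
    "gyration_shape",
    "hull_volume",
    "map_length_scale",
    "map_time_scale",
    "distance_series",
    "smooth_series",
    "contact_times",
    "cooccurrence_fraction",
]


@dataclass
class ShapeStats:
    """Gyration-tensor shape descriptors of one conformation."""

    tensor: np.ndarray          # (3, 3)
    eigenvalues: np.ndarray     # ascending, sigma^2
    anisotropy: float
    asphericity: float          # sigma^2
    rg2: float                  # squared radius of gyration = trace(G)


def gyration_shape(coords: np.ndarray) -> ShapeStats:
    """Gyration tensor, eigenvalues, anisotropy and asphericity.

    Requires at least 2 beads of unwrapped coordinates; collinear chains
    give anisotropy exactly 1, spherically symmetric clouds 0.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if x.shape[0] < 2:
        raise ValueError("shape descriptors need at least 2 beads")
    d = x - x.mean(axis=0)
    G = d.T @ d / x.shape[0]
    lam = np.linalg.eigvalsh(G)          # ascending
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    if tr == 0:
        raise ValueError("degenerate conformation: all beads coincide")
    aniso = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
    asph = lam[2] - 0.5 * (lam[0] + lam[1])
    return ShapeStats(tensor=G, eigenvalues=lam, anisotropy=float(aniso),
                      asphericity=float(asph), rg2=float(tr))


def hull_volume(coords: np.ndarray, sigma_nm: float = 1.0) -> float:
    """Convex-hull volume of a conformation, in sigma^3 scaled by sigma_nm^3."""
    x = np.asarray(coords, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("convex hull needs at least 4 beads")
    try:
        hull = ConvexHull(x)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar/collinear) conformation: {exc}") from exc
    return float(hull.volume) * sigma_nm**3


def map_length_scale(g_bp: float, G_bp: float = 6.6e9, D_nm: float = 7000.0) -> float:
    """Physical bead size: sigma = (g/G)^(1/3) * D, in nm.

    With g = 500 bp, the genome G = 6.6 Gbp and nuclear diameter D = 7 um
    this gives sigma ~ 30 nm, the working scale of the locus models.
    """
    if g_bp <= 0:
        raise ValueError("genomic content per bead must be positive")
    if g_bp > G_bp:
        raise ValueError("bead content cannot exceed the genome")
    return (g_bp / G_bp) ** (1.0 / 3.0) * D_nm


def map_time_scale(eta_Pa_s: float = 2e-4, sigma_nm: float = 29.6,
                   T_K: float = 300.0) -> float:
    """Brownian time tau = eta * 6 pi sigma^3 / (kB T), in seconds.

    Evaluated exactly as written with eta in Pa*s (0.2 cP = 2e-4 Pa*s) and
    sigma in nm.  Scales as sigma^3 and linearly in eta; used only to label
    time axes.
    """
    if eta_Pa_s <= 0 or sigma_nm <= 0:
        raise ValueError("viscosity and sigma must be positive")
    sigma_m = sigma_nm * 1e-9
    return eta_Pa_s * 6.0 * np.pi * sigma_m**3 / (const.k * T_K)


@dataclass
class ContactTimeSeries:
    """Per-frame 3D distance between two loci, with frame spacing metadata."""

    distances_nm: np.ndarray
    frame_interval_steps: int = 1000
    frame_interval_s: float | None = None
    bead_i: int = 0
    bead_j: int = 0

    def __post_init__(self) -> None:
        self.distances_nm = np.asarray(self.distances_nm, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.distances_nm.mean())

    @property
    def sd(self) -> float:
        return float(self.distances_nm.std())


def distance_series(traj: Trajectory, bead_i: int, bead_j: int,
                    sigma_nm: float = 1.0,
                    frame_interval_s: float | None = None) -> ContactTimeSeries:
    """Euclidean distance between two beads in every frame, in nm."""
    pos = traj.positions()
    n = pos.shape[1]
    if not (0 <= bead_i < n and 0 <= bead_j < n):
        raise ValueError(f"bead indices ({bead_i}, {bead_j}) outside polymer of {n}")
    if bead_i == bead_j:
        warnings.warn("identical beads: distance series is identically zero", stacklevel=2)
    d = np.linalg.norm(pos[:, bead_i] - pos[:, bead_j], axis=1) * sigma_nm
    return ContactTimeSeries(distances_nm=d,
                             frame_interval_steps=traj.sample_interval,
                             frame_interval_s=frame_interval_s,
                             bead_i=bead_i, bead_j=bead_j)


def smooth_series(series: np.ndarray | ContactTimeSeries, window: int,
                  order: int = 1) -> np.ndarray:
    """Savitzky-Golay smoothing (local polynomial least squares).

    ``window`` must be odd and >= 3, ``order`` < ``window``; endpoints are
    handled by the filter's polynomial edge fit.  Order-1 smoothing leaves
    constants and linear ramps unchanged and strictly reduces the variance
    of noise.
    """
    y = series.distances_nm if isinstance(series, ContactTimeSeries) else np.asarray(series, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if window > y.size:
        raise ValueError(f"window {window} exceeds series length {y.size}")
    return savgol_filter(y, window_length=window, polyorder=order, mode="interp")


@dataclass
class ContactTimes:
    """Run-length decomposition of a distance series at a threshold."""

    durations: np.ndarray       # frames below threshold (interior runs)
    gaps: np.ndarray            # frames above threshold (interior runs)
    edge_runs: np.ndarray       # lengths of the censored first/last runs
    frame_interval_s: float | None = None

    @property
    def mean_contact_time(self) -> float | None:
        if self.durations.size == 0:
            return None
        m = float(self.durations.mean())
        return m * self.frame_interval_s if self.frame_interval_s else m

    @property
    def mean_gap(self) -> float | None:
        if self.gaps.size == 0:
            return None
        m = float(self.gaps.mean())
        return m * self.frame_interval_s if self.frame_interval_s else m


def contact_times(series: ContactTimeSeries | np.ndarray,
                  threshold_nm: float = 150.0,
                  include_edges: bool = False) -> ContactTimes:
    """Contact durations and inter-contact gaps at a distance threshold.

    Maximal runs below the threshold are contact durations, maximal runs
    above are gaps; the first and last runs of the series are open-ended
    (censored) and excluded from the means unless ``include_edges``.
    Durations, gaps and edge runs exactly tile the series.
    """
    if isinstance(series, ContactTimeSeries):
        y = series.distances_nm
        dt_s = series.frame_interval_s
    else:
        y = np.asarray(series, dtype=float)
        dt_s = None
    if y.size < 1:
        raise ValueError("series must contain at least one frame")
    below = y < threshold_nm
    # run-length encode
    change = np.nonzero(np.diff(below))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [y.size]])
    lengths = ends - starts
    states = below[starts]
    interior = np.ones(len(lengths), dtype=bool)
    edge_lengths = np.array([], dtype=int)
    if not include_edges:
        interior[0] = False
        interior[-1] = False
        if len(lengths) == 1:
            edge_lengths = lengths[:1]
        else:
            edge_lengths = lengths[[0, -1]]
    durations = lengths[interior & states]
    gaps = lengths[interior & ~states]
    return ContactTimes(durations=durations, gaps=gaps, edge_runs=edge_lengths,
                        frame_interval_s=dt_s)


def cooccurrence_fraction(traj: Trajectory | np.ndarray, elements, threshold: float,
                          sigma_nm: float = 1.0) -> float:
    """Fraction of frames in which >= 2 elements are all mutually close.

    A co-occurrence frame is one where *every* pairwise distance among the
    given bead indices is below ``threshold`` (same units as
    ``sigma_nm``-scaled coordinates) -- the all-pairs definition of a
    multi-way colocalisation event.
    """
    elements = list(elements)
    if len(elements) < 2:
        raise ValueError("need at least 2 elements")
    if len(set(elements)) != len(elements):
        raise ValueError("elements must be distinct")
    pos = traj.positions() if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    sub = pos[:, elements] * sigma_nm
    n_el = len(elements)
    ok = np.ones(pos.shape[0], dtype=bool)
    for a in range(n_el - 1):
        for b in range(a + 1, n_el):
            d = np.linalg.norm(sub[:, a] - sub[:, b], axis=1)
            ok &= d < threshold
    return float(ok.mean())
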