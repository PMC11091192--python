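"""Shared fixtures: tiny polymer systems and brute-force reference helpers."""

from __future__ import annotations

import numpy as np
import pytest

import chrom4d as c4


@pytest.fixture
def rng():
    """Fresh, identically seeded generator per test: results never depend
    on test ordering or selection."""
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def rod20():
    """A straight rod of 20 beads with unit bonds along x."""
    x = np.zeros((20, 3))
    x[:, 0] = np.arange(20)
    return x


@pytest.fixture(scope="session")
def cloud_frames():
    """A 6-frame, 15-bead random-cloud 'trajectory' array for oracle tests."""
    return np.random.default_rng(7041).normal(scale=2.0, size=(6, 15, 3))


@pytest.fixture(scope="session")
def small_homopolymer_traj():
    """A short but real MD trajectory of a 40-bead homopolymer (no binders);
    session-scoped because the engine run is the expensive part."""
    model = c4.PolymerModel(
        bead_types=np.zeros(40, dtype=int), type_labels=["U"], g_bp=5000.0,
        affinity_matrix=np.zeros((1, 1)),
    )
    cfg = c4.SimulationConfig(box_L=12.0, n_equil_steps=2000,
                              n_production_steps=6000, sample_interval=1000,
                              rng_seed=11)
    sim = c4.Simulator(model, cfg)
    return sim.run_replica(seed=11)


def brute_contact_map(frames: np.ndarray, threshold: float) -> np.ndarray:
    """Triple-loop reference for the ensemble contact map."""
    n_frames, n, _ = frames.shape
    acc = np.zeros((n, n))
    for f in range(n_frames):
        for i in range(n):
            for j in range(n):
                d = np.sqrt(((frames[f, i] - frames[f, j]) ** 2).sum())
                acc[i, j] += 1.0 if d < threshold else 0.0
    out = acc / n_frames
    np.fill_diagonal(out, 1.0)
    return out


def brute_triplet_matrix(frames: np.ndarray, viewpoint: int, threshold: float) -> np.ndarray:
    """Quadruple-loop reference for the triplet-contact matrix."""
    n_frames, n, _ = frames.shape
    acc = np.zeros((n, n))
    for f in range(n_frames):
        d = np.sqrt(((frames[f][:, None] - frames[f][None, :]) ** 2).sum(-1))
        for j in range(n):
            for k in range(n):
                if d[viewpoint, j] < threshold and d[j, k] < threshold and d[k, viewpoint] < threshold:
                    acc[j, k] += 1.0
    return acc / n_frames


def brute_gyration_tensor(x: np.ndarray) -> np.ndarray:
    """Direct double-sum evaluation of the gyration tensor definition."""
    n = x.shape[0]
    cm = x.mean(axis=0)
    G = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            for i in range(n):
                G[a, b] += (x[i, a] - cm[a]) * (x[i, b] - cm[b])
    return G / n
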