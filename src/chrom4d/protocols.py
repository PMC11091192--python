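"""Reference study protocols at desk scale.

These functions bundle the scaled-down study conditions used for the
directional physics experiments: a 200-bead block copolymer (25-bead
blocks, 10 kb/bead) with the standard affinities (hetero-typic 3.1 kBT,
homo-typic 3.2-3.4 kBT) and a Langevin schedule of 1e5 equilibration +
5e4 production steps (frames every 5e3 steps, 10 replicas), and a
150-bead locus model (500 bp/bead, r_int = 2.5) for gene-enhancer
dynamics with fine (1e3-step) sampling.  The schedules are far shorter
than full-scale equilibration, and equilibration length matters more
than chain length for compartment demixing at this scale, so the
polymer is kept short and the schedule long; the conditions were chosen
once in calibration pilots so that micro-phase separation is developed
enough for directional comparisons while a complete experiment series
runs on a single CPU, and are documented in the methods note.

For the extrusion-depletion comparison, processivity is deliberately
larger than the compartment block (100 beads vs 25), preserving the
mechanism by which extrusion opposes compartmentalisation -- loops that
cross block boundaries -- at reduced polymer length.
"""

from __future__ import annotations

import numpy as np

from .builders import PolymerModel, build_compartment_model, build_locus_model, infected_variant
from .compartments import compartment_strength, compute_e1, corner_means, saddle_plot
from .config import SimulationConfig
from .engine import run_replicas
from .extrusion import AnchorSet, BIDIRECTIONAL, ExtrusionParams
from .maps import contact_map
from .metrics import contact_times, distance_series, map_length_scale

__all__ = [
    "COMPARTMENT_N", "COMPARTMENT_BLOCK", "compartment_config",
    "run_compartment_experiment", "locus_models", "run_locus_metrics",
]

# frozen desk-scale study conditions
COMPARTMENT_N = 200
COMPARTMENT_BLOCK = 25
COMPARTMENT_G_BP = 10_000.0
BOX_L = 12.0
N_EQUIL = 100_000
N_PROD = 50_000
SAMPLE = 2_500
CONTACT_THRESHOLD = 3.0
SADDLE_BINS = 20

LOCUS_BINS = 100
LOCUS_TAIL = 25
LOCUS_GENE, LOCUS_ENHANCER = 30, 70   # profile-grid positions
LOCUS_SIGMA_NM = map_length_scale(500.0)


def compartment_config(n_replicas: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        box_L=BOX_L, n_equil_steps=N_EQUIL, n_production_steps=N_PROD,
        sample_interval=SAMPLE, n_replicas=n_replicas, rng_seed=seed,
    )


def run_compartment_experiment(
    E_AA: float = 3.3,
    E_BB: float = 3.3,
    extrusion: ExtrusionParams | None = None,
    n_replicas: int = 10,
    seed: int = 0,
    ranking: str = "e1",
) -> dict:
    """Simulate one compartment condition and summarise its saddle.

    ``ranking`` chooses the saddle summary: ``"e1"`` ranks by the map's
    own compartment eigenvector (sign-oriented on the planted labels) and
    uses the quantile saddle with 20% corners; ``"planted"`` bins directly
    by the known block labels into a 2x2 quadrant saddle whose "corners"
    are the full A-A, B-B and A-B quadrant means over every far pair --
    the ground-truth segregation measure for builder-generated polymers,
    free of eigenvector instability and quantile-corner artefacts at
    desk-scale sampling.

    Returns strength, corner means and the aggregated map.
    """
    model = build_compartment_model(
        n_beads=COMPARTMENT_N, block_size=COMPARTMENT_BLOCK,
        E_AA=E_AA, E_BB=E_BB, E_AB=3.1, g_bp=COMPARTMENT_G_BP,
    )
    model.extrusion = extrusion
    ens = run_replicas(model, compartment_config(n_replicas, seed))
    cmap = contact_map(ens, threshold=CONTACT_THRESHOLD, bin_bp=COMPARTMENT_G_BP)
    labels = np.where(model.bead_types == 0, 1.0, -1.0)
    if ranking == "e1":
        order = compute_e1(cmap, labels)
        sad = saddle_plot(cmap, order, n_bins=SADDLE_BINS)
        corner = 0.2
    elif ranking == "planted":
        sad = saddle_plot(cmap, labels, n_bins=2)
        corner = 0.5
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    bb, aa, ab = corner_means(sad, corner)
    return {
        "strength": compartment_strength(sad, corner),
        "bb": bb, "aa": aa, "ab": ab,
        "map": cmap, "saddle": sad, "labels": labels, "ensemble": ens,
    }


def depletion_extrusion_params() -> ExtrusionParams:
    """Extruder population for the depletion comparison: 8 extruders with
    1 Mb (100-bead) processivity on the 200-bead copolymer, no anchors, so
    loops freely cross the 25-bead compartment blocks."""
    return ExtrusionParams(n_extruders=8, processivity_kb=1000.0)


def _locus_profile(seed: int = 1) -> np.ndarray:
    """Two-type binding profile with type-0 clusters at the gene and
    enhancer positions plus scattered intervening sites."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((2, LOCUS_BINS), dtype=int)
    for centre in (LOCUS_GENE, LOCUS_ENHANCER):
        counts[0, centre - 2:centre + 3] = 1
    counts[0, rng.choice(np.arange(35, 66), 6, replace=False)] = 1
    counts[1, rng.choice(np.arange(0, 25), 8, replace=False)] = 1
    counts[1, rng.choice(np.arange(76, 100), 8, replace=False)] = 1
    return counts


def locus_models(profile_seed: int = 1) -> tuple[PolymerModel, PolymerModel, int, int]:
    """Mock and infected locus models plus gene/enhancer bead indices.

    The mock model is a 150-bead locus (100 typed bins + 25-bead inert
    tails) with convergent-domain anchors flanking the gene-enhancer pair;
    the infected variant halves the extruder density and reduces all
    affinities by 17.5%.
    """
    anchors = AnchorSet(np.array([20, 80]), np.array([BIDIRECTIONAL] * 2),
                        np.array([1.0, 1.0]))
    mock = build_locus_model(
        _locus_profile(profile_seed), anchors=anchors, n_tail=LOCUS_TAIL,
        affinity=2.9, separation_kb=50.0, processivity_kb=300.0, name="locus_mock",
    )
    infected = infected_variant(mock)
    return mock, infected, LOCUS_GENE + LOCUS_TAIL, LOCUS_ENHANCER + LOCUS_TAIL


def run_locus_metrics(model: PolymerModel, gene: int, enhancer: int,
                      n_replicas: int = 20, seed: int = 0) -> dict:
    """Fine-sampled locus simulation and per-replica dynamics metrics.

    Returns per-replica arrays: mean and SD of the gene-enhancer 3D
    distance (nm), mean contact time at the 150 nm threshold (frames, NaN
    when a replica never establishes an interior contact run), and the
    mean intra-domain contact frequency between the anchors.
    """
    cfg = SimulationConfig(
        box_L=14.0, n_equil_steps=20_000, n_production_steps=100_000,
        sample_interval=1_000, n_replicas=n_replicas, rng_seed=seed,
    )
    ens = run_replicas(model, cfg)
    lo, hi = LOCUS_TAIL + 20, LOCUS_TAIL + 80
    means, sds, cts, intra = [], [], [], []
    for traj in ens:
        ser = distance_series(traj, gene, enhancer, sigma_nm=LOCUS_SIGMA_NM)
        means.append(ser.mean)
        sds.append(ser.sd)
        # edge runs are included: a replica glued below the threshold for a
        # whole window is a maximally stable contact, not missing data
        ct = contact_times(ser, threshold_nm=150.0, include_edges=True)
        cts.append(np.nan if ct.mean_contact_time is None else ct.mean_contact_time)
        cm = contact_map(traj, threshold=CONTACT_THRESHOLD)
        sub = cm.matrix[lo:hi, lo:hi]
        intra.append(sub[np.triu_indices(hi - lo, k=5)].mean())
    return {
        "mean_distance_nm": np.array(means),
        "sd_distance_nm": np.array(sds),
        "mean_contact_time_frames": np.array(cts),
        "intra_domain_contact": np.array(intra),
        "ensemble": ens,
    }
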