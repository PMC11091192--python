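# chrom4d

Multiscale chromatin polymer simulation and Hi-C-style analysis in one
package: a bead-spring Langevin MD engine combining **binder-mediated
phase separation** (the strings-and-binders picture of compartments) with
**loop extrusion** (cohesin-like factors blocked at convergent CTCF
anchors), plus the full analysis layer used on the resulting
conformational ensembles — contact maps and P(s) curves, compartment
eigenvectors and saddle plots, convex mixture fitting of population
heterogeneity, triplet (three-way) contacts, polymer shape descriptors,
gene–enhancer contact-time dynamics, simulated-annealing inference of
binding sites from contact maps, and epigenetic cross-correlation of the
inferred site types.

It is written for computational chromatin biologists who want to test
mechanistic hypotheses — e.g. *does weakening homo-typic A–A affinity
reproduce the compartment weakening seen after a perturbation?* — on
synthetic or binned experimental contact matrices, without cluster-scale
infrastructure.

## Model in brief

Chromatin is a chain of N beads (diameter σ, FENE bonds, R0 = 1.6 σ,
K = 30 kBT/σ²) with typed binding sites; diffusing binders bridge cognate
sites through a truncated-shifted Lennard-Jones well

    V(r) = 4ε[(σ/r)¹² − (σ/r)⁶ − (σ/r_int)¹² + (σ/r_int)⁶ ],   r < r_int,

whose depth |min V| is the quoted binding affinity (3.1–3.8 kBT at
compartment/TAD scale). Micro-phase separation of A/B blocks requires
E_AA, E_BB > E_AB. Loop extruders are harmonic springs that slide one
bead outward every 500 MD steps, stall at each other, and halt at engaged
convergent anchors; detachment at rate k_off gives processivity
proc = 2g/k_off for genomic content g per bead. Dynamics are Langevin
(T = 1, ζ = 0.5, dt = 0.01, BAOAB splitting) in a periodic box. Lengths
map to physical units via σ = (g/G)^{1/3}·D (σ ≈ 30 nm at 500 bp/bead).
See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic compartment map with a weakened A compartment (the
kind of change seen after perturbations that disrupt A–A interactions),
call compartments, and quantify the asymmetry:

```python
import chrom4d as c4
import numpy as np
from chrom4d.compartments import corner_means

spec = c4.SyntheticSpec(n_bins=200, block_size=25, compartment_strength=0.5,
                        a_weakening=0.8, noise=0.05, seed=42)
cmap, labels = c4.synth_compartment_map(spec)
e1  = c4.compute_e1(cmap, labels)            # leading O/E-correlation eigenvector
sad = c4.saddle_plot(cmap, e1, n_bins=20)    # ranked-E1 saddle
bb, aa, ab = corner_means(sad)
print(f"compartment strength: {c4.compartment_strength(sad):.2f}")
print(f"corner means  BB={bb:.2f}  AA={aa:.2f}  AB={ab:.2f}")
```

prints

```
compartment strength: 1.31
corner means  BB=1.21  AA=0.97  AB=0.84
```

— homo-typic corners above the hetero-typic one (strength > 1 means
segregated compartments), and BB > AA because A–A contacts were weakened
by the planted factor 0.8. The E1 sign call recovers the planted A/B
labels on all 200 bins. A mixed population is decomposed by a
simplex-constrained fit:

```python
mix = 0.6 * healthy.matrix + 0.4 * infected.matrix
res = c4.SimplexMixture(mix, [healthy.matrix, infected.matrix],
                        kind="saddle", basis_ids=["healthy", "infected"]).fit()
print(res.summary())
```

```
Simplex mixture fit
----------------------------------------
healthy                    0.6000
infected                   0.4000
----------------------------------------
objective (SSQ)          8.08421e-30
```

Simulations follow the same pattern — build a model, run replicas,
analyse the ensemble:

```python
model = c4.build_compartment_model(n_beads=400, block_size=25,
                                   E_AA=3.3, E_BB=3.3, E_AB=3.1, g_bp=10_000)
cfg = c4.SimulationConfig(box_L=15, n_equil_steps=40_000,
                          n_production_steps=20_000, sample_interval=4_000,
                          n_replicas=10, rng_seed=1)
ens  = c4.run_replicas(model, cfg)
cmap = c4.contact_map(ens, threshold=3.0)
```

A thin CLI (`chrom4d simulate|contactmap|ps|saddle|fit|triplets|shapes|
dynamics|infer|episcan|synth`) wraps the same functions and writes a
provenance manifest next to every output.

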