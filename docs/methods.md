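# Methods

`chrom4d` simulates chromatin as a bead-spring polymer folded by two
mechanisms — binder-mediated phase separation and loop extrusion — and
analyses the resulting conformational ensembles the way binned Hi-C data
are analysed. This note records the model, the numerical choices, the
scaled-down study conditions the tests run at, and the limits of what
those tests demonstrate.

## Polymer and binder model

The chromatin fibre is a chain of `N` beads of diameter σ = 1 and mass
m = 1 (reduced Lennard-Jones units); diffusing binders are spheres of the
same diameter. Consecutive beads are linked by FENE bonds with maximum
extension R0 = 1.6 σ and spring constant 30 kBT/σ². Every particle pair
repels through a WCA core (truncated purely repulsive LJ, ε = 1, cut at
2^{1/6} σ). A binder of type t attracts a bead of type c through a
truncated-and-shifted LJ well,

    V(r) = 4ε [ (σ/r)^12 − (σ/r)^6 − (σ/r_int)^12 + (σ/r_int)^6 ],  r < r_int,

identically zero beyond the cutoff (r_int = 1.3 σ for compartment- and
TAD-scale models, 2.5 σ for locus models). Published affinities quote the
*depth of this well*, |min V|, not the bare ε; `PolymerModel` therefore
stores affinities in kBT and the engine converts through the exact linear
map (at r_int = 1.3, affinity = 0.343 ε, so the usual 3.1–3.8 kBT range
corresponds to ε ≈ 9–11).

Binder concentration is a model input the literature pins down only as
"above the coil–globule transition". The default is 0.5 binders per
cognate bead, calibrated once against that transition (a 3.1 kBT
homopolymer collapses from Rg ≈ 6 σ to ≈ 3 σ at this concentration, and a
doubled concentration begins to re-swell the chain by saturating sites)
and then held fixed everywhere.

## Dynamics

The system obeys the Langevin equation at T = 1, friction ζ = 0.5,
integrated with the BAOAB splitting at dt = 0.01: half kick, half drift,
exact Ornstein–Uhlenbeck velocity refresh, half drift, half kick. With
ζ = 0 and the noise off this is exactly velocity Verlet; the test suite
verifies total-energy conservation (drift < 0.02 kBT per particle over
10⁴ steps from a thermalised state) and kinetic temperature within 5% of
target under the thermostat. Initial polymer conformations are
self-avoiding walks grown with backtracking on the unit cubic lattice
(unit bonds, no two beads closer than 1 σ); binders start uniformly at
random, rejecting placements closer than 0.9 σ to any particle.

Positions are stored wrapped in the periodic cubic box with integer image
counters; unwrapped polymer coordinates — required by every shape,
distance and contact analysis — are reconstructed exactly as
`x + img·L`. Nonbonded forces use a Verlet pair list (cell-assisted
build, 0.4 σ skin) rebuilt when any particle has moved more than half the
skin; the list's forces are bit-reproducible against an all-pairs
reference, which is under test. Runs are deterministic given the replica
seed: SAW growth, binder placement, thermostat noise and extrusion
randomness all flow from one PCG64 generator per replica.

## Loop extrusion

Extruders are harmonic springs (K = 10 kBT/σ², rest length 1.1 σ) between
two legs that slide one bead outward every 500 MD steps. A leg stalls
while the next bead is occupied by another extruder's leg (no
pass-through; it retries on later updates), halts at the polymer ends,
and halts permanently when it lands on an *engaged* anchor whose
orientation opposes its travel: forward ("+") anchors block leftward
travel, reverse ("−") block rightward, so convergent pairs enclose a
domain; bidirectional anchors block both. Engagement is drawn once per
extruder–anchor encounter with the anchor's probability and remembered
until that extruder detaches. A halted leg's partner continues extruding
(one-sided continuation; configurable). Detachment is stochastic with
per-update probability 1 − exp(−k_off); a detached extruder is re-seeded
at a random free position so the population size is invariant. Since a
free extruder grows its loop by 2 beads (2g in genomic units) per update
and survives 1/k_off updates on average, the mean extruded loop obeys
proc = 2g/k_off, which the Monte-Carlo test verifies to 10%. Anchor
probabilities derived from an occupancy signal are normalised to the
signal maximum by default (a global scaling is exposed), and extruders
update in a randomised order each step to break ties.

## Contact-map analysis

A contact is a pair distance below A σ (A in 2–3.5; default 3 for
compartment/TAD models). Per-conformation boolean maps are averaged,
weighting replicas equally regardless of frame counts. P(s) is the mean
of each diagonal. Triplet matrices fix a viewpoint bead and mark (j, k)
when all three mutual distances fall below 5 σ; significance of a chosen
triple is a one-sided Mann–Whitney test of per-conformation binary
indicators against a control triple shifted 100 kb downstream with the
same internal spacing. The fold-change pseudocount defaults to 10⁻² times
the smallest nonzero entry of either map.

Compartment calling divides each diagonal by its mean (diagonals with
fewer than 10 entries are left at 1), takes the Pearson correlation
matrix, and uses its leading eigenvector with the sign oriented against a
supplied track that is higher in A (planted labels in synthetic work, GC
content on real data). Saddle plots average O/E between equal-occupancy
quantile bins of ranked E1 (default 50 bins; 20 at desk scale), and
compartment strength is (AA + BB) / (2·AB) over the top/bottom 20% corner
bins.

## Mixture fitting

Population heterogeneity is modelled as a convex combination of
single-state summaries: coefficients are nonnegative and sum to one. The
least-squares problem is convex and is solved exactly by Lawson–Hanson
NNLS with the sum constraint as a heavily weighted extra equation;
exactly duplicated basis elements are collapsed with their mass assigned
to the first occurrence. For P(s) curves a single positive global scale
is fitted jointly (substituting d = scale·c reduces the joint problem to
plain NNLS) and the χ² is restricted to 15 kb–2.5 Mb.

## Binding-site inference (forward model declared)

The inference layer searches for the number of binding-site types and
their placements that best explain a contact map under a declared
mean-field forward model: a fixed power-law background
B(u,v) = 1/(1+|u−v|) plus a saturating function of the type-wise
co-occupancy E(u,v) = Σ_t n_{t,u} n_{t,v},

    predicted(u,v) = clip( B + 0.8·(1 − e^{−E}), 0, 1 ).

This is the simplest model consistent with binder-mediated bridging —
beads sharing site types contact more often — and deliberately does not
reproduce the full polymer thermodynamics of published inference
codes. The saturating form (rather than normalising by the matrix
maximum) keeps the cost locally updatable, so each Monte-Carlo move costs
O(n). The cost is the entry-wise squared difference plus λ × total site
count (λ = 10⁻⁴ by default), and the search is Metropolis simulated
annealing over site flips and relocations (a type change is a flip pair),
geometric cooling from T0 = 0.05 by 0.92 per stage. The number of types
is the smallest candidate whose penalised cost lies within 1% of the
best. Evaluation against planted profiles uses Hungarian matching of
type labels, which are arbitrary up to permutation.

## Epigenetic cross-correlation

Site types are compared with binned tracks (5 kb working resolution,
length-weighted binning) by Pearson correlation. The null randomly
permutes each type's site positions along the locus (preserving per-type
site counts; 10,000 draws by default), and correlations inside the 15th–
85th percentile band of the null — with the observed value included in
its own null, so a degenerate (0, 100) band keeps nothing — are zeroed.
Between-condition changes use the absolute correlation difference
against the same positional null (1,000 draws), one-sided, reporting the
top 4 smallest p-values with ties broken by larger absolute change.

## Synthetic data

Generators plant known structure in the formats the pipeline consumes:
checkerboard compartment maps (power-law decay of exponent 1, block
labels ±1 modulating contacts by 1 ± strength, optional A-weakening
factor multiplying A–A cells), locus maps from the inference forward
model plus Gaussian corner peaks at anchor pairs, and epigenetic tracks
built as ρ·z(profile) + √(1−ρ²)·noise. Map noise is multiplicative
log-normal (Hi-C-like overdispersion). Everything is deterministic under
its seed. These generators emulate the *statistical* structure of binned
Hi-C and ChIP-seq — they contain no sequencing depth, mappability or
normalisation artefacts — so closed-loop tests demonstrate correctness
of the algorithms, not robustness to raw-data pathologies.

## Desk-scale study conditions

Full-scale runs in this problem domain equilibrate 10³-bead polymers for
5×10⁷ steps; a laptop-scale test suite cannot. The frozen conditions in
`chrom4d.protocols` are: a 200-bead copolymer in 25-bead blocks
(10 kb/bead) in an L = 12 σ box, equilibrated 10⁵ steps and sampled
every 5×10³ over 5×10⁴ production steps, 10 replicas per condition; and a
150-bead locus model (100 typed bins, 25-bead inert tails, σ ≈ 30 nm)
sampled every 10³ steps over 10⁵ production steps, 20 replicas. Blocks
are smaller than the full-scale 75-bead blocks, and the chain shorter,
because micro-phase separation must develop within the shortened
schedule — calibration pilots showed equilibration length matters far
more than chain length for the directional comparisons; the box is
sized to keep binder concentration in the collapsed regime.

Two desk-scale readings deserve emphasis:

* **Extruder depletion.** Extrusion opposes compartmentalisation through
  loops that cross compartment boundaries, so at reduced polymer length
  the depletion comparison keeps processivity (100 beads) larger than the
  block (25 beads), with 8 unanchored extruders on the 200-bead chain. The comparison ranks the saddle by the planted block
  labels — the ground truth available for builder-generated polymers —
  because on these short schedules the map's own E1 mixes compartment
  signal with slow chain-relaxation modes. With E1 ranking, short-schedule
  runs can show the *opposite* direction (extrusion accelerates early
  coarsening kinetics), an artefact of incomplete equilibration rather
  than the equilibrium effect.
* **Contact times.** Locus contact-time comparisons include the censored
  edge runs: a replica that stays below the 150 nm threshold for its
  whole window is a maximally stable contact, and excluding it would both
  bias the mean downward and discard exactly the replicas carrying the
  signal. For descriptive run-length statistics the default remains to
  flag and exclude open-ended edge runs.

## Physical units

Lengths map to nanometres through σ = (g/G)^{1/3}·D with nuclear
diameter D = 7 μm and genome size G = 6.6 Gbp; g = 500 bp per bead gives
σ ≈ 29.6 nm. Times are labelled through the Brownian time
τ = 6πησ³/kBT. Evaluated literally with η = 0.2 cP, T = 300 K and
σ ≈ 29.6 nm this gives τ ≈ 2.4×10⁻⁵ s (0.024 ms); chromatin-polymer
studies usually quote ≈ 0.5 ms for comparable models, a factor that
presumably absorbs an effective nucleoplasmic viscosity much larger than
the dilute value. The function evaluates the formula as written and the
discrepancy is noted here rather than hidden in an adjusted constant;
time axes in physical units should be read as order-of-magnitude labels.

## Known limitations

* Desk-scale ensembles are far from equilibrium; all physics tests are
  directional comparisons under matched schedules, not absolute
  observables.
* The binding-site forward model is mean-field: recovered profiles are
  meaningful for maps whose enrichment is approximately bilinear in site
  co-occupancy, and the closed-loop tests use exactly that class.
* No bending rigidity, hydrodynamics, or GPU execution; binders are free
  Langevin spheres with no binder–binder or binder–extruder coupling.
* The matrix reader handles dense text maps only; balancing (ICE/KR) of
  experimental matrices is out of scope and must be done upstream.
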