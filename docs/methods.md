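# Methods

## The model

The nucleus is a fixed set of particles in reduced units (length
σ = 385 nm, Brownian time τ = 0.65 s, temperature T = 1):

* **Chromatin** — each chromosome is a chain of 100-KB beads
  (`ceil(length / 10⁵)` beads per chromosome, 0-based half-open bins; a
  trailing partial bin is kept as a full bead).  The diploid human
  genome is 22 autosome pairs plus X and Y — 46 chains whose homologs
  share length and compartment labels.  Each bead carries one label
  A (euchromatin), B (heterochromatin) or C (pericentromeric); labels
  are an input, not something the package calls from Hi-C.
* **Nucleoli and speckles** — free particles of nominal diameter 0.5 σ.
  Speckles carry a chemical state, P or dP.
* **Lamina** — a deterministic generalized-spiral point set on the
  5-µm-radius sphere, each vertex bonded to its k nearest neighbours
  (k = 6 by default, symmetrized).  Lamina particles are frozen except
  in deformation runs.

### Energy terms

| term | form | default |
|---|---|---|
| backbone bond | ½ k (r − r₀)² | k = 30, r₀ = 1 σ |
| lamina mesh bond | ½ k (r − r₀)², r₀ = initial edge length | k = 100 |
| excluded volume | ½ k_ev (d − r)² for r < d (bounded at r = 0) | k_ev = 20, d = 0.5 σ |
| ideal | α_ideal(s) · f(r), intra-chain, s ≥ 2, clamped at s_max | fitted; s_max = 1000 |
| compartment | α_comp(c_i, c_j) · f(r), all chromatin pairs | fitted |
| chromosome-pair | χ(I, J) · f(r), inter-chain | fitted |
| lamina / speckle / nucleolus coupling | λ_bead · f(r) per haploid bead; speckle term gated on the dP state | fitted |
| body condensation | 12-6 LJ, ε for nucleolus–nucleolus and dP–dP; repulsive branch (cut at the minimum) otherwise | ε = 3, σ_LJ = 0.5, cutoff 2.5 σ_LJ |
| confinement | half-harmonic beyond R_conf for non-lamina particles | k = 100, R_conf = mesh radius − 0.1 |
| deformation | ½ k_z z² per lamina particle (dynamic-lamina runs) | off |

f(r) = ½[1 + tanh(η(r_c − r))], shifted by its tail value and truncated
at r_c + 6/η so energies and forces are continuous; defaults
r_c = 1.75 σ, η = 3.  Negative couplings are attractive.  The same
truncated indicator defines every contact observable, so simulation and
analysis share one notion of "contact".  The Lennard-Jones branch is
linearized below 0.7 σ_LJ so overlapping initial placements have finite,
bounded forces.

The tanh/soft-core forms, the particle counts for bodies and mesh, and
the bead diameters are this package's own parameterization of the
model's interaction classes; every value above is configurable and
round-trips losslessly through the JSON parameter document.

### Dynamics

BAOAB Langevin (dt = 0.005, γ⁻¹ = 10, unit masses) for sampling;
Euler–Maruyama Brownian dynamics (γ⁻¹ = 0.01, so D = 0.01 σ²/τ per free
particle) when physical time matters.  Speckle chemistry is semi-grand
canonical MC at zero chemical-potential difference: every 4000 steps,
N_Sp attempts each pick a speckle uniformly, propose a state flip with
probability 0.2, and accept by Metropolis on the energy change.  The
paper-style flip probability is kept as the proposal rate; making
acceptance energy-aware preserves detailed balance and stabilizes dP
droplets (a flag restores unconditional flipping).  Three named RNG
streams (placement, thermostat, chemistry) derive from the run seed;
trajectories, restarts and analysis outputs are bit-reproducible.

Neighbour lists use a Verlet skin (0.5 σ) over per-category-pair
interaction ranges; the pair list is provably conservative (rebuilt
before any particle can travel half the skin), so pruning never changes
forces, only speed.

### Maximum-entropy fitting

Each coupling is dual to one ensemble average: α_ideal(s) to the mean
contact at separation s, compartment and chromosome-pair couplings to
their class means (homolog-averaged), per-bead lamina/speckle couplings
to DamID-like and TSA-Seq-like per-bead contact frequencies (the
"soft-OR" probability of touching at least one landmark particle,
1 − Π(1 − f)).  One round = simulate → extract → Adam update per block
with gradient (experimental − simulated); a contact deficit lowers the
coupling (more attractive).  Adam defaults: lr 0.02, β₁ 0.9, β₂ 0.999,
ε 10⁻⁸, per-block learning-rate overrides allowed.  Rounds warm-start
from the previous round's final configuration.  Experimental inputs
(bedGraph tracks at 25 KB, dense/sparse 100-KB matrices) are averaged
onto the model grid; replicate tracks are merged bin-wise.  Because
balanced Hi-C counts have no absolute probability scale, all
count-derived blocks are multiplied by a single factor that matches the
mean short-range (s = 2–5) intra-chromosomal contact of a reference
simulation, and the factor is reported; DamID/TSA tracks are
rank-preserving quantile-mapped onto the simulated profile scale before
mismatches are formed.

### Initial configurations and selection

Each chromosome is laid down as a random-walk coil recentred on its
centroid, shrunk into a ball sized from the mean chromatin density, at a
centre drawn uniformly by volume; bodies are uniform in the nucleus; a
brief clipped-gradient minimization under a purely repulsive body
potential removes overlaps without pre-condensing droplets.  For
production ensembles, `select_starting_configurations` picks k of N
candidates to match target lamina profiles and chromosome-pair contacts
by steepest-descent swap search from random restarts; the accepted
objective is monotonically non-increasing, which is why plain descent is
used rather than annealing.

## The toy nucleus

Desk-scale work uses a generated stand-in: 4 chains × 100 beads with
alternating A/B blocks and a central C run, 30 nucleoli, 80 speckles,
500 lamina vertices, in a sphere whose radius preserves the full model's
chromatin volume fraction (≈ 0.43) — phase behaviour is density-driven,
so density, not absolute size, is what the toy keeps.  Because the toy
nucleus is only ≈ 2.5 σ in radius, its contact indicator is scaled down
(r_c = 0.75, η = 6); the full-scale r_c = 1.75 would span the whole toy
nucleus and saturate every profile.  Synthetic optimization targets come
from simulating the toy with planted couplings (magnitudes ≤ 0.4 kT),
giving the recovery experiment a known ground truth; synthetic DamID/
TSA-like tracks are smooth anti-correlated Gaussian fields with two
noisy replicates each.  What toy-scale tests show: the machinery
(forces, sampling, extraction, optimization) is correct and the phase
behaviour is qualitatively right.  What they do not show: quantitative
agreement with real HFF sequencing data, which requires the full
46-chromosome system and experiment-derived targets.

## Standardized experiments (`nucsim.experiments`)

Problem sizes are chosen to run the whole battery on one core in well
under half an hour:

* force–gradient consistency: 20 random toy configurations with random
  couplings of every family, central differences at h = 10⁻⁵;
* Einstein relation: 100 free Brownian particles, 10⁴ steps; the MSD
  power law is fitted over the first decade of lags, where time-origin
  averaging is dense;
* equipartition: 64 harmonically bonded pairs (k = 2, r₀ = 0) at
  γ⁻¹ = 0.5 — heavier damping than the sampling default so the variance
  estimate decorrelates within the run;
* speckle chemistry: 40 speckles beyond every cutoff (ΔE = 0), 500
  sweeps — Binomial(N_Sp, 0.2) flips and stationary dP fraction ½;
* max-ent recovery: 4 × 30-bead toy, 15,000-step rounds (100 frames,
  3,000 discarded), 20 rounds;
* coarsening: the standard toy nucleus for 2 × 10⁵ steps; droplets are
  counted by single-linkage clustering at 1.5 σ_LJ including singletons,
  so the dispersed initial state is resolved;
* deformation: a pressurized-envelope variant (400-vertex mesh with
  first- and second-neighbour bonds, impermeable lamina excluded volume,
  auxiliary confinement off so the chromatin filling supports the mesh)
  compressed along z at force constants 0, 1 and 4.

## Numerical choices and edge cases

* Bonded neighbours (|s| = 1) carry no excluded volume or coupling —
  the backbone spring alone sets their distance.
* The ideal-potential separation axis is clamped at its last entry; the
  constraint extractor clamps identically so parameter and constraint
  vectors stay aligned index-by-index.
* Chromosome-pair classes with no realized bead pairs (and compartment
  classes absent from the annotation) are masked out of residuals and
  updates rather than imputed.
* Contact maps store the truncated indicator's saturation value on the
  diagonal; ensemble correlations of maps use the strict upper triangle.
* MSD fits require ≥ 5 lag points in the window; otherwise the curve is
  returned without exponents.  MSDs are time-origin averaged; pooled
  MSD is the unweighted mean over particles.
* PDB output is used while atom counts, residue ids and one-character
  chain labels fit the fixed columns; otherwise mmCIF.  Compartments,
  speckle states, the mesh recipe and seeds live in a JSON sidecar; the
  mesh is rebuilt from its recipe (deterministic), not stored.
* Equilibration discard (500,000 steps at full scale) is an
  analysis-time parameter; trajectory files always keep all frames.

## Known limitations

* Loop extrusion is approximated by the ideal potential; no explicit
  motors, no hydrodynamics, no electrostatics.
* The soft excluded volume permits occasional chain crossing; this aids
  equilibration but forbids studying entanglement dynamics.
* The frozen-lamina container is backed by an auxiliary spherical
  confinement; the particulate mesh alone is permeable at toy mesh
  densities.  Deformation runs use the denser impermeable-mesh variant.
* In-silico DamID/TSA-Seq are contact frequencies in [0, 1]; comparing
  with real tracks requires the documented quantile/z-score mapping, and
  no absolute-units calibration of sequencing signals is attempted.
* Homolog averaging assumes both copies share annotation; structural
  variants between homologs are out of scope.
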