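"""Deterministic desk-scale stand-ins for the full nucleus.

The toy nucleus shrinks the particle counts by two orders of magnitude
while preserving the chromatin volume fraction of the full-scale model,
because the phase behaviour that matters (droplet condensation,
territory compaction, lamina association) is density-driven.  Synthetic
optimization targets come from simulating the toy model itself with
planted couplings, which gives the parameterization loop a ground truth
with exactly the statistical structure of its own observables.

Everything here is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dynamics import (IntegratorSpec, Simulation, SpeckleReactionSpec,
                       minimize_energy)
from .forcefield import ContactFunction, ForceFieldParameters
from .genome_model import (BIN_SIZE, COMP_A, COMP_B, COMP_C, Configuration,
                           GenomeAnnotation, NucleusTopology,
                           build_genome_annotation, build_lamina_mesh,
                           build_topology, generate_initial_configuration)
from .io_formats import ExperimentalTrack
from .maxent import ConstraintSet, SimulationBudget, constraints_from_trajectory

# GRCh38 primary-assembly chromosome lengths (bp)
HG38_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}

CHROMATIN_BEAD_RADIUS = 0.25     # reduced units (nominal diameter 0.5)
FULL_NUCLEUS_RADIUS = 5000.0 / 385.0


def diploid_bead_count(lengths: dict[str, int] | None = None,
                       haploid_chroms=("chrX", "chrY")) -> int:
    """Total beads of the diploid genome at 100-KB binning (male)."""
    lengths = lengths or HG38_CHROM_LENGTHS
    total = 0
    for c, L in lengths.items():
        n = -(-L // BIN_SIZE)
        total += n if c in haploid_chroms else 2 * n
    return total


def chromatin_volume_fraction(n_beads: int, radius: float,
                              bead_radius: float = CHROMATIN_BEAD_RADIUS
                              ) -> float:
    return n_beads * bead_radius ** 3 / radius ** 3


def full_scale_volume_fraction() -> float:
    """Chromatin volume fraction of the full 46-chromosome nucleus."""
    return chromatin_volume_fraction(diploid_bead_count(),
                                     FULL_NUCLEUS_RADIUS)


def stylized_compartments(n_beads: int, block: int = 10,
                          centromere_fraction: float = 0.1) -> np.ndarray:
    """Alternating A/B blocks with a central pericentromeric C run."""
    labels = np.where((np.arange(n_beads) // block) % 2 == 0,
                      COMP_A, COMP_B).astype(np.int8)
    c_len = max(1, int(round(centromere_fraction * n_beads)))
    mid = n_beads // 2
    labels[mid - c_len // 2: mid - c_len // 2 + c_len] = COMP_C
    return labels


def full_genome_annotation(block: int = 50) -> GenomeAnnotation:
    """Diploid human genome annotation with stylized compartment labels.

    Labels are synthetic (alternating blocks plus a central C run), for
    exercising the full-scale layout without any external data.
    """
    track = {c: [("ABC"[int(lab)]) for lab in
                 stylized_compartments(-(-L // BIN_SIZE), block=block)]
             for c, L in HG38_CHROM_LENGTHS.items()}
    return build_genome_annotation(HG38_CHROM_LENGTHS, track, diploid=True)


# ---------------------------------------------------------------------------
# toy nucleus


@dataclass
class ToySpec:
    """Desk-scale nucleus preserving the full model's chromatin density."""

    n_chains: int = 4
    beads_per_chain: int = 100
    compartment_block: int = 10
    n_nucleolus: int = 30
    n_speckle: int = 80
    n_lamina: int = 500
    diploid_pairs: bool = False      # chains come as homolog pairs
    volume_fraction: float | None = None   # default: full-scale value
    lamina_k_neighbors: int = 6
    # contact range shrinks with the nucleus: the full-scale r_c = 1.75
    # would see the whole toy nucleus and saturate every profile
    contact_r_c: float = 0.75
    contact_eta: float = 6.0
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def radius(self) -> float:
        phi = self.volume_fraction or full_scale_volume_fraction()
        return (self.n_beads * CHROMATIN_BEAD_RADIUS ** 3 / phi) ** (1.0 / 3.0)


def make_toy_nucleus(spec: ToySpec | None = None
                     ) -> tuple[GenomeAnnotation, NucleusTopology,
                                Configuration, ForceFieldParameters]:
    """Ready-to-simulate toy system, reproducible from its seed.

    Chromatin couplings start at zero (they are what the max-ent loop
    determines); the body condensation strengths use the tuned defaults
    that produce a few nucleolus droplets and speckle clusters.
    """
    spec = spec or ToySpec()
    if spec.diploid_pairs and spec.n_chains % 2:
        raise ValueError("diploid_pairs needs an even number of chains")
    n_hap = spec.n_chains // 2 if spec.diploid_pairs else spec.n_chains
    lengths = {f"toy{h + 1}": spec.beads_per_chain * BIN_SIZE
               for h in range(n_hap)}
    labels = stylized_compartments(spec.beads_per_chain,
                                   block=spec.compartment_block)
    track = {c: [("ABC"[int(x)]) for x in labels] for c in lengths}
    ann = build_genome_annotation(
        lengths, track, diploid=spec.diploid_pairs, haploid_chroms=())
    mesh = build_lamina_mesh(spec.radius, spec.n_lamina,
                             k_neighbors=spec.lamina_k_neighbors)
    topo = build_topology(ann, spec.n_nucleolus, spec.n_speckle, mesh)
    config = generate_initial_configuration(topo, seed=spec.seed)
    params = ForceFieldParameters.zeros(
        ann, s_max=spec.beads_per_chain - 1,
        contact=ContactFunction(r_c=spec.contact_r_c, eta=spec.contact_eta))
    # relax overlaps under a purely repulsive body potential (LJ truncated
    # at its minimum) so the start stays randomly distributed
    prep = ForceFieldParameters.from_dict(params.to_dict())
    prep.lj_cutoff_factor = 2.0 ** (1.0 / 6.0)
    config = minimize_energy(topo, prep, config)
    return ann, topo, config, params


# ---------------------------------------------------------------------------
# synthetic optimization targets


def planted_toy_parameters(annotation: GenomeAnnotation,
                           s_max: int,
                           ideal_strength: float = -0.3,
                           comp_strength: float = -0.2,
                           pair_strength: float = 0.15,
                           lamina_strength: float = -0.4,
                           speckle_strength: float = -0.4,
                           contact: ContactFunction | None = None,
                           seed: int = 0) -> ForceFieldParameters:
    """A known ground-truth coupling set for recovery experiments.

    Magnitudes stay well below 1 kT: attraction of B beads to the
    lamina, of A beads to speckles, B-B and A-A compartmental cohesion,
    a decaying intra-chromosomal ideal attraction, and random
    chromosome-pair preferences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x71A]))
    contact = contact or ContactFunction(r_c=0.75, eta=6.0)
    p = ForceFieldParameters.zeros(annotation, s_max=s_max, contact=contact)
    s = np.arange(s_max + 1)
    p.alpha_ideal = ideal_strength * np.exp(-s / 10.0)
    p.alpha_ideal[:2] = 0.0
    comp = np.zeros((3, 3))
    comp[COMP_A, COMP_A] = comp_strength
    comp[COMP_B, COMP_B] = comp_strength
    comp[COMP_C, COMP_C] = comp_strength
    comp[COMP_A, COMP_B] = comp[COMP_B, COMP_A] = -comp_strength * 0.5
    p.alpha_comp = comp
    n_hap = annotation.n_haploid
    chi = rng.uniform(-pair_strength, pair_strength, size=(n_hap, n_hap))
    chi = 0.5 * (chi + chi.T)
    np.fill_diagonal(chi, 0.0)
    p.chrom_pair = chi
    hap_comp = annotation.haploid_compartments()
    p.lamina_coupling = np.where(hap_comp == COMP_B, lamina_strength, 0.0)
    p.speckle_coupling = np.where(hap_comp == COMP_A, speckle_strength, 0.0)
    return p


def make_synthetic_targets(planted: ForceFieldParameters,
                           spec: ToySpec,
                           budget: SimulationBudget | None = None,
                           seed: int = 0,
                           integrator: IntegratorSpec | None = None,
                           reactions: SpeckleReactionSpec | None = None
                           ) -> ConstraintSet:
    """Self-consistent optimization targets from a planted simulation."""
    ann, topo, config, _ = make_toy_nucleus(spec)
    budget = budget or SimulationBudget()
    sim = Simulation(topo, planted, config, integrator=integrator,
                     reactions=reactions, seed=seed)
    traj = sim.run(budget.n_steps, record_interval=budget.record_interval)
    return constraints_from_trajectory(
        traj, topo, planted.contact, discard_steps=budget.discard_steps,
        s_max=len(planted.alpha_ideal) - 1)


# ---------------------------------------------------------------------------
# synthetic experimental tracks


def make_track_fixtures(seed: int = 0, n_bins: int = 400,
                        resolution: int = 25_000, chrom: str = "toy1",
                        smooth_bins: float = 8.0, noise: float = 0.3
                        ) -> dict[str, list[ExperimentalTrack]]:
    """Smooth anti-correlated DamID-like / TSA-like tracks, 2 replicates.

    A smoothed Gaussian field sets the shared spatial structure; the
    DamID-like signal follows it and the TSA-like signal its negative
    (peripheral heterochromatin sits far from speckles), each observed
    through two independently noisy replicates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7AC5]))
    base = gaussian_filter1d(rng.standard_normal(n_bins), smooth_bins)
    base = base / np.std(base)
    starts = np.arange(n_bins) * resolution

    def track(values, tag):
        df = pd.DataFrame({"chrom": chrom, "start": starts,
                           "end": starts + resolution, "value": values})
        return ExperimentalTrack(df, resolution, provenance=tag)

    out: dict[str, list[ExperimentalTrack]] = {"damid": [], "tsaseq": []}
    for rep in range(2):
        eps = gaussian_filter1d(rng.standard_normal(n_bins), 2.0)
        eps = noise * eps / np.std(eps)
        out["damid"].append(track(base + eps, f"synthetic-damid-rep{rep + 1}"))
    for rep in range(2):
        eps = gaussian_filter1d(rng.standard_normal(n_bins), 2.0)
        eps = noise * eps / np.std(eps)
        out["tsaseq"].append(track(-base + eps,
                                   f"synthetic-tsaseq-rep{rep + 1}"))
    return out
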