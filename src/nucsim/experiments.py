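"""Standardized desk-scale validation experiments.

Each function sets up a small, fully specified system, runs the
relevant piece of the machinery, and returns summary statistics.  They
back both the test suite and the reproduction script, so the protocol
(system sizes, step counts, windows) is defined once, here.

Problem sizes are chosen so the whole battery runs on one CPU core in
well under half an hour: free-particle physics uses O(100) particles for
10^4-10^5 steps, the parameter-recovery experiment a 120-bead nucleus
with 15,000-step optimization rounds, and the condensation and
deformation experiments the standard 1,010-particle toy nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import cluster_droplets, compute_msd
from .dynamics import (DeformationSpec, IntegratorSpec, Simulation,
                       SpeckleReactionSpec, speckle_reaction_sweep)
from .forcefield import ContactFunction, ForceField, ForceFieldParameters
from .fixtures import ToySpec, make_toy_nucleus, make_synthetic_targets, \
    planted_toy_parameters
from .genome_model import (BIN_SIZE, LAMINA, NUCLEOLUS, Configuration,
                           DEFAULT_UNITS, build_genome_annotation,
                           build_topology)
from .maxent import SimulationBudget, optimize_parameters

MAXENT_SPEC = ToySpec(n_chains=4, beads_per_chain=30, compartment_block=5,
                      n_nucleolus=8, n_speckle=16, n_lamina=100, seed=11)
MAXENT_BUDGET = SimulationBudget(n_steps=15_000, record_interval=150,
                                 discard_steps=3_000)


def _free_particles(n: int) -> tuple:
    track = {f"c{i}": ["A"] for i in range(n)}
    ann = build_genome_annotation(
        {f"c{i}": BIN_SIZE for i in range(n)}, track, diploid=False)
    topo = build_topology(ann)
    p = ForceFieldParameters.zeros(ann, s_max=1)
    p.excluded_volume_k = 0.0
    return topo, p


def force_gradient_check(seed: int = 0, n_configs: int = 20,
                         n_checked_particles: int = 12,
                         h: float = 1e-5) -> float:
    """Largest relative mismatch between forces and -dE/dx.

    Random toy configurations with random couplings of every family;
    central differences per Cartesian component.
    """
    spec = ToySpec(n_chains=2, beads_per_chain=12, compartment_block=3,
                   n_nucleolus=4, n_speckle=6, n_lamina=30, seed=1)
    ann, topo, _, _ = make_toy_nucleus(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFD]))
    worst = 0.0
    for _ in range(n_configs):
        p = ForceFieldParameters.zeros(
            ann, s_max=11, contact=ContactFunction(r_c=0.75, eta=6.0))
        p.alpha_ideal = rng.uniform(-0.5, 0.2, p.alpha_ideal.shape)
        p.alpha_ideal[:2] = 0.0
        a = rng.uniform(-0.4, 0.4, (3, 3))
        p.alpha_comp = 0.5 * (a + a.T)
        c = rng.uniform(-0.3, 0.3, p.chrom_pair.shape)
        p.chrom_pair = 0.5 * (c + c.T)
        p.lamina_coupling = rng.uniform(-0.6, 0.1, p.lamina_coupling.shape)
        p.speckle_coupling = rng.uniform(-0.6, 0.1, p.speckle_coupling.shape)
        p.nucleolus_coupling = rng.uniform(-0.6, 0.1,
                                           p.nucleolus_coupling.shape)
        pos = rng.uniform(-1.2, 1.2, (topo.n_particles, 3))
        states = rng.integers(0, 2, topo.n_speckle).astype(np.int8)
        ff = ForceField(topo, p)
        _, forces = ff.energy_forces(pos, states)
        for i in rng.choice(topo.n_particles, n_checked_particles,
                            replace=False):
            for d in range(3):
                pos[i, d] += h
                ep, _ = ff.energy_forces(pos, states)
                pos[i, d] -= 2 * h
                em, _ = ff.energy_forces(pos, states)
                pos[i, d] += h
                fd = -(ep - em) / (2 * h)
                denom = max(abs(fd), 1e-2)
                worst = max(worst, abs(forces[i, d] - fd) / denom)
    return worst


@dataclass
class DiffusionResult:
    alpha: float
    diffusion_constant: float            # um^2/s from the fit
    diffusion_expected: float
    relative_error: float


def brownian_free_diffusion(seed: int = 0, n_replicas: int = 100,
                            n_steps: int = 10_000) -> DiffusionResult:
    """Free Brownian particles must obey the Einstein relation.

    With damping gamma^-1 = 0.01 and T = 1 the input diffusion
    coefficient is D = 0.01 sigma^2/tau; the MSD fit must recover
    alpha = 1 and D.
    """
    topo, p = _free_particles(n_replicas)
    cfg = Configuration(np.zeros((n_replicas, 3)),
                        np.zeros(0, dtype=np.int8))
    sim = Simulation(topo, p, cfg,
                     integrator=IntegratorSpec(scheme="brownian"),
                     reactions=SpeckleReactionSpec(enabled=False),
                     seed=seed)
    traj = sim.run(n_steps, record_interval=n_steps // 100)
    # fit the first decade of lags, where time-origin averaging is dense
    lag1 = (n_steps // 100) * sim.integrator.dt * DEFAULT_UNITS.tau_s
    res = compute_msd(traj, np.arange(n_replicas),
                      fit_window=(0.5 * lag1, 10.4 * lag1))
    d_fit = res.d_alpha / 6.0
    d_expect = 0.01 * DEFAULT_UNITS.length_to_um(1.0) ** 2 \
        / DEFAULT_UNITS.tau_s
    return DiffusionResult(alpha=res.alpha, diffusion_constant=d_fit,
                           diffusion_expected=d_expect,
                           relative_error=abs(d_fit - d_expect) / d_expect)


def langevin_equipartition(seed: int = 0, n_pairs: int = 64,
                           bond_k: float = 2.0, burn_in: int = 20_000,
                           n_samples: int = 400,
                           sample_interval: int = 50) -> float:
    """Positional variance of harmonically bound pairs over T/k.

    Pairs bonded with rest length zero: each Cartesian component of the
    bond vector is harmonic with stiffness ``bond_k``, so its stationary
    variance must equal T/k.  Returns the measured/expected ratio.
    """
    track = {f"c{i}": ["A", "A"] for i in range(n_pairs)}
    ann = build_genome_annotation(
        {f"c{i}": 2 * BIN_SIZE for i in range(n_pairs)}, track,
        diploid=False)
    topo = build_topology(ann)
    p = ForceFieldParameters.zeros(ann, s_max=1)
    p.excluded_volume_k = 0.0
    p.bond_k = bond_k
    p.bond_r0 = 0.0
    pos = np.zeros((2 * n_pairs, 3))
    pos[:, 0] = np.repeat(np.arange(n_pairs) * 50.0, 2)
    cfg = Configuration(pos, np.zeros(0, dtype=np.int8))
    sim = Simulation(topo, p, cfg,
                     integrator=IntegratorSpec(scheme="langevin",
                                               gamma_inv=0.5),
                     reactions=SpeckleReactionSpec(enabled=False),
                     seed=seed)
    sim.step(burn_in)
    acc = []
    for _ in range(n_samples):
        sim.step(sample_interval)
        acc.append((sim.positions[0::2] - sim.positions[1::2]).copy())
    var = float(np.mean(np.concatenate(acc) ** 2))
    return var / (sim.integrator.temperature / bond_k)


@dataclass
class SpeckleChemistryResult:
    mean_flips_per_sweep: float
    expected_flips: float
    binomial_se: float
    dp_fraction: float


def speckle_chemistry_stats(seed: int = 0, n_speckle: int = 40,
                            n_sweeps: int = 500) -> SpeckleChemistryResult:
    """Flip statistics of the semi-grand MC at zero couplings.

    Speckles far beyond every cutoff: all proposals are energy-neutral,
    so flips per sweep are Binomial(N_Sp, 0.2) and the stationary dP
    fraction is 1/2.
    """
    track = {"c": ["A"]}
    ann = build_genome_annotation({"c": BIN_SIZE}, track, diploid=False)
    topo = build_topology(ann, 0, n_speckle)
    p = ForceFieldParameters.zeros(ann, s_max=1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C]))
    pos = np.vstack([[0.0, 0.0, 0.0],
                     rng.uniform(-1, 1, (n_speckle, 3)) * 1e4])
    cfg = Configuration(pos, np.zeros(n_speckle, dtype=np.int8))
    ff = ForceField(topo, p)
    spec = SpeckleReactionSpec()
    flips, fractions = [], []
    for _ in range(n_sweeps):
        cfg, k = speckle_reaction_sweep(cfg, spec, ff, rng)
        flips.append(k)
        fractions.append(float(np.mean(cfg.speckle_states)))
    burn = n_sweeps // 5
    return SpeckleChemistryResult(
        mean_flips_per_sweep=float(np.mean(flips)),
        expected_flips=spec.probability * n_speckle,
        binomial_se=float(np.sqrt(
            n_speckle * spec.probability * (1 - spec.probability)
            / n_sweeps)),
        dp_fraction=float(np.mean(fractions[burn:])))


@dataclass
class RecoveryResult:
    pearson_by_block: dict[str, float]      # at the best iterate
    worst_block_pearson: float
    residual_reduction: float               # 1 - best/first
    iterations: int


def maxent_recovery(seed: int = 0, n_iterations: int = 20) -> RecoveryResult:
    """Recover planted couplings from a zero start on the toy nucleus.

    Targets are generated by simulating the toy model with known
    couplings; the optimization loop must drive the simulated constraint
    averages back onto those targets.
    """
    ann, topo, config, params = make_toy_nucleus(MAXENT_SPEC)
    planted = planted_toy_parameters(ann, s_max=29, contact=params.contact,
                                     seed=7)
    target = make_synthetic_targets(planted, MAXENT_SPEC,
                                    budget=MAXENT_BUDGET, seed=seed + 1)
    _, history, _ = optimize_parameters(
        topo, config, target, n_iterations=n_iterations,
        budget=MAXENT_BUDGET, params=params, seed=seed + 2)
    best = min(history, key=lambda h: h.total_residual)
    pear = {k: v for k, v in best.pearson.items() if np.isfinite(v)}
    return RecoveryResult(
        pearson_by_block=pear,
        worst_block_pearson=float(min(pear.values())),
        residual_reduction=1.0 - best.total_residual
        / history[0].total_residual,
        iterations=len(history))


@dataclass
class CoarseningResult:
    initial_clusters: int
    final_clusters: int
    cutoff_sweep_counts: list[int]          # final config, growing cutoff


def nucleolus_coarsening(seed: int = 0, n_steps: int = 200_000,
                         cutoff: float = 0.75) -> CoarseningResult:
    """Condensation of nucleolar particles in the standard toy nucleus.

    Starts from randomly distributed bodies and runs with the tuned
    Lennard-Jones strength; the droplet count must collapse from many
    initial fragments to a few nucleoli.  Cluster counts include
    singletons (min_size=1) so the initial dispersed state is resolved.
    """
    spec = ToySpec(seed=seed)
    _, topo, config, params = make_toy_nucleus(spec)
    initial = cluster_droplets(config, topo, NUCLEOLUS, cutoff=cutoff,
                               min_size=1).n_clusters
    sim = Simulation(topo, params, config, seed=seed + 1)
    sim.step(n_steps)
    final_cfg = sim.configuration
    final = cluster_droplets(final_cfg, topo, NUCLEOLUS, cutoff=cutoff,
                             min_size=1).n_clusters
    sweep = [cluster_droplets(final_cfg, topo, NUCLEOLUS, cutoff=c,
                              min_size=1).n_clusters
             for c in np.linspace(0.3, 2.0, 8)]
    return CoarseningResult(initial_clusters=initial, final_clusters=final,
                            cutoff_sweep_counts=sweep)


@dataclass
class DeformationResult:
    aspect_by_force: dict[float, float]     # z/xy extent of the lamina
    sphericity_zero_force: float            # max/min principal semi-axis
    max_edge_stretch: float


def deformation_response(seed: int = 0,
                         forces: tuple = (0.0, 1.0, 4.0),
                         n_steps: int = 15_000) -> DeformationResult:
    """Compress a dynamic lamina mesh along z at increasing force.

    The envelope is simulated as a pressurized particle shell: dense
    mesh with first- and second-neighbour bonds, impermeable excluded
    volume, and the chromatin filling providing internal pressure (the
    auxiliary spherical confinement is off so the mesh itself is the
    container).
    """
    aspect = {}
    sphericity = None
    max_stretch = 0.0
    for kdef in forces:
        spec = ToySpec(n_chains=2, beads_per_chain=30, n_nucleolus=6,
                       n_speckle=10, n_lamina=400, lamina_k_neighbors=12,
                       seed=4)
        _, topo, config, params = make_toy_nucleus(spec)
        params.confinement_k = 0.0
        params.excluded_volume_k = 40.0
        params.lamina_bond_k = 300.0
        params.diameters = np.array([0.5, 0.5, 0.5, 0.7])
        sim = Simulation(topo, params, config,
                         deformation=DeformationSpec(force_k=kdef),
                         reactions=SpeckleReactionSpec(enabled=False),
                         seed=seed + 10)
        sim.step(n_steps)
        lam = topo.indices(LAMINA)
        p = sim.positions[lam] - sim.positions[lam].mean(axis=0)
        z_ext = np.sqrt(np.mean(p[:, 2] ** 2))
        xy_ext = np.sqrt(np.mean(p[:, 0] ** 2 + p[:, 1] ** 2) / 2.0)
        aspect[kdef] = float(z_ext / xy_ext)
        mesh = topo.lamina_mesh
        d = np.linalg.norm(sim.positions[lam][mesh.edges[:, 0]]
                           - sim.positions[lam][mesh.edges[:, 1]], axis=1)
        max_stretch = max(max_stretch,
                          float(np.max(d / mesh.edge_rest_lengths)))
        if kdef == 0.0:
            cov = p.T @ p / len(p)
            ax = np.sqrt(np.sort(np.linalg.eigvalsh(cov)))
            sphericity = float(ax[2] / ax[0])
    return DeformationResult(aspect_by_force=aspect,
                             sphericity_zero_force=sphericity,
                             max_edge_stretch=max_stretch)
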