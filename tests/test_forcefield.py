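import numpy as np
import pytest

from nucsim.dynamics import IntegratorSpec, Simulation, SpeckleReactionSpec
from nucsim.forcefield import (ContactFunction, ForceField,
                               ForceFieldParameters, body_pair_energy,
                               chromatin_pair_energy, contact_indicator,
                               landmark_coupling_energy, total_energy_forces)
from nucsim.genome_model import (BIN_SIZE, NUCLEOLUS, SPECKLE, STATE_DP,
                                 STATE_P, Configuration,
                                 build_genome_annotation, build_topology)

from oracles import naive_total_energy


def random_params(ann, rng, contact=None):
    p = ForceFieldParameters.zeros(
        ann, s_max=int(ann.beads_per_chain.max()) - 1,
        contact=contact or ContactFunction(r_c=0.75, eta=6.0))
    p.alpha_ideal = rng.uniform(-0.5, 0.2, p.alpha_ideal.shape)
    p.alpha_ideal[:2] = 0.0
    a = rng.uniform(-0.4, 0.4, (3, 3))
    p.alpha_comp = 0.5 * (a + a.T)
    c = rng.uniform(-0.3, 0.3, p.chrom_pair.shape)
    p.chrom_pair = 0.5 * (c + c.T)
    p.lamina_coupling = rng.uniform(-0.6, 0.1, p.lamina_coupling.shape)
    p.speckle_coupling = rng.uniform(-0.6, 0.1, p.speckle_coupling.shape)
    p.nucleolus_coupling = rng.uniform(-0.6, 0.1, p.nucleolus_coupling.shape)
    return p


def random_configuration(topo, rng, radius=2.0):
    n = topo.n_particles
    pos = rng.uniform(-radius, radius, (n, 3))
    states = rng.integers(0, 2, topo.n_speckle).astype(np.int8)
    return Configuration(pos, states)


class TestContactFunction:
    def test_midpoint_is_half(self):
        c = ContactFunction()
        assert contact_indicator(c.r_c, c) == pytest.approx(0.5, abs=1e-12)

    def test_saturates_near_zero_distance(self):
        c = ContactFunction(r_c=1.75, eta=3.0)
        assert c.value(0.0) > 0.99

    def test_monotone_nonincreasing_and_bounded(self):
        c = ContactFunction()
        r = np.linspace(0, 5, 200)
        v = c.value(r)
        assert np.all(np.diff(v) <= 0)
        assert np.all((v > 0) & (v < 1))

    def test_derivative_matches_finite_differences(self, rng):
        c = ContactFunction(r_c=1.3, eta=4.0)
        r = rng.uniform(0.05, 3.0, 50)
        h = 1e-6
        fd = (c.value(r + h) - c.value(r - h)) / (2 * h)
        assert np.allclose(c.derivative(r), fd, rtol=1e-6, atol=1e-12)

    def test_truncated_is_zero_beyond_cutoff_and_continuous(self):
        c = ContactFunction(r_c=0.75, eta=6.0)
        eps = 1e-9
        assert c.truncated(c.cutoff + 1.0) == 0.0
        assert c.truncated(c.cutoff - eps) < 1e-8   # no jump at the cutoff


class TestPairEnergies:
    def test_zero_couplings_give_zero_energy(self, small_toy):
        ann, _, _, params = small_toy
        for r in (0.3, 1.0, 2.0):
            assert chromatin_pair_energy(r, params, separation=5) == 0.0
            assert chromatin_pair_energy(r, params) == 0.0

    def test_intrachain_midpoint_value(self, small_toy):
        ann, _, _, _ = small_toy
        p = ForceFieldParameters.zeros(ann, s_max=19)
        p.alpha_ideal[5] = -1.0
        e = chromatin_pair_energy(p.contact.r_c, p, separation=5)
        assert e == pytest.approx(-0.5, abs=1e-4)

    def test_separation_beyond_table_clamps_to_last(self, small_toy):
        ann, _, _, _ = small_toy
        p = ForceFieldParameters.zeros(ann, s_max=19)
        p.alpha_ideal[-1] = -0.8
        e_edge = chromatin_pair_energy(1.0, p, separation=19)
        e_beyond = chromatin_pair_energy(1.0, p, separation=500)
        assert e_edge == e_beyond != 0.0

    def test_lj_minimum_depth(self):
        p = ForceFieldParameters(lj_eps_speckle=2.0)
        r_min = 2 ** (1 / 6) * p.lj_sigma
        e = body_pair_energy(r_min, p, SPECKLE, SPECKLE,
                             STATE_DP, STATE_DP)
        # truncated-shifted LJ: minimum sits at -(eps + tail shift)
        x6 = (p.lj_sigma / p.lj_cutoff) ** 6
        shift = 4 * 2.0 * (x6 * x6 - x6)
        assert e == pytest.approx(-2.0 - shift, rel=1e-12)
        assert e == pytest.approx(-2.0, rel=0.02)

    def test_p_state_pair_repulsive_branch_zero_at_minimum(self):
        p = ForceFieldParameters()
        r_min = 2 ** (1 / 6) * p.lj_sigma
        assert body_pair_energy(r_min, p, SPECKLE, SPECKLE,
                                STATE_P, STATE_DP) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_zero_beyond_cutoff(self):
        p = ForceFieldParameters()
        assert body_pair_energy(p.lj_cutoff, p, NUCLEOLUS, NUCLEOLUS) == 0.0
        assert body_pair_energy(p.lj_cutoff + 1, p, NUCLEOLUS,
                                NUCLEOLUS) == 0.0

    def test_landmark_coupling_values(self):
        c = ContactFunction()
        assert landmark_coupling_energy(0.7, 0.0, c) == 0.0
        assert landmark_coupling_energy(c.r_c, -2.0, c) == \
            pytest.approx(-1.0, abs=1e-4)
        assert landmark_coupling_energy(c.r_c, -2.0, c,
                                        dp_state=STATE_P) == 0.0


class TestTotalEnergyForces:
    def test_bonded_pair_at_rest_length(self):
        ann = build_genome_annotation({"c": 2 * BIN_SIZE}, {"c": ["A", "A"]},
                                      diploid=False)
        topo = build_topology(ann)
        p = ForceFieldParameters.zeros(ann, s_max=1)
        p.excluded_volume_k = 0.0
        cfg = Configuration(np.array([[0., 0., 0.], [1., 0., 0.]]),
                            np.zeros(0, dtype=np.int8))
        e, f = total_energy_forces(cfg, topo, p)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_matches_naive_reimplementation(self, small_toy, rng):
        ann, topo, _, _ = small_toy
        params = random_params(ann, rng)
        cfg = random_configuration(topo, rng)
        e, f, comps = total_energy_forces(cfg, topo, params,
                                          return_components=True)
        naive = naive_total_energy(cfg.positions, topo, params,
                                   cfg.speckle_states)
        for term, val in naive.items():
            assert comps[term] == pytest.approx(val, abs=1e-9), term
        assert e == pytest.approx(sum(naive.values()), abs=1e-8)

    def test_decomposition_sums_to_total(self, small_toy, rng):
        ann, topo, _, _ = small_toy
        params = random_params(ann, rng)
        cfg = random_configuration(topo, rng)
        e, _, comps = total_energy_forces(cfg, topo, params,
                                          return_components=True)
        assert e == pytest.approx(sum(comps.values()),
                                  rel=1e-10, abs=1e-12)

    def test_forces_match_central_differences(self, small_toy, rng):
        ann, topo, _, _ = small_toy
        params = random_params(ann, rng)
        cfg = random_configuration(topo, rng, radius=1.2)
        ff = ForceField(topo, params)
        _, forces = ff.energy_forces(cfg.positions, cfg.speckle_states)
        h = 1e-5
        pos = cfg.positions
        check = rng.choice(topo.n_particles, size=12, replace=False)
        for i in check:
            for d in range(3):
                pos[i, d] += h
                ep, _ = ff.energy_forces(pos, cfg.speckle_states)
                pos[i, d] -= 2 * h
                em, _ = ff.energy_forces(pos, cfg.speckle_states)
                pos[i, d] += h
                fd = -(ep - em) / (2 * h)
                assert forces[i, d] == pytest.approx(
                    fd, rel=1e-4, abs=2e-4)

    def test_translation_invariance(self, small_toy, rng):
        ann, topo, _, _ = small_toy
        params = random_params(ann, rng)
        params.confinement_k = 0.0      # confinement pins the centre
        cfg = random_configuration(topo, rng)
        e1, f1 = total_energy_forces(cfg, topo, params)
        cfg2 = cfg.copy()
        cfg2.positions = cfg.positions + np.array([1.7, -2.2, 0.4])
        e2, f2 = total_energy_forces(cfg2, topo, params)
        assert e2 == pytest.approx(e1, rel=1e-10)
        assert np.allclose(f1, f2, atol=1e-8)
        assert np.linalg.norm(f1.sum(axis=0)) < 1e-8   # Newton's third law

    def test_overlapping_particles_finite(self, small_toy):
        ann, topo, _, params = small_toy
        cfg = Configuration(np.zeros((topo.n_particles, 3)),
                            np.ones(topo.n_speckle, dtype=np.int8))
        e, f = total_energy_forces(cfg, topo, params)
        assert np.isfinite(e)
        assert np.all(np.isfinite(f))

    def test_energy_continuous_across_lj_cutoff(self):
        p = ForceFieldParameters(lj_eps_nucleolus=3.0)
        eps = 1e-7
        below = body_pair_energy(p.lj_cutoff - eps, p, NUCLEOLUS, NUCLEOLUS)
        assert abs(below) < 1e-5


class TestParameterSerialization:
    def test_json_roundtrip_lossless(self, small_toy, rng, tmp_path):
        ann, _, _, _ = small_toy
        p = random_params(ann, rng)
        path = tmp_path / "params.json"
        p.save(path)
        q = ForceFieldParameters.load(path)
        for attr in ("alpha_ideal", "alpha_comp", "chrom_pair",
                     "lamina_coupling", "speckle_coupling",
                     "nucleolus_coupling", "diameters"):
            assert np.array_equal(getattr(p, attr), getattr(q, attr)), attr
        assert q.contact == p.contact
        assert q.lj_eps_nucleolus == p.lj_eps_nucleolus

    def test_asymmetric_matrix_rejected(self, small_toy):
        ann, _, _, _ = small_toy
        bad = np.zeros((3, 3))
        bad[0, 1] = 1.0
        with pytest.raises(ValueError):
            ForceFieldParameters(alpha_comp=bad)


def free_chain_ensemble(n_chains, n_beads, seed):
    """Independent bond-only chains, each starting from a random coil."""
    rng = np.random.default_rng(seed)
    track = {f"c{i}": ["A"] * n_beads for i in range(n_chains)}
    ann = build_genome_annotation(
        {f"c{i}": n_beads * BIN_SIZE for i in range(n_chains)}, track,
        diploid=False)
    topo = build_topology(ann)
    p = ForceFieldParameters.zeros(ann, s_max=n_beads - 1)
    p.excluded_volume_k = 0.0
    pos = []
    for m in range(n_chains):
        steps = rng.standard_normal((n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        pos.append(walk + np.array([m * 200.0, 0.0, 0.0]))
    cfg = Configuration(np.vstack(pos), np.zeros(0, dtype=np.int8))
    return ann, topo, p, cfg


class TestIdealChainLimit:
    def test_internal_distances_follow_random_walk_scaling(self):
        # bonds only, free space: <R^2(s)> should grow linearly with s
        M, n = 16, 60
        ann, topo, p, cfg = free_chain_ensemble(M, n, seed=8)
        sim = Simulation(topo, p, cfg,
                         integrator=IntegratorSpec(gamma_inv=1.0),
                         reactions=SpeckleReactionSpec(enabled=False),
                         seed=8)
        traj = sim.run(40_000, record_interval=400)
        pos = traj.positions[25:]
        seps = np.array([2, 4, 8, 16, 32])
        msd_s = []
        for s in seps:
            acc = []
            for m in range(M):
                ch = pos[:, m * n:(m + 1) * n, :]
                d = ch[:, s:, :] - ch[:, :-s, :]
                acc.append(np.mean(np.sum(d * d, axis=2)))
            msd_s.append(np.mean(acc))
        slope = np.polyfit(np.log(seps), np.log(msd_s), 1)[0]
        assert 0.8 < slope < 1.2
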