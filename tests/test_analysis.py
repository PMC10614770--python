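import numpy as np
import pytest

from nucsim.analysis import (chromosome_geometry, cluster_droplets,
                             compute_contact_map, compute_msd,
                             contact_scaling, ensemble_correlations,
                             homolog_average_map, insilico_profile,
                             ContactMap, LinearProfile)
from nucsim.dynamics import (IntegratorSpec, Simulation, SpeckleReactionSpec,
                             Trajectory)
from nucsim.forcefield import ContactFunction, ForceFieldParameters
from nucsim.genome_model import (BIN_SIZE, LAMINA, NUCLEOLUS, Configuration,
                                 build_genome_annotation, build_topology,
                                 DEFAULT_UNITS)

from oracles import (naive_clusters, naive_contact_map, naive_pearson_matrix,
                     naive_profile)


def make_traj(topo, frames, states=None, step_gap=100):
    F = len(frames)
    n_sp = topo.n_speckle
    if states is None:
        states = [np.zeros(n_sp)] * F
    return Trajectory(np.stack(frames),
                      np.stack(states).astype(np.int8),
                      np.arange(F) * step_gap, dt=0.005)


class TestContactMap:
    def test_symmetric_and_matches_oracle(self, small_toy, rng):
        ann, topo, _, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(3)]
        traj = make_traj(topo, frames)
        cmap = compute_contact_map(traj, topo, params.contact)
        assert np.array_equal(cmap.matrix, cmap.matrix.T)
        ref = naive_contact_map([f[:ann.n_beads] for f in frames],
                                ann.n_beads, params.contact)
        assert np.allclose(cmap.matrix, ref, atol=1e-12)

    def test_straight_chain_monotone_decay(self):
        n = 10
        ann = build_genome_annotation({"c": n * BIN_SIZE},
                                      {"c": ["A"] * n}, diploid=False)
        topo = build_topology(ann)
        contact = ContactFunction(r_c=1.75, eta=3.0)
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n)
        traj = make_traj(topo, [pos])
        cmap = compute_contact_map(traj, topo, contact)
        row = cmap.matrix[0]
        assert np.all(np.diff(row) <= 0)        # flat only beyond support
        assert np.all(np.diff(row[:4]) < 0)
        assert row[1] == pytest.approx(float(contact.truncated(1.0)),
                                       abs=1e-12)

    def test_homolog_average_idempotent_and_commutes(self, diploid_toy, rng):
        ann, topo, _, params = diploid_toy
        frames = [rng.uniform(-1.5, 1.5, (topo.n_particles, 3))
                  for _ in range(2)]
        traj = make_traj(topo, frames)
        collapsed = compute_contact_map(traj, topo, params.contact,
                                        homolog_average=True)
        diploid = compute_contact_map(traj, topo, params.contact)
        after = homolog_average_map(diploid, topo)
        assert np.allclose(collapsed.matrix, after.matrix, atol=1e-12)
        again = homolog_average_map(after, topo)
        assert np.allclose(again.matrix, after.matrix, atol=1e-15)


class TestContactScaling:
    def test_constant_matrix_gives_flat_curve(self, small_toy):
        ann, topo, _, _ = small_toy
        cmap = ContactMap(np.full((ann.n_beads, ann.n_beads), 0.3),
                          haploid=False, n_frames=1)
        df = contact_scaling(cmap, topo)
        assert np.allclose(df["mean_contact"], 0.3, atol=1e-15)

    def test_matches_bruteforce_recomputation(self, small_toy, rng):
        ann, topo, _, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))]
        traj = make_traj(topo, frames)
        cmap = compute_contact_map(traj, topo, params.contact)
        df = contact_scaling(cmap, topo)
        chain = ann.chain_of_bead
        wci = ann.within_chain_index
        for _, row in df.iterrows():
            s = int(row["separation"])
            vals = [cmap.matrix[i, j]
                    for i in range(ann.n_beads)
                    for j in range(i + 1, ann.n_beads)
                    if chain[i] == chain[j] and abs(wci[i] - wci[j]) == s]
            assert row["mean_contact"] == pytest.approx(np.mean(vals),
                                                        abs=1e-12)

    def test_ideal_chain_scaling_exponent(self):
        # bonds only in free space: contact decay ~ s^-3/2 (return
        # probability of a random walk); ensemble of independent chains
        from test_forcefield import free_chain_ensemble
        ann, topo, p, cfg = free_chain_ensemble(32, 60, seed=12)
        p.contact = ContactFunction(r_c=0.6, eta=6.0)
        sim = Simulation(topo, p, cfg,
                         integrator=IntegratorSpec(gamma_inv=1.0),
                         reactions=SpeckleReactionSpec(enabled=False),
                         seed=12)
        traj = sim.run(60_000, record_interval=400)
        cmap = compute_contact_map(traj, topo, p.contact,
                                   discard_steps=10_000)
        df = contact_scaling(cmap, topo)
        sel = (df["separation"] >= 4) & (df["separation"] <= 24)
        slope = np.polyfit(np.log(df["separation"][sel]),
                           np.log(df["mean_contact"][sel]), 1)[0]
        assert -1.7 < slope < -1.3


class TestProfiles:
    def test_lamina_adjacent_bead_high_center_bead_low(self):
        ann = build_genome_annotation({"c": 2 * BIN_SIZE},
                                      {"c": ["A", "A"]}, diploid=False)
        from nucsim.genome_model import build_lamina_mesh
        mesh = build_lamina_mesh(5.0, 50)
        topo = build_topology(ann, 0, 0, mesh)
        contact = ContactFunction(r_c=0.75, eta=6.0)
        pos = np.zeros((topo.n_particles, 3))
        pos[0] = mesh.vertices[0] * 0.99        # glued to the envelope
        pos[1] = 0.0                            # nuclear centre
        pos[2:] = mesh.vertices
        traj = make_traj(topo, [pos])
        prof = insilico_profile(traj, topo, "damid", contact)
        assert prof.values[0] > 0.9
        assert prof.values[1] < 1e-6

    def test_all_p_speckles_give_zero_tsaseq(self, small_toy, rng):
        _, topo, _, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))]
        traj = make_traj(topo, frames,
                         [np.zeros(topo.n_speckle)])
        prof = insilico_profile(traj, topo, "tsaseq", params.contact)
        assert np.all(prof.values == 0.0)

    def test_matches_bruteforce_oracle(self, small_toy, rng):
        ann, topo, _, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(2)]
        states = [rng.integers(0, 2, topo.n_speckle) for _ in range(2)]
        traj = make_traj(topo, frames, states)
        prof = insilico_profile(traj, topo, "tsaseq", params.contact)
        spk = topo.indices(2)
        ref = naive_profile(frames, [spk[states[f] == 1] for f in range(2)],
                            ann.n_beads, params.contact)
        assert np.allclose(prof.values, ref, atol=1e-12)

    def test_missing_landmarks_rejected(self, rng):
        ann = build_genome_annotation({"c": 2 * BIN_SIZE},
                                      {"c": ["A", "A"]}, diploid=False)
        topo = build_topology(ann)
        traj = make_traj(topo, [np.zeros((2, 3))])
        with pytest.raises(ValueError):
            insilico_profile(traj, topo, "damid")
        with pytest.raises(ValueError):
            insilico_profile(traj, topo, "ctcf")

    def test_zscore_normalization(self, small_toy, rng):
        _, topo, _, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))]
        states = [np.ones(topo.n_speckle)]
        traj = make_traj(topo, frames, states)
        z = insilico_profile(traj, topo, "damid", params.contact).zscored()
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std() == pytest.approx(1.0, abs=1e-12)


class TestMSD:
    def test_immobile_particle_zero_msd_fit_rejected(self, small_toy):
        _, topo, cfg, _ = small_toy
        frames = [cfg.positions.copy() for _ in range(10)]
        traj = make_traj(topo, frames)
        res = compute_msd(traj, [0, 1], fit_window=(1e-3, 1e9))
        assert np.all(res.msd_um2 == 0.0)
        assert res.alpha is None            # no positive MSD to fit

    def test_translation_invariance(self, small_toy, rng):
        _, topo, _, _ = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(6)]
        traj1 = make_traj(topo, frames)
        shift = np.array([3.0, -1.0, 2.0])
        traj2 = make_traj(topo, [f + shift for f in frames])
        a = compute_msd(traj1, [0, 3, 5])
        b = compute_msd(traj2, [0, 3, 5])
        assert np.allclose(a.msd_um2, b.msd_um2, atol=1e-9)

    def test_pooled_equals_mean_of_per_particle(self, small_toy, rng):
        _, topo, _, _ = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(5)]
        traj = make_traj(topo, frames)
        res = compute_msd(traj, [0, 1, 2])
        assert np.allclose(res.msd_um2, res.per_particle.mean(axis=0),
                           atol=1e-12)

    def test_needs_two_frames(self, small_toy):
        _, topo, cfg, _ = small_toy
        traj = make_traj(topo, [cfg.positions])
        with pytest.raises(ValueError):
            compute_msd(traj, [0])


class TestGeometry:
    def test_single_and_two_bead_chains_analytic(self):
        track = {"c1": ["A"], "c2": ["A", "A"]}
        ann = build_genome_annotation({"c1": BIN_SIZE, "c2": 2 * BIN_SIZE},
                                      track, diploid=False)
        topo = build_topology(ann)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        traj = make_traj(topo, [pos])
        geom = chromosome_geometry(traj, topo, nucleus_radius=4.0)
        rg_red = geom.radius_of_gyration_um / DEFAULT_UNITS.length_to_um(1.0)
        assert rg_red[0] == pytest.approx(0.0, abs=1e-12)
        assert rg_red[1] == pytest.approx(1.0, abs=1e-12)   # d/2 with d=2
        assert geom.bead_radial_position[0] == pytest.approx(0.0, abs=1e-12)
        assert geom.bead_radial_position[2] == pytest.approx(1.0, abs=1e-12)


class TestClustering:
    def test_all_far_apart_zero_droplets(self, small_toy):
        _, topo, cfg, _ = small_toy
        cfg2 = cfg.copy()
        nuc = topo.indices(NUCLEOLUS)
        cfg2.positions[nuc] = np.arange(len(nuc))[:, None] * [50.0, 0, 0]
        res = cluster_droplets(cfg2, topo, NUCLEOLUS, cutoff=0.75)
        assert res.n_clusters == 0

    def test_chain_of_neighbours_is_one_cluster(self, small_toy):
        _, topo, cfg, _ = small_toy
        cfg2 = cfg.copy()
        nuc = topo.indices(NUCLEOLUS)
        cfg2.positions[nuc] = np.arange(len(nuc))[:, None] * [0.5, 0, 0]
        res = cluster_droplets(cfg2, topo, NUCLEOLUS, cutoff=0.6)
        assert res.n_clusters == 1
        assert res.sizes[0] == len(nuc)

    def test_matches_union_find_oracle(self, rng):
        ann = build_genome_annotation({"c": BIN_SIZE}, {"c": ["A"]},
                                      diploid=False)
        topo = build_topology(ann, 200, 0)
        pts = rng.uniform(-3, 3, (200, 3))
        pos = np.vstack([[100.0, 0, 0], pts])
        cfg = Configuration(pos, np.zeros(0, dtype=np.int8))
        for cutoff in rng.uniform(0.3, 1.5, 4):
            got = cluster_droplets(cfg, topo, NUCLEOLUS, cutoff=cutoff,
                                   min_size=2)
            assert got.n_clusters == naive_clusters(pts, cutoff, 2)

    def test_droplet_count_monotone_in_cutoff(self, rng):
        ann = build_genome_annotation({"c": BIN_SIZE}, {"c": ["A"]},
                                      diploid=False)
        topo = build_topology(ann, 80, 0)
        pos = np.vstack([[100.0, 0, 0], rng.uniform(-2, 2, (80, 3))])
        cfg = Configuration(pos, np.zeros(0, dtype=np.int8))
        counts = [cluster_droplets(cfg, topo, NUCLEOLUS, cutoff=c,
                                   min_size=1).n_clusters
                  for c in np.linspace(0.2, 3.0, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestEnsembleCorrelations:
    def test_identical_inputs_give_unity(self, rng):
        v = rng.random(30)
        mat, off = ensemble_correlations([v, v.copy(), v.copy()])
        assert np.allclose(mat, 1.0, atol=1e-12)
        assert off == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, rng):
        v = rng.random(30)
        mat, off = ensemble_correlations([v, -v])
        assert mat[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_pearson(self, rng):
        vecs = [rng.random(40) for _ in range(4)]
        mat, _ = ensemble_correlations(vecs)
        assert np.allclose(mat, naive_pearson_matrix(vecs), atol=1e-12)

    def test_contact_maps_use_upper_triangle(self, rng):
        m1 = rng.random((6, 6))
        m1 = 0.5 * (m1 + m1.T)
        m2 = m1.copy()
        np.fill_diagonal(m2, 0.0)       # diagonal must not matter
        c1 = ContactMap(m1, haploid=True, n_frames=1)
        c2 = ContactMap(m2, haploid=True, n_frames=1)
        mat, _ = ensemble_correlations([c1, c2])
        assert mat[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_correlations([rng.random(5), rng.random(6)])
        with pytest.raises(ValueError):
            ensemble_correlations([rng.random(5)])
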