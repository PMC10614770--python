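import numpy as np
import pytest

from nucsim.dynamics import Simulation, SpeckleReactionSpec
from nucsim.forcefield import ContactFunction, ForceFieldParameters
from nucsim.genome_model import (BIN_SIZE, Configuration,
                                 build_genome_annotation, build_topology)
from nucsim.maxent import (ConstraintSet, MaxEntOptimizer, OptimizerState,
                           adam_update, compare_constraints,
                           constraints_from_trajectory)
from nucsim.dynamics import Trajectory

from oracles import naive_constraints


def make_trajectory(topo, positions_list, states_list, dt=0.005):
    return Trajectory(
        positions=np.stack(positions_list),
        speckle_states=np.stack(states_list).astype(np.int8),
        steps=np.arange(len(positions_list)) * 100, dt=dt)


class TestAdam:
    def test_zero_gradient_is_fixed_point(self):
        theta = np.array([1.0, -2.0, 0.5])
        st = OptimizerState.for_shape(3, learning_rate=0.05)
        st = OptimizerState(m=np.full(3, 0.3), v=np.full(3, 0.2),
                            iteration=4, learning_rate=0.05)
        new, st2 = adam_update(theta, np.zeros(3), st)
        assert np.allclose(new, theta, atol=st.learning_rate * 0.35)
        assert np.all(np.abs(st2.m) < np.abs(st.m))   # moments decay

    def test_first_step_magnitude_is_learning_rate(self, rng):
        theta = rng.standard_normal(20)
        g = rng.standard_normal(20) * 10 ** rng.uniform(-3, 3, 20)
        st = OptimizerState.for_shape(20, learning_rate=0.02)
        new, _ = adam_update(theta, g, st)
        # bias-corrected Adam: the first step is lr * sign(g) to ~eps
        assert np.allclose(np.abs(new - theta), 0.02, rtol=0.01)
        assert np.all(np.sign(theta - new) == np.sign(g))

    def test_constant_gradient_moves_monotonically(self):
        theta = np.zeros(4)
        g = np.array([1.0, -1.0, 0.5, -2.0])
        st = OptimizerState.for_shape(4, learning_rate=0.01)
        prev = theta
        for _ in range(50):
            theta, st = adam_update(theta, g, st)
            assert np.all(np.sign(theta - prev) == -np.sign(g))
            prev = theta

    def test_shape_mismatch_rejected(self):
        st = OptimizerState.for_shape(3)
        with pytest.raises(ValueError):
            adam_update(np.zeros(3), np.zeros(4), st)


class TestConstraintExtraction:
    def test_colocated_beads_have_saturated_contact(self):
        ann = build_genome_annotation({"c": 3 * BIN_SIZE},
                                      {"c": ["A"] * 3}, diploid=False)
        topo = build_topology(ann)
        contact = ContactFunction(r_c=0.75, eta=6.0)
        pos = np.array([[0, 0, 0], [10, 0, 0], [0.0001, 0, 0]])
        traj = make_trajectory(topo, [pos], [np.zeros(0)])
        c = constraints_from_trajectory(traj, topo, contact)
        assert c.ideal[2] > 0.99        # beads 0 and 2 sit on top of each other

    def test_all_distant_gives_zero_constraints(self):
        ann = build_genome_annotation({"c": 4 * BIN_SIZE},
                                      {"c": ["A"] * 4}, diploid=False)
        topo = build_topology(ann, 0, 2)
        contact = ContactFunction(r_c=0.75, eta=6.0)
        pos = np.arange(6)[:, None] * np.array([100.0, 0, 0])
        traj = make_trajectory(topo, [pos], [np.array([1, 1])])
        c = constraints_from_trajectory(traj, topo, contact)
        assert np.all(c.ideal == 0)
        assert np.all(c.compartment == 0)
        assert np.all(c.tsaseq == 0)

    def test_empty_post_discard_rejected(self, small_toy):
        _, topo, cfg, params = small_toy
        traj = make_trajectory(topo, [cfg.positions], [cfg.speckle_states])
        with pytest.raises(ValueError, match="discard"):
            constraints_from_trajectory(traj, topo, params.contact,
                                        discard_steps=10_000)

    def test_matches_bruteforce_oracle(self, small_toy, rng):
        ann, topo, cfg, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(3)]
        states = [rng.integers(0, 2, topo.n_speckle) for _ in range(3)]
        traj = make_trajectory(topo, frames, states)
        got = constraints_from_trajectory(traj, topo, params.contact,
                                          s_max=19)
        ref = naive_constraints(frames, states, topo, params.contact, 19)
        assert np.allclose(got.ideal, ref["ideal"], atol=1e-12)
        assert np.allclose(got.compartment, ref["compartment"], atol=1e-12)
        assert np.allclose(got.chrom_pair, ref["chrom_pair"], atol=1e-12)
        assert np.allclose(got.damid, ref["damid"], atol=1e-12)
        assert np.allclose(got.tsaseq, ref["tsaseq"], atol=1e-12)

    def test_invariant_under_homolog_relabeling(self, diploid_toy, rng):
        ann, topo, cfg, params = diploid_toy
        frames = [rng.uniform(-1.5, 1.5, (topo.n_particles, 3))
                  for _ in range(2)]
        states = [rng.integers(0, 2, topo.n_speckle) for _ in range(2)]
        traj = make_trajectory(topo, frames, states)
        c1 = constraints_from_trajectory(traj, topo, params.contact)

        # swap the two copies of every chromosome (beads move blockwise)
        perm = np.arange(topo.n_particles)
        nb = ann.n_beads
        offs, lens = ann.chain_offsets, ann.beads_per_chain
        for h in range(ann.n_haploid):
            a, b = np.flatnonzero(ann.haploid_index == h)
            pa = np.arange(offs[a], offs[a] + lens[a])
            pb = np.arange(offs[b], offs[b] + lens[b])
            perm[pa], perm[pb] = pb, pa.copy()
        frames2 = [f[perm] for f in frames]
        traj2 = make_trajectory(topo, frames2, states)
        c2 = constraints_from_trajectory(traj2, topo, params.contact)
        for name in ("ideal", "compartment", "chrom_pair", "damid",
                     "tsaseq"):
            assert np.allclose(getattr(c1, name), getattr(c2, name),
                               atol=1e-12), name

    def test_roundtrip_serialization(self, small_toy, rng, tmp_path):
        _, topo, cfg, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))]
        states = [rng.integers(0, 2, topo.n_speckle)]
        traj = make_trajectory(topo, frames, states)
        c = constraints_from_trajectory(traj, topo, params.contact)
        path = tmp_path / "targets.json"
        c.save(path)
        back = ConstraintSet.load(path)
        assert np.array_equal(back.damid, c.damid)
        assert np.array_equal(back.chrom_pair, c.chrom_pair)


class TestExperimentalImporters:
    @staticmethod
    def _haploid_layout(ann):
        lens = ann.haploid_beads_per_chrom
        chain = np.repeat(np.arange(ann.n_haploid), lens)
        wci = np.arange(lens.sum()) - ann.haploid_offsets[chain]
        return chain, wci, ann.haploid_compartments()

    def test_hic_blocks_match_bruteforce_classification(self, small_toy,
                                                        rng):
        from nucsim.maxent import hic_constraint_blocks
        ann = small_toy[0]
        nhb = ann.n_haploid_beads
        m = rng.random((nhb, nhb))
        m = 0.5 * (m + m.T)
        (ideal, cnt_i), (comp, cnt_c), (cpair, cnt_p) = \
            hic_constraint_blocks(m, ann)
        chain, wci, labels = self._haploid_layout(ann)
        for s in (2, 5, 11):
            vals = [m[i, j] for i in range(nhb) for j in range(i + 1, nhb)
                    if chain[i] == chain[j] and abs(wci[i] - wci[j]) == s]
            assert ideal[s] == pytest.approx(np.mean(vals), abs=1e-12)
        inter = [(i, j) for i in range(nhb) for j in range(i + 1, nhb)
                 if chain[i] != chain[j]]
        got = cpair[0, 1]
        assert got == pytest.approx(
            np.mean([m[i, j] for i, j in inter
                     if {chain[i], chain[j]} == {0, 1}]), abs=1e-12)
        aa = [m[i, j] for i in range(nhb) for j in range(i + 1, nhb)
              if labels[i] == 0 and labels[j] == 0
              and (chain[i] != chain[j] or abs(wci[i] - wci[j]) >= 2)]
        assert comp[0, 0] == pytest.approx(np.mean(aa), abs=1e-12)

    def test_probability_rescaling_recovers_known_factor(self, small_toy,
                                                         rng):
        from nucsim.maxent import targets_from_experiment
        ann, topo, cfg, params = small_toy
        frames = [rng.uniform(-2, 2, (topo.n_particles, 3))
                  for _ in range(2)]
        states = [rng.integers(0, 2, topo.n_speckle) for _ in range(2)]
        ref = constraints_from_trajectory(
            make_trajectory(topo, frames, states), topo, params.contact,
            s_max=19)
        # a fake count matrix that is exactly 40x the reference scale
        nhb = ann.n_haploid_beads
        chain, wci, _ = self._haploid_layout(ann)
        m = np.zeros((nhb, nhb))
        for i in range(nhb):
            for j in range(i + 1, nhb):
                if chain[i] == chain[j]:
                    s = min(abs(wci[i] - wci[j]), 19)
                    m[i, j] = m[j, i] = 40.0 * ref.ideal[s]
                else:
                    m[i, j] = m[j, i] = 40.0 * ref.chrom_pair[chain[i],
                                                              chain[j]]
        damid = rng.random(nhb)
        tsa = rng.random(nhb)
        target, diag = targets_from_experiment(ann, m, damid, tsa, ref,
                                               s_max=19)
        assert diag["hic_probability_factor"] == pytest.approx(1 / 40.0,
                                                               rel=1e-9)
        valid = ref.ideal_count > 0
        assert np.allclose(target.ideal[valid], ref.ideal[valid],
                           atol=1e-12)

    def test_quantile_map_preserves_ranks_and_distribution(self, rng):
        from nucsim.maxent import quantile_map
        values = rng.standard_normal(200) * 7 + 3
        reference = rng.random(200) ** 2
        mapped = quantile_map(values, reference)
        assert np.array_equal(np.argsort(values), np.argsort(mapped))
        assert np.allclose(np.sort(mapped), np.sort(reference), atol=1e-12)
        with_nan = values.copy()
        with_nan[5] = np.nan
        m2 = quantile_map(with_nan, reference)
        assert m2[5] == pytest.approx(np.median(np.sort(reference)))

    def test_sparse_matrix_roundtrip(self, small_toy, rng, tmp_path):
        from nucsim.analysis import ContactMap, contact_map_to_sparse_text
        from nucsim.maxent import read_sparse_matrix
        ann, topo, _, _ = small_toy
        nhb = ann.n_haploid_beads
        m = rng.random((nhb, nhb))
        m = 0.5 * (m + m.T)
        cmap = ContactMap(m, haploid=True, n_frames=1)
        path = tmp_path / "sparse.txt"
        contact_map_to_sparse_text(cmap, topo, path)
        back = read_sparse_matrix(path, nhb)
        assert np.allclose(back, m, atol=1e-7)


class TestOptimizerCoupling:
    def test_zero_mismatch_leaves_parameters_unchanged(self, small_toy, rng):
        ann, topo, cfg, params = small_toy
        frames = [rng.uniform(-1.5, 1.5, (topo.n_particles, 3))
                  for _ in range(2)]
        states = [rng.integers(0, 2, topo.n_speckle) for _ in range(2)]
        traj = make_trajectory(topo, frames, states)
        c = constraints_from_trajectory(traj, topo, params.contact, s_max=19)
        opt = MaxEntOptimizer(ann, s_max=19)
        new = opt.update(params, c, c)
        assert np.array_equal(new.alpha_ideal, params.alpha_ideal)
        assert np.array_equal(new.lamina_coupling, params.lamina_coupling)
        assert np.array_equal(new.chrom_pair, params.chrom_pair)

    def test_update_direction_follows_contact_deficit(self, small_toy, rng):
        ann, topo, cfg, params = small_toy
        frames = [rng.uniform(-1.5, 1.5, (topo.n_particles, 3))]
        states = [rng.integers(0, 2, topo.n_speckle)]
        traj = make_trajectory(topo, frames, states)
        sim_c = constraints_from_trajectory(traj, topo, params.contact,
                                            s_max=19)
        target = ConstraintSet.from_dict(sim_c.to_dict())
        target.damid = np.clip(sim_c.damid + 0.2, 0, 1)  # want MORE contact
        opt = MaxEntOptimizer(ann, s_max=19)
        new = opt.update(params, sim_c, target)
        changed = target.damid > sim_c.damid
        # more target contact -> coupling decreases (more attractive)
        assert np.all(new.lamina_coupling[changed]
                      < params.lamina_coupling[changed])

    def test_block_residuals_and_pearson_reported(self, small_toy, rng):
        ann, topo, cfg, params = small_toy
        frames = [rng.uniform(-1.5, 1.5, (topo.n_particles, 3))]
        states = [rng.integers(0, 2, topo.n_speckle)]
        traj = make_trajectory(topo, frames, states)
        c = constraints_from_trajectory(traj, topo, params.contact)
        norms, pear = compare_constraints(c, c)
        assert set(norms) == {"ideal", "compartment", "chrom_pair",
                              "damid", "tsaseq"}
        assert all(v == 0.0 for v in norms.values())
        assert pear["damid"] == pytest.approx(1.0)
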