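"""Maximum-entropy parameterization of the nucleus model.

The couplings of the force field are in one-to-one correspondence with
ensemble-averaged contact statistics (max-ent duality): the ideal
potential with the mean intra-chromosomal contact at each genomic
separation, the compartment and chromosome-pair couplings with the mean
contact of the corresponding pair class, and the per-bead lamina /
speckle couplings with DamID-like and TSA-Seq-like contact frequencies.

Each optimization round simulates the current model, extracts those
averages (homolog-averaged), and moves every coupling against the
mismatch between simulated and experimental averages using Adam with
bias correction.  A coupling is lowered (made more attractive) when the
simulation shows too little contact, and raised when it shows too much.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .dynamics import (IntegratorSpec, Simulation, SpeckleReactionSpec,
                       Trajectory)
from .forcefield import ContactFunction, ForceField, ForceFieldParameters
from .genome_model import (LAMINA, SPECKLE, Configuration, GenomeAnnotation,
                           NucleusTopology)

BLOCKS = ("ideal", "compartment", "chrom_pair", "damid", "tsaseq")

_COMP_PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


# ---------------------------------------------------------------------------
# constraint container


@dataclass
class ConstraintSet:
    """Matched simulated/experimental ensemble averages.

    All entries are mean contact-indicator values in [0, 1].  Matrix
    blocks carry count arrays; classes with zero pairs are invalid and
    excluded from residuals and updates.
    """

    ideal: np.ndarray              # (S,) mean contact at separation s
    ideal_count: np.ndarray        # (S,) number of contributing pairs
    compartment: np.ndarray        # (3, 3) symmetric
    compartment_count: np.ndarray
    chrom_pair: np.ndarray         # (n_hap, n_hap) symmetric, homolog-avg
    chrom_pair_count: np.ndarray
    damid: np.ndarray              # (n_haploid_beads,)
    tsaseq: np.ndarray             # (n_haploid_beads,)
    n_frames: int = 0

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, valid mask) of one constraint block, flattened."""
        if name == "ideal":
            valid = self.ideal_count > 0
            valid[:2] = False          # s <= 1 carries no coupling
            return self.ideal, valid
        if name == "compartment":
            iu = np.triu_indices(3)
            return (self.compartment[iu],
                    self.compartment_count[iu] > 0)
        if name == "chrom_pair":
            n = self.chrom_pair.shape[0]
            iu = np.triu_indices(n)
            return (self.chrom_pair[iu], self.chrom_pair_count[iu] > 0)
        if name == "damid":
            return self.damid, np.ones(self.damid.size, dtype=bool)
        if name == "tsaseq":
            return self.tsaseq, np.ones(self.tsaseq.size, dtype=bool)
        raise KeyError(name)

    def residuals(self, other: "ConstraintSet") -> dict[str, np.ndarray]:
        out = {}
        for name in BLOCKS:
            a, va = self.block(name)
            b, vb = other.block(name)
            v = va & vb
            out[name] = a[v] - b[v]
        return out

    def total_residual_norm(self, other: "ConstraintSet") -> float:
        res = self.residuals(other)
        return float(np.sqrt(sum(np.sum(r * r) for r in res.values())))

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist()
                for k in ("ideal", "ideal_count", "compartment",
                          "compartment_count", "chrom_pair",
                          "chrom_pair_count", "damid", "tsaseq")} | {
                              "n_frames": self.n_frames}

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintSet":
        return cls(**{k: np.array(d[k]) for k in
                      ("ideal", "ideal_count", "compartment",
                       "compartment_count", "chrom_pair", "chrom_pair_count",
                       "damid", "tsaseq")},
                   n_frames=int(d.get("n_frames", 0)))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ConstraintSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# extraction kernels


@njit(cache=True)
def _chromatin_pair_sums(pos, n_chrom, chain, wci, comp, hap_chrom,
                         rc, eta, fshift, rcut, s_last,
                         sum_ideal, cnt_ideal, sum_comp, cnt_comp,
                         sum_cpair, cnt_cpair):
    for i in range(n_chrom):
        for j in range(i + 1, n_chrom):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            f = 0.0
            if r < rcut:
                e = np.exp(-2.0 * eta * (rc - r))
                t = (1.0 - e) / (1.0 + e)
                f = 0.5 * (1.0 + t) - fshift
                if f < 0.0:
                    f = 0.0
            if chain[i] == chain[j]:
                s = wci[j] - wci[i]
                if s < 0:
                    s = -s
                if s >= 2:
                    ss = s if s < s_last else s_last
                    sum_ideal[ss] += f
                    cnt_ideal[ss] += 1
                    a, b = comp[i], comp[j]
                    sum_comp[a, b] += f
                    cnt_comp[a, b] += 1
            else:
                a, b = comp[i], comp[j]
                sum_comp[a, b] += f
                cnt_comp[a, b] += 1
                ha, hb = hap_chrom[i], hap_chrom[j]
                sum_cpair[ha, hb] += f
                cnt_cpair[ha, hb] += 1


@njit(cache=True)
def _landmark_profile(pos, bead_idx, landmark_idx, rc, eta, fshift, rcut,
                      out):
    """Soft-OR contact frequency of each bead with a set of landmarks."""
    for n in range(bead_idx.shape[0]):
        i = bead_idx[n]
        miss = 1.0
        for m in range(landmark_idx.shape[0]):
            j = landmark_idx[m]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rcut:
                e = np.exp(-2.0 * eta * (rc - r))
                t = (1.0 - e) / (1.0 + e)
                f = 0.5 * (1.0 + t) - fshift
                if f > 0.0:
                    miss *= 1.0 - f
        out[n] += 1.0 - miss


def constraints_from_trajectory(trajectory: Trajectory,
                                topology: NucleusTopology,
                                contact: ContactFunction | None = None,
                                discard_steps: int = 0,
                                s_max: int | None = None) -> ConstraintSet:
    """Time- and homolog-averaged constraint vectors from a trajectory.

    Speckle (TSA-like) contacts are counted against dP particles only;
    per-bead profiles use the soft-OR probability of touching at least
    one landmark particle.  ``s_max`` clamps the separation axis exactly
    as the ideal potential does, so constraint and parameter vectors
    align one-to-one.
    """
    ann = topology.annotation
    if ann is None:
        raise ValueError("constraint extraction needs a genome annotation")
    contact = contact or ContactFunction()
    traj = trajectory.after_discard(discard_steps)
    if traj.n_frames == 0:
        raise ValueError("no frames left after equilibration discard")

    n_chrom = ann.n_beads
    chain = ann.chain_of_bead.astype(np.int64)
    wci = ann.within_chain_index.astype(np.int64)
    comp = ann.compartments.astype(np.int64)
    hapc = ann.haploid_index[ann.chain_of_bead].astype(np.int64)
    hap_bead = ann.bead_haploid_id
    n_hap = ann.n_haploid
    if s_max is None:
        s_max = int(ann.beads_per_chain.max()) - 1
    S = s_max + 1
    s_last = s_max

    rc, eta = contact.r_c, contact.eta
    fshift, rcut = float(contact.shift), contact.cutoff

    sum_ideal = np.zeros(S)
    cnt_ideal = np.zeros(S, dtype=np.int64)
    sum_comp = np.zeros((3, 3))
    cnt_comp = np.zeros((3, 3), dtype=np.int64)
    sum_cpair = np.zeros((n_hap, n_hap))
    cnt_cpair = np.zeros((n_hap, n_hap), dtype=np.int64)
    damid_acc = np.zeros(n_chrom)
    tsa_acc = np.zeros(n_chrom)

    bead_idx = np.arange(n_chrom, dtype=np.int64)
    lam_idx = topology.indices(LAMINA).astype(np.int64)
    spk_idx = topology.indices(SPECKLE).astype(np.int64)

    for fidx in range(traj.n_frames):
        pos = traj.positions[fidx]
        _chromatin_pair_sums(pos, n_chrom, chain, wci, comp, hapc,
                             rc, eta, fshift, rcut, s_last,
                             sum_ideal, cnt_ideal, sum_comp, cnt_comp,
                             sum_cpair, cnt_cpair)
        if lam_idx.size:
            _landmark_profile(pos, bead_idx, lam_idx, rc, eta, fshift, rcut,
                              damid_acc)
        if spk_idx.size:
            dp = spk_idx[traj.speckle_states[fidx] == 1]
            if dp.size:
                _landmark_profile(pos, bead_idx, dp, rc, eta, fshift, rcut,
                                  tsa_acc)

    nf = traj.n_frames
    ideal = np.where(cnt_ideal > 0, sum_ideal / np.maximum(cnt_ideal, 1), 0.0)
    # symmetrize the label/ chromosome matrices (accumulated one-sided)
    sum_comp = sum_comp + sum_comp.T - np.diag(np.diag(sum_comp))
    cnt_comp = cnt_comp + cnt_comp.T - np.diag(np.diag(cnt_comp))
    compartment = np.where(cnt_comp > 0, sum_comp / np.maximum(cnt_comp, 1),
                           0.0)
    sum_cpair = sum_cpair + sum_cpair.T - np.diag(np.diag(sum_cpair))
    cnt_cpair = cnt_cpair + cnt_cpair.T - np.diag(np.diag(cnt_cpair))
    cpair = np.where(cnt_cpair > 0, sum_cpair / np.maximum(cnt_cpair, 1), 0.0)

    # homolog-average the per-bead profiles
    nhb = ann.n_haploid_beads
    damid = np.zeros(nhb)
    tsa = np.zeros(nhb)
    copies = np.zeros(nhb)
    np.add.at(damid, hap_bead, damid_acc / nf)
    np.add.at(tsa, hap_bead, tsa_acc / nf)
    np.add.at(copies, hap_bead, 1.0)
    damid /= np.maximum(copies, 1.0)
    tsa /= np.maximum(copies, 1.0)

    return ConstraintSet(ideal=ideal, ideal_count=cnt_ideal // nf,
                         compartment=compartment,
                         compartment_count=cnt_comp // nf,
                         chrom_pair=cpair, chrom_pair_count=cnt_cpair // nf,
                         damid=damid, tsaseq=tsa, n_frames=nf)


# ---------------------------------------------------------------------------
# experimental-target importers


@njit(cache=True)
def _matrix_class_sums(mat, chain, wci, comp, s_last,
                       sum_ideal, cnt_ideal, sum_comp, cnt_comp,
                       sum_cpair, cnt_cpair, hap_of_chain):
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            v = mat[i, j]
            if np.isnan(v):
                continue
            if chain[i] == chain[j]:
                s = wci[j] - wci[i]
                if s < 0:
                    s = -s
                if s >= 2:
                    ss = s if s < s_last else s_last
                    sum_ideal[ss] += v
                    cnt_ideal[ss] += 1
                    sum_comp[comp[i], comp[j]] += v
                    cnt_comp[comp[i], comp[j]] += 1
            else:
                sum_comp[comp[i], comp[j]] += v
                cnt_comp[comp[i], comp[j]] += 1
                sum_cpair[hap_of_chain[chain[i]], hap_of_chain[chain[j]]] += v
                cnt_cpair[hap_of_chain[chain[i]], hap_of_chain[chain[j]]] += 1


def hic_constraint_blocks(matrix: np.ndarray, annotation: GenomeAnnotation,
                          s_max: int | None = None):
    """Class-averaged contact statistics from a haploid 100-KB matrix.

    ``matrix`` is dense over the concatenated haploid bins (e.g. a
    VC_SQRT-normalized Hi-C matrix); NaN entries are skipped.  Returns
    the (values, counts) pairs for the ideal, compartment and
    chromosome-pair blocks, on the matrix's own count scale.
    """
    nhb = annotation.n_haploid_beads
    if matrix.shape != (nhb, nhb):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match the haploid "
            f"genome ({nhb} bins)")
    if s_max is None:
        s_max = int(annotation.haploid_beads_per_chrom.max()) - 1
    lens = annotation.haploid_beads_per_chrom
    chain = np.repeat(np.arange(annotation.n_haploid), lens).astype(np.int64)
    wci = (np.arange(nhb) - annotation.haploid_offsets[chain]).astype(np.int64)
    comp = annotation.haploid_compartments().astype(np.int64)
    n_hap = annotation.n_haploid
    S = s_max + 1
    sum_ideal, cnt_ideal = np.zeros(S), np.zeros(S, dtype=np.int64)
    sum_comp, cnt_comp = np.zeros((3, 3)), np.zeros((3, 3), dtype=np.int64)
    sum_cp, cnt_cp = np.zeros((n_hap, n_hap)), np.zeros((n_hap, n_hap),
                                                        dtype=np.int64)
    _matrix_class_sums(np.asarray(matrix, dtype=np.float64), chain, wci,
                       comp, s_max, sum_ideal, cnt_ideal, sum_comp,
                       cnt_comp, sum_cp, cnt_cp,
                       np.arange(n_hap, dtype=np.int64))
    ideal = np.where(cnt_ideal > 0, sum_ideal / np.maximum(cnt_ideal, 1), 0)
    sum_comp = sum_comp + sum_comp.T - np.diag(np.diag(sum_comp))
    cnt_comp = cnt_comp + cnt_comp.T - np.diag(np.diag(cnt_comp))
    compartment = np.where(cnt_comp > 0,
                           sum_comp / np.maximum(cnt_comp, 1), 0)
    sum_cp = sum_cp + sum_cp.T - np.diag(np.diag(sum_cp))
    cnt_cp = cnt_cp + cnt_cp.T - np.diag(np.diag(cnt_cp))
    cpair = np.where(cnt_cp > 0, sum_cp / np.maximum(cnt_cp, 1), 0)
    return (ideal, cnt_ideal), (compartment, cnt_comp), (cpair, cnt_cp)


def quantile_map(values: np.ndarray,
                 reference: np.ndarray) -> np.ndarray:
    """Map a track onto the distribution of a reference signal.

    Rank-preserving: each value is replaced by the reference quantile of
    its own rank.  NaNs are filled with the reference median.  Used to
    bring raw DamID/TSA-Seq units onto the simulated contact-frequency
    scale before computing mismatches.
    """
    values = np.asarray(values, dtype=float)
    ref = np.sort(np.asarray(reference, dtype=float))
    out = np.full(values.shape, np.median(ref))
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = np.empty(n)
    order = np.argsort(values[ok], kind="stable")
    ranks[order] = np.arange(n)
    q = ranks / max(n - 1, 1)
    out[ok] = np.interp(q, np.linspace(0, 1, ref.size), ref)
    return out


def targets_from_experiment(annotation: GenomeAnnotation,
                            hic_matrix: np.ndarray,
                            damid_values: np.ndarray,
                            tsaseq_values: np.ndarray,
                            reference: ConstraintSet,
                            s_max: int | None = None,
                            short_range: tuple[int, int] = (2, 5)
                            ) -> tuple[ConstraintSet, dict]:
    """Assemble experimental optimization targets on the model's scale.

    Hi-C counts carry no absolute contact-probability scale, so all
    count-derived blocks are multiplied by one factor chosen to match
    the reference (simulated) mean contact over the short-range
    separations ``short_range``; DamID/TSA tracks are quantile-mapped
    onto the corresponding simulated profiles.  Returns the target set
    and a diagnostics dict including the rescaling factor.
    """
    (ideal, cnt_i), (comp, cnt_c), (cpair, cnt_p) = hic_constraint_blocks(
        hic_matrix, annotation, s_max=s_max)
    lo, hi = short_range
    sel = np.zeros(ideal.size, dtype=bool)
    sel[lo:hi + 1] = True
    sel &= cnt_i > 0
    ref_sel = sel.copy()
    ref_sel &= reference.ideal_count[:sel.size] > 0
    exp_mean = float(np.mean(ideal[ref_sel]))
    ref_mean = float(np.mean(reference.ideal[:sel.size][ref_sel]))
    if exp_mean <= 0:
        raise ValueError("short-range Hi-C signal is empty; cannot rescale")
    factor = ref_mean / exp_mean
    out = ConstraintSet(
        ideal=np.clip(ideal * factor, 0, 1), ideal_count=cnt_i,
        compartment=np.clip(comp * factor, 0, 1), compartment_count=cnt_c,
        chrom_pair=np.clip(cpair * factor, 0, 1), chrom_pair_count=cnt_p,
        damid=quantile_map(damid_values, reference.damid),
        tsaseq=quantile_map(tsaseq_values, reference.tsaseq),
        n_frames=0)
    return out, {"hic_probability_factor": factor,
                 "short_range_exp_mean": exp_mean,
                 "short_range_ref_mean": ref_mean}


def read_dense_matrix(path) -> np.ndarray:
    """Dense whitespace-separated 100-KB matrix text."""
    return np.loadtxt(path)


def read_sparse_matrix(path, n_bins: int) -> np.ndarray:
    """Sparse bin-pair text (``i j value`` rows, ``#`` comments)."""
    out = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            i, j, v = line.split()
            i, j = int(i), int(j)
            out[i, j] = out[j, i] = float(v)
    return out


# ---------------------------------------------------------------------------
# Adam


@dataclass
class OptimizerState:
    """Adam moment estimates for one parameter block."""

    m: np.ndarray
    v: np.ndarray
    iteration: int = 0
    learning_rate: float = 0.02
    beta1: float = 0.9
    beta2: float = 0.999
    eps_adam: float = 1e-8

    @classmethod
    def for_shape(cls, shape, learning_rate: float = 0.02,
                  **kw) -> "OptimizerState":
        return cls(m=np.zeros(shape), v=np.zeros(shape),
                   learning_rate=learning_rate, **kw)


def adam_update(parameters: np.ndarray, gradient: np.ndarray,
                state: OptimizerState) -> tuple[np.ndarray, OptimizerState]:
    """One bias-corrected Adam descent step; returns new copies."""
    g = np.asarray(gradient, dtype=float)
    if g.shape != np.asarray(parameters).shape or g.shape != state.m.shape:
        raise ValueError("gradient/parameter/moment shapes do not match")
    t = state.iteration + 1
    m = state.beta1 * state.m + (1 - state.beta1) * g
    v = state.beta2 * state.v + (1 - state.beta2) * g * g
    mhat = m / (1 - state.beta1 ** t)
    vhat = v / (1 - state.beta2 ** t)
    new = np.asarray(parameters, dtype=float) - \
        state.learning_rate * mhat / (np.sqrt(vhat) + state.eps_adam)
    return new, OptimizerState(m=m, v=v, iteration=t,
                               learning_rate=state.learning_rate,
                               beta1=state.beta1, beta2=state.beta2,
                               eps_adam=state.eps_adam)


# ---------------------------------------------------------------------------
# the iteration loop


@dataclass
class SimulationBudget:
    n_steps: int = 30_000
    record_interval: int = 300
    discard_steps: int = 3_000


@dataclass
class IterationDiagnostics:
    iteration: int
    residual_norms: dict[str, float]
    pearson: dict[str, float]
    total_residual: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compare_constraints(sim: ConstraintSet,
                        target: ConstraintSet) -> tuple[dict, dict]:
    """Per-block residual norms and Pearson correlations."""
    norms, pear = {}, {}
    for name in BLOCKS:
        a, va = sim.block(name)
        b, vb = target.block(name)
        v = va & vb
        norms[name] = float(np.linalg.norm(a[v] - b[v]))
        pear[name] = _pearson(a[v], b[v])
    return norms, pear


class MaxEntOptimizer:
    """Adam state per constraint block, mapped one-to-one onto couplings."""

    def __init__(self, annotation: GenomeAnnotation, s_max: int,
                 learning_rate: float = 0.02,
                 block_learning_rates: dict[str, float] | None = None,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps_adam: float = 1e-8):
        lr = {name: learning_rate for name in BLOCKS}
        lr.update(block_learning_rates or {})
        nhb = annotation.n_haploid_beads
        n_hap = annotation.n_haploid
        kw = dict(beta1=beta1, beta2=beta2, eps_adam=eps_adam)
        self.states = {
            "ideal": OptimizerState.for_shape(s_max + 1, lr["ideal"], **kw),
            "compartment": OptimizerState.for_shape((3, 3),
                                                    lr["compartment"], **kw),
            "chrom_pair": OptimizerState.for_shape((n_hap, n_hap),
                                                   lr["chrom_pair"], **kw),
            "damid": OptimizerState.for_shape(nhb, lr["damid"], **kw),
            "tsaseq": OptimizerState.for_shape(nhb, lr["tsaseq"], **kw),
        }

    def update(self, params: ForceFieldParameters, sim_c: ConstraintSet,
               target: ConstraintSet) -> ForceFieldParameters:
        """Move each coupling against its own average's mismatch.

        The descent gradient for a coupling is (experimental - simulated)
        mean contact: a deficit of simulated contact lowers the coupling
        (more attractive), an excess raises it.
        """
        import copy
        p = copy.deepcopy(params)

        g = np.zeros_like(p.alpha_ideal)
        n = min(g.size, sim_c.ideal.size)
        valid = sim_c.ideal_count[:n] > 0
        valid[:2] = False
        g[:n][valid] = target.ideal[:n][valid] - sim_c.ideal[:n][valid]
        p.alpha_ideal, self.states["ideal"] = adam_update(
            p.alpha_ideal, g, self.states["ideal"])

        g = np.where((sim_c.compartment_count > 0),
                     target.compartment - sim_c.compartment, 0.0)
        p.alpha_comp, self.states["compartment"] = adam_update(
            p.alpha_comp, g, self.states["compartment"])
        p.alpha_comp = 0.5 * (p.alpha_comp + p.alpha_comp.T)

        g = np.where(sim_c.chrom_pair_count > 0,
                     target.chrom_pair - sim_c.chrom_pair, 0.0)
        p.chrom_pair, self.states["chrom_pair"] = adam_update(
            p.chrom_pair, g, self.states["chrom_pair"])
        p.chrom_pair = 0.5 * (p.chrom_pair + p.chrom_pair.T)

        g = target.damid - sim_c.damid
        p.lamina_coupling, self.states["damid"] = adam_update(
            p.lamina_coupling, g, self.states["damid"])

        g = target.tsaseq - sim_c.tsaseq
        p.speckle_coupling, self.states["tsaseq"] = adam_update(
            p.speckle_coupling, g, self.states["tsaseq"])
        return p


def maxent_iteration(params: ForceFieldParameters,
                     target: ConstraintSet,
                     topology: NucleusTopology,
                     configuration: Configuration,
                     optimizer: MaxEntOptimizer,
                     budget: SimulationBudget,
                     integrator: IntegratorSpec | None = None,
                     reactions: SpeckleReactionSpec | None = None,
                     seed: int = 0,
                     iteration: int = 0):
    """One optimization round: simulate, extract, Adam-update.

    Returns (new params, final configuration for warm-starting the next
    round, simulated constraints, diagnostics).
    """
    sim = Simulation(topology, params, configuration,
                     integrator=integrator, reactions=reactions, seed=seed)
    traj = sim.run(budget.n_steps, record_interval=budget.record_interval)
    sim_c = constraints_from_trajectory(
        traj, topology, params.contact, discard_steps=budget.discard_steps,
        s_max=len(params.alpha_ideal) - 1)
    norms, pear = compare_constraints(sim_c, target)
    diag = IterationDiagnostics(
        iteration=iteration, residual_norms=norms, pearson=pear,
        total_residual=float(np.sqrt(sum(x * x for x in norms.values()))))
    new_params = optimizer.update(params, sim_c, target)
    return new_params, sim.configuration, sim_c, diag


def optimize_parameters(topology: NucleusTopology,
                        configuration: Configuration,
                        target: ConstraintSet,
                        n_iterations: int,
                        budget: SimulationBudget | None = None,
                        params: ForceFieldParameters | None = None,
                        integrator: IntegratorSpec | None = None,
                        reactions: SpeckleReactionSpec | None = None,
                        learning_rate: float = 0.02,
                        block_learning_rates: dict[str, float] | None = None,
                        seed: int = 0):
    """Full iterative loop from (by default) zero couplings.

    Returns (best parameters by total residual, history of diagnostics,
    last simulated constraints).  Each round warm-starts from the final
    configuration of the previous one.
    """
    ann = topology.annotation
    budget = budget or SimulationBudget()
    if params is None:
        params = ForceFieldParameters.zeros(
            ann, s_max=int(ann.beads_per_chain.max()) - 1)
    optimizer = MaxEntOptimizer(ann, s_max=len(params.alpha_ideal) - 1,
                                learning_rate=learning_rate,
                                block_learning_rates=block_learning_rates)
    history: list[IterationDiagnostics] = []
    best_params, best_res = params, np.inf
    config = configuration
    sim_c = None
    for it in range(n_iterations):
        try:
            params, config, sim_c, diag = maxent_iteration(
                params, target, topology, config, optimizer, budget,
                integrator=integrator, reactions=reactions,
                seed=seed + 1000 * it, iteration=it)
        except Exception as exc:
            raise RuntimeError(
                f"optimization failed in iteration {it}: {exc}") from exc
        history.append(diag)
        if diag.total_residual < best_res:
            best_res = diag.total_residual
            best_params = params
    return best_params, history, sim_c
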