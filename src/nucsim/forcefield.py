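"""Energy and force evaluation for the whole-nucleus model.

Interaction classes
-------------------
* chromatin backbone bonds (harmonic) and the lamina mesh bonds,
* a bounded soft-core excluded volume between all particle pairs,
* contact-based chromatin couplings: an ideal potential by genomic
  separation, compartment-pair couplings over {A, B, C}, specific
  chromosome-pair couplings, and per-bead couplings to the lamina,
  speckles (dP state only) and nucleoli,
* Lennard-Jones condensation for nucleolus-nucleolus and dP-dP speckle
  pairs; all other body pairs are purely repulsive (WCA),
* a half-harmonic spherical confinement and an optional harmonic
  z-compression acting on lamina particles (nuclear deformation).

All couplings multiply a smooth contact indicator
``f(r) = 1/2 [1 + tanh(eta (r_c - r))]`` which is shifted and truncated
at a finite support radius so that energies and forces are continuous.
Negative couplings are attractive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .genome_model import (CHROMATIN, LAMINA, NUCLEOLUS, SPECKLE, STATE_DP,
                           Configuration, GenomeAnnotation, NucleusTopology)

SCHEMA_VERSION = 1

ENERGY_TERMS = (
    "bond_backbone", "bond_lamina", "excluded_volume", "ideal",
    "compartment", "chrom_pair", "lamina_coupling", "speckle_coupling",
    "nucleolus_coupling", "lj_body", "confinement", "deformation",
)


# ---------------------------------------------------------------------------
# contact indicator


@dataclass(frozen=True)
class ContactFunction:
    """Smooth, differentiable contact indicator.

    ``value`` is the raw sigmoid (0.5 exactly at ``r_c``); ``truncated``
    subtracts the tail value at the support cutoff and is identically
    zero beyond it -- this is the form entering energies and
    contact-frequency observables so that both are consistent.
    """

    r_c: float = 1.75
    eta: float = 3.0
    cutoff_pad: float = 6.0

    @property
    def cutoff(self) -> float:
        return self.r_c + self.cutoff_pad / self.eta

    @property
    def shift(self) -> float:
        return 0.5 * (1.0 + np.tanh(-self.cutoff_pad))

    def value(self, r):
        r = np.asarray(r, dtype=float)
        return 0.5 * (1.0 + np.tanh(self.eta * (self.r_c - r)))

    def derivative(self, r):
        r = np.asarray(r, dtype=float)
        t = np.tanh(self.eta * (self.r_c - r))
        return -0.5 * self.eta * (1.0 - t * t)

    def truncated(self, r):
        r = np.asarray(r, dtype=float)
        out = self.value(r) - self.shift
        return np.where(r < self.cutoff, np.maximum(out, 0.0), 0.0)


# ---------------------------------------------------------------------------
# parameters


def _sym(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError(f"{name} must be a symmetric square matrix")
    return a


@dataclass
class ForceFieldParameters:
    """All tunable couplings of the nucleus model (reduced units)."""

    bond_style: str = "harmonic"
    bond_k: float = 30.0
    bond_r0: float = 1.0
    lamina_bond_k: float = 100.0

    excluded_volume_k: float = 20.0
    # per-category nominal diameters: chromatin, nucleolus, speckle, lamina
    diameters: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.5))

    contact: ContactFunction = field(default_factory=ContactFunction)

    # chromatin couplings (negative = attractive)
    alpha_ideal: np.ndarray = field(
        default_factory=lambda: np.zeros(1001))      # indexed by separation
    alpha_comp: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3)))    # over {A, B, C}
    chrom_pair: np.ndarray = field(
        default_factory=lambda: np.zeros((1, 1)))    # over haploid ids
    lamina_coupling: np.ndarray = field(
        default_factory=lambda: np.zeros(0))         # per haploid bead
    speckle_coupling: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    nucleolus_coupling: np.ndarray = field(
        default_factory=lambda: np.zeros(0))

    # body condensation
    lj_eps_nucleolus: float = 3.0
    lj_eps_speckle: float = 3.0
    lj_eps_repulsive: float = 1.0
    lj_sigma: float = 0.5
    lj_cutoff_factor: float = 2.5

    confinement_k: float = 100.0
    confinement_radius: float | None = None   # default: mesh radius - 0.1

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.alpha_ideal = np.asarray(self.alpha_ideal, dtype=float)
        self.alpha_comp = _sym(self.alpha_comp, "alpha_comp")
        self.chrom_pair = _sym(self.chrom_pair, "chrom_pair")
        self.lamina_coupling = np.asarray(self.lamina_coupling, dtype=float)
        self.speckle_coupling = np.asarray(self.speckle_coupling, dtype=float)
        self.nucleolus_coupling = np.asarray(self.nucleolus_coupling, dtype=float)
        if self.lj_sigma <= 0 or self.lj_cutoff_factor <= 0:
            raise ValueError("LJ sigma and cutoff must be positive")

    @property
    def lj_cutoff(self) -> float:
        return self.lj_cutoff_factor * self.lj_sigma

    @classmethod
    def zeros(cls, annotation: GenomeAnnotation, s_max: int = 1000,
              **kwargs) -> "ForceFieldParameters":
        """Parameters with all chromatin couplings zero, sized for a genome."""
        n_hap = annotation.n_haploid
        n_hb = annotation.n_haploid_beads
        return cls(alpha_ideal=np.zeros(s_max + 1),
                   alpha_comp=np.zeros((3, 3)),
                   chrom_pair=np.zeros((n_hap, n_hap)),
                   lamina_coupling=np.zeros(n_hb),
                   speckle_coupling=np.zeros(n_hb),
                   nucleolus_coupling=np.zeros(n_hb),
                   **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "bonds": {"style": self.bond_style, "k": self.bond_k,
                      "r0": self.bond_r0, "lamina_k": self.lamina_bond_k},
            "excluded_volume": {"k": self.excluded_volume_k,
                                "diameters": self.diameters.tolist()},
            "contact": {"r_c": self.contact.r_c, "eta": self.contact.eta,
                        "cutoff_pad": self.contact.cutoff_pad},
            "alpha_ideal": self.alpha_ideal.tolist(),
            "alpha_comp": self.alpha_comp.tolist(),
            "chrom_pair": self.chrom_pair.tolist(),
            "lamina_coupling": self.lamina_coupling.tolist(),
            "speckle_coupling": self.speckle_coupling.tolist(),
            "nucleolus_coupling": self.nucleolus_coupling.tolist(),
            "lj": {"eps_nucleolus": self.lj_eps_nucleolus,
                   "eps_speckle": self.lj_eps_speckle,
                   "eps_repulsive": self.lj_eps_repulsive,
                   "sigma": self.lj_sigma,
                   "cutoff_factor": self.lj_cutoff_factor},
            "confinement": {"k": self.confinement_k,
                            "radius": self.confinement_radius},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParameters":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported parameter schema version")
        return cls(
            bond_style=d["bonds"]["style"], bond_k=d["bonds"]["k"],
            bond_r0=d["bonds"]["r0"], lamina_bond_k=d["bonds"]["lamina_k"],
            excluded_volume_k=d["excluded_volume"]["k"],
            diameters=np.array(d["excluded_volume"]["diameters"]),
            contact=ContactFunction(**d["contact"]),
            alpha_ideal=np.array(d["alpha_ideal"]),
            alpha_comp=np.array(d["alpha_comp"]),
            chrom_pair=np.array(d["chrom_pair"]),
            lamina_coupling=np.array(d["lamina_coupling"]),
            speckle_coupling=np.array(d["speckle_coupling"]),
            nucleolus_coupling=np.array(d["nucleolus_coupling"]),
            lj_eps_nucleolus=d["lj"]["eps_nucleolus"],
            lj_eps_speckle=d["lj"]["eps_speckle"],
            lj_eps_repulsive=d["lj"]["eps_repulsive"],
            lj_sigma=d["lj"]["sigma"],
            lj_cutoff_factor=d["lj"]["cutoff_factor"],
            confinement_k=d["confinement"]["k"],
            confinement_radius=d["confinement"]["radius"],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ForceFieldParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# numba kernels

_LJ_CAP_FACTOR = 0.7  # below this fraction of sigma the LJ branch is linearized


@njit(cache=True, inline="always")
def _lj_pair(r, eps, sigma, cutoff, shift, cap):
    """Truncated-shifted 12-6 LJ with a linear soft cap below ``cap``.

    Returns (energy, dE/dr)."""
    if r >= cutoff:
        return 0.0, 0.0
    rr = r if r > cap else cap
    x2 = (sigma / rr) * (sigma / rr)
    x6 = x2 * x2 * x2
    x12 = x6 * x6
    e = 4.0 * eps * (x12 - x6) - shift
    de = -4.0 * eps * (12.0 * x12 - 6.0 * x6) / rr
    if r < cap:
        e = e + de * (r - cap)
    return e, de


@njit(cache=True, inline="always")
def _contact_pair(r, rc, eta, fshift, cutoff):
    """Shifted-truncated contact indicator and its radial derivative."""
    if r >= cutoff:
        return 0.0, 0.0
    # tanh via exp is ~3x faster under numba and identical to rounding
    e = np.exp(-2.0 * eta * (rc - r))
    t = (1.0 - e) / (1.0 + e)
    f = 0.5 * (1.0 + t) - fshift
    if f < 0.0:
        f = 0.0
        return f, 0.0
    df = -0.5 * eta * (1.0 - t * t)
    return f, df


@njit(cache=True)
def _bond_kernel(pos, bi, bj, bk, br0, forces):
    e = 0.0
    for n in range(bi.shape[0]):
        i, j = bi[n], bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[n]
        e += 0.5 * bk[n] * dr * dr
        if r > 1e-12:
            g = bk[n] * dr / r        # dE/dr / r
            fx, fy, fz = -g * dx, -g * dy, -g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e


@njit(cache=True)
def _pair_kernel(pos, pi, pj, cat, chain, comp, wci, hap_chrom, hap_bead,
                 state, alpha_ideal, alpha_comp, chi, lam_c, spk_c, nuc_c,
                 rc, eta, fshift, rcut_contact,
                 ev_k, diam, lj_eps_nn, lj_eps_ss, lj_eps_rep, lj_sigma,
                 lj_cut, lj_shift_att_nn, lj_shift_att_ss, wca_cut,
                 has_cc, has_cl, has_cs, has_cn, rcut2_pair,
                 forces, energies):
    """Accumulate all non-bonded pair terms for an explicit pair list.

    ``energies`` indexes: 0 excluded volume, 1 ideal, 2 compartment,
    3 chrom-pair, 4 lamina coupling, 5 speckle coupling, 6 nucleolus
    coupling, 7 body LJ.
    """
    cap = _LJ_CAP_FACTOR * lj_sigma
    s_last = alpha_ideal.shape[0] - 1
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut2_pair[cat[i], cat[j]]:
            continue
        r = np.sqrt(r2)
        ci, cj = cat[i], cat[j]
        dEdr = 0.0

        body_lj = False
        if ci == 1 and cj == 1:            # nucleolus-nucleolus
            e, de = _lj_pair(r, lj_eps_nn, lj_sigma, lj_cut,
                             lj_shift_att_nn, cap)
            energies[7] += e
            dEdr += de
            body_lj = True
        elif ci == 2 and cj == 2:          # speckle-speckle
            if state[i] == 1 and state[j] == 1:
                e, de = _lj_pair(r, lj_eps_ss, lj_sigma, lj_cut,
                                 lj_shift_att_ss, cap)
            else:
                e, de = _lj_pair(r, lj_eps_rep, lj_sigma, wca_cut,
                                 -lj_eps_rep, cap)
            energies[7] += e
            dEdr += de
            body_lj = True

        if not body_lj:
            # soft-core excluded volume, bounded at r = 0
            d = 0.5 * (diam[ci] + diam[cj])
            if r < d:
                skip = False
                if ci == 0 and cj == 0 and chain[i] == chain[j]:
                    s = wci[i] - wci[j]
                    if s < 0:
                        s = -s
                    if s == 1:
                        skip = True     # bonded neighbours: backbone only
                if not skip:
                    dr = d - r
                    energies[0] += 0.5 * ev_k * dr * dr
                    dEdr += -ev_k * dr

        if ci == 0 and cj == 0:
            same = chain[i] == chain[j]
            coeff = 0.0
            s = wci[i] - wci[j]
            if s < 0:
                s = -s
            if same and s <= 1:
                coeff = 0.0              # bonded or identical: no coupling
            elif has_cc:
                coeff = alpha_comp[comp[i], comp[j]]
                if same:
                    ss = s if s < s_last else s_last
                    coeff += alpha_ideal[ss]
                else:
                    coeff += chi[hap_chrom[i], hap_chrom[j]]
            if coeff != 0.0 and r < rcut_contact:
                f, df = _contact_pair(r, rc, eta, fshift, rcut_contact)
                if same:
                    ss = s if s < s_last else s_last
                    ai = alpha_ideal[ss]
                    energies[1] += ai * f
                    energies[2] += alpha_comp[comp[i], comp[j]] * f
                else:
                    energies[2] += alpha_comp[comp[i], comp[j]] * f
                    energies[3] += chi[hap_chrom[i], hap_chrom[j]] * f
                dEdr += coeff * df
        elif (ci == 0 and cj == 3) or (ci == 3 and cj == 0):
            if has_cl:
                b = i if ci == 0 else j
                c = lam_c[hap_bead[b]]
                if c != 0.0 and r < rcut_contact:
                    f, df = _contact_pair(r, rc, eta, fshift, rcut_contact)
                    energies[4] += c * f
                    dEdr += c * df
        elif (ci == 0 and cj == 2) or (ci == 2 and cj == 0):
            if has_cs:
                b, sp = (i, j) if ci == 0 else (j, i)
                if state[sp] == 1:       # dP particles only
                    c = spk_c[hap_bead[b]]
                    if c != 0.0 and r < rcut_contact:
                        f, df = _contact_pair(r, rc, eta, fshift,
                                              rcut_contact)
                        energies[5] += c * f
                        dEdr += c * df
        elif (ci == 0 and cj == 1) or (ci == 1 and cj == 0):
            if has_cn:
                b = i if ci == 0 else j
                c = nuc_c[hap_bead[b]]
                if c != 0.0 and r < rcut_contact:
                    f, df = _contact_pair(r, rc, eta, fshift, rcut_contact)
                    energies[6] += c * f
                    dEdr += c * df

        if dEdr != 0.0 and r > 1e-12:
            g = dEdr / r
            fx, fy, fz = -g * dx, -g * dy, -g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz


@njit(cache=True)
def _speckle_flip_delta(pos, p, cat, state, hap_bead, spk_c,
                        rc, eta, fshift, rcut_contact, has_cs,
                        lj_eps_ss, lj_eps_rep, lj_sigma, lj_cut,
                        lj_shift_att_ss, wca_cut):
    """Energy change of flipping speckle ``p`` between P and dP."""
    cap = _LJ_CAP_FACTOR * lj_sigma
    old = state[p]
    new = 1 - old
    de = 0.0
    for j in range(pos.shape[0]):
        if j == p:
            continue
        dx = pos[p, 0] - pos[j, 0]
        dy = pos[p, 1] - pos[j, 1]
        dz = pos[p, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if cat[j] == 2:
            if r >= lj_cut and r >= wca_cut:
                continue
            if old == 1 and state[j] == 1:
                e_old, _ = _lj_pair(r, lj_eps_ss, lj_sigma, lj_cut,
                                    lj_shift_att_ss, cap)
            else:
                e_old, _ = _lj_pair(r, lj_eps_rep, lj_sigma, wca_cut,
                                    -lj_eps_rep, cap)
            if new == 1 and state[j] == 1:
                e_new, _ = _lj_pair(r, lj_eps_ss, lj_sigma, lj_cut,
                                    lj_shift_att_ss, cap)
            else:
                e_new, _ = _lj_pair(r, lj_eps_rep, lj_sigma, wca_cut,
                                    -lj_eps_rep, cap)
            de += e_new - e_old
        elif cat[j] == 0 and has_cs and r < rcut_contact:
            c = spk_c[hap_bead[j]]
            if c != 0.0:
                f, _ = _contact_pair(r, rc, eta, fshift, rcut_contact)
                if new == 1:
                    de += c * f
                else:
                    de -= c * f
    return de


# ---------------------------------------------------------------------------
# force field facade


class ForceField:
    """Packs a topology + parameter set into kernel-ready arrays."""

    def __init__(self, topology: NucleusTopology,
                 params: ForceFieldParameters,
                 frozen_lamina: bool = True,
                 deformation_k: float = 0.0):
        self.topology = topology
        self.params = params
        self.deformation_k = float(deformation_k)
        n = topology.n_particles
        ann = topology.annotation

        self.cat = topology.categories.astype(np.int8)
        self.chain = topology.chain_id.astype(np.int32)
        self.comp = topology.compartments.astype(np.int8)
        self.wci = np.zeros(n, dtype=np.int64)
        self.hap_chrom = np.zeros(n, dtype=np.int32)
        self.hap_bead = np.zeros(n, dtype=np.int64)
        if ann is not None:
            nc = ann.n_beads
            self.wci[:nc] = ann.within_chain_index
            self.hap_chrom[:nc] = ann.haploid_index[ann.chain_of_bead]
            self.hap_bead[:nc] = ann.bead_haploid_id
            for arr, name in ((params.lamina_coupling, "lamina_coupling"),
                              (params.speckle_coupling, "speckle_coupling"),
                              (params.nucleolus_coupling, "nucleolus_coupling")):
                if arr.size not in (0, ann.n_haploid_beads):
                    raise ValueError(f"{name} has wrong length")
            if params.chrom_pair.shape[0] < ann.n_haploid:
                raise ValueError("chrom_pair matrix smaller than genome")

        def _full(arr):
            if ann is None or arr.size == 0:
                return np.zeros(max(1, 0 if ann is None else ann.n_haploid_beads))
            return np.asarray(arr, dtype=float)

        self.lam_c = _full(params.lamina_coupling)
        self.spk_c = _full(params.speckle_coupling)
        self.nuc_c = _full(params.nucleolus_coupling)

        self.frozen = np.zeros(n, dtype=bool)
        if frozen_lamina:
            self.frozen[self.cat == LAMINA] = True

        # bonds
        self.bond_i = topology.bonds[:, 0].astype(np.int64)
        self.bond_j = topology.bonds[:, 1].astype(np.int64)
        self.bond_k_arr = np.where(topology.bond_kinds == 0,
                                   params.bond_k, params.lamina_bond_k)
        self.bond_r0 = np.where(np.isnan(topology.bond_rest_lengths),
                                params.bond_r0, topology.bond_rest_lengths)

        # flags: which coupling families are active at all
        self.has_cc = bool(np.any(params.alpha_ideal) or
                           np.any(params.alpha_comp) or
                           np.any(params.chrom_pair))
        self.has_cl = bool(np.any(self.lam_c)) and np.any(self.cat == LAMINA)
        self.has_cs = bool(np.any(self.spk_c)) and np.any(self.cat == SPECKLE)
        self.has_cn = bool(np.any(self.nuc_c)) and np.any(self.cat == NUCLEOLUS)

        c = params.contact
        self._contact_args = (c.r_c, c.eta, float(c.shift), c.cutoff)
        eps = params
        sig = params.lj_sigma
        self.wca_cut = 2.0 ** (1.0 / 6.0) * sig
        x6 = (sig / params.lj_cutoff) ** 6
        self.lj_shift_nn = 4.0 * eps.lj_eps_nucleolus * (x6 * x6 - x6)
        self.lj_shift_ss = 4.0 * eps.lj_eps_speckle * (x6 * x6 - x6)

        r_candidates = [float(np.max(params.diameters))]
        if np.any(self.cat == NUCLEOLUS) or np.any(self.cat == SPECKLE):
            r_candidates.append(params.lj_cutoff)
        if self.has_cc or self.has_cl or self.has_cs or self.has_cn:
            r_candidates.append(c.cutoff)
        self.r_max = max(r_candidates)

        # largest relevant interaction range per category pair, for pruning
        ev = 0.5 * (params.diameters[:, None] + params.diameters[None, :])
        rcp = ev.copy()
        rcp[NUCLEOLUS, NUCLEOLUS] = max(rcp[NUCLEOLUS, NUCLEOLUS],
                                        params.lj_cutoff)
        rcp[SPECKLE, SPECKLE] = max(rcp[SPECKLE, SPECKLE], params.lj_cutoff)
        if self.has_cc:
            rcp[CHROMATIN, CHROMATIN] = max(rcp[CHROMATIN, CHROMATIN],
                                            c.cutoff)
        for flag, other in ((self.has_cl, LAMINA), (self.has_cs, SPECKLE),
                            (self.has_cn, NUCLEOLUS)):
            if flag:
                rcp[CHROMATIN, other] = rcp[other, CHROMATIN] = max(
                    rcp[CHROMATIN, other], c.cutoff)
        self._rcut_pair = rcp

        self.conf_radius = params.confinement_radius
        if self.conf_radius is None and topology.lamina_mesh is not None:
            self.conf_radius = topology.lamina_mesh.radius - 0.1

    # -- pair list ----------------------------------------------------------

    def build_pairs(self, positions: np.ndarray, skin: float = 0.0,
                    prune: bool = False,
                    skip_frozen: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Candidate interaction pairs within range (plus ``skin``).

        With ``prune`` each pair is kept only within the largest cutoff
        relevant to its category pair (pairs beyond it contribute
        exactly zero); ``skip_frozen`` drops pairs of two frozen
        particles, whose mutual forces never enter the dynamics.
        """
        contact_active = (self.has_cc or self.has_cl or self.has_cs
                          or self.has_cn)
        ev_max = float(np.max(self.params.diameters))
        if prune and not contact_active and self.params.lj_cutoff > ev_max:
            # fast path: short-range query for everything, a body-only
            # query for the longer LJ range
            tree = cKDTree(positions)
            short = tree.query_pairs(ev_max + skin,
                                     output_type="ndarray").reshape(-1, 2)
            is_body = (self.cat == NUCLEOLUS) | (self.cat == SPECKLE)
            # body-body pairs come exclusively from the dedicated query
            short = short[~(is_body[short[:, 0]] & is_body[short[:, 1]])]
            parts = [short]
            body = np.flatnonzero(is_body)
            if body.size:
                bt = cKDTree(positions[body])
                bp = bt.query_pairs(self.params.lj_cutoff + skin,
                                    output_type="ndarray").reshape(-1, 2)
                parts.append(body[bp])
            pairs = np.concatenate(parts)
        else:
            tree = cKDTree(positions)
            pairs = tree.query_pairs(self.r_max + skin,
                                     output_type="ndarray")
        if pairs.size == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        i, j = pairs[:, 0], pairs[:, 1]
        keep = np.ones(len(i), dtype=bool)
        if skip_frozen:
            keep &= ~(self.frozen[i] & self.frozen[j])
        if prune:
            thr = self._rcut_pair[self.cat[i], self.cat[j]] + skin
            d2 = np.sum((positions[i] - positions[j]) ** 2, axis=1)
            keep &= d2 < thr * thr
        i, j = i[keep], j[keep]
        return (np.ascontiguousarray(i.astype(np.int64)),
                np.ascontiguousarray(j.astype(np.int64)))

    # -- evaluation ---------------------------------------------------------

    def energy_forces(self, positions: np.ndarray,
                      speckle_states: np.ndarray | None = None,
                      pairs: tuple[np.ndarray, np.ndarray] | None = None,
                      return_components: bool = False):
        """Total potential energy and per-particle forces.

        Forces are the exact negative gradient of the returned energy;
        frozen particles still receive their forces (the integrator is
        what pins them).
        """
        p = self.params
        n = len(positions)
        state = np.zeros(n, dtype=np.int8)
        if speckle_states is not None and len(speckle_states):
            state[self.cat == SPECKLE] = np.asarray(speckle_states,
                                                    dtype=np.int8)
        forces = np.zeros((n, 3))
        energies = np.zeros(8)
        if pairs is None:
            pairs = self.build_pairs(positions)
        pi, pj = pairs
        rc, eta, fshift, rcut = self._contact_args
        e_bb = _bond_kernel(positions,
                            self.bond_i[self.topology.bond_kinds == 0],
                            self.bond_j[self.topology.bond_kinds == 0],
                            self.bond_k_arr[self.topology.bond_kinds == 0],
                            self.bond_r0[self.topology.bond_kinds == 0],
                            forces)
        e_lam = _bond_kernel(positions,
                             self.bond_i[self.topology.bond_kinds == 1],
                             self.bond_j[self.topology.bond_kinds == 1],
                             self.bond_k_arr[self.topology.bond_kinds == 1],
                             self.bond_r0[self.topology.bond_kinds == 1],
                             forces)
        if pi.size:
            _pair_kernel(positions, pi, pj, self.cat, self.chain, self.comp,
                         self.wci, self.hap_chrom, self.hap_bead, state,
                         p.alpha_ideal, p.alpha_comp, p.chrom_pair,
                         self.lam_c, self.spk_c, self.nuc_c,
                         rc, eta, fshift, rcut,
                         p.excluded_volume_k, p.diameters,
                         p.lj_eps_nucleolus, p.lj_eps_speckle,
                         p.lj_eps_repulsive, p.lj_sigma, p.lj_cutoff,
                         self.lj_shift_nn, self.lj_shift_ss, self.wca_cut,
                         self.has_cc, self.has_cl, self.has_cs, self.has_cn,
                         self._rcut_pair ** 2, forces, energies)

        e_conf = 0.0
        if self.conf_radius is not None and p.confinement_k > 0:
            mobile = self.cat != LAMINA
            r = np.linalg.norm(positions[mobile], axis=1)
            over = r - self.conf_radius
            mask = over > 0
            if np.any(mask):
                e_conf = 0.5 * p.confinement_k * float(np.sum(over[mask] ** 2))
                g = np.zeros_like(r)
                g[mask] = p.confinement_k * over[mask] / np.maximum(r[mask],
                                                                    1e-12)
                forces[mobile] -= g[:, None] * positions[mobile]

        e_def = 0.0
        if self.deformation_k > 0:
            lam = self.cat == LAMINA
            z = positions[lam, 2]
            e_def = 0.5 * self.deformation_k * float(np.sum(z * z))
            forces[lam, 2] -= self.deformation_k * z

        comps = {
            "bond_backbone": e_bb, "bond_lamina": e_lam,
            "excluded_volume": energies[0], "ideal": energies[1],
            "compartment": energies[2], "chrom_pair": energies[3],
            "lamina_coupling": energies[4], "speckle_coupling": energies[5],
            "nucleolus_coupling": energies[6], "lj_body": energies[7],
            "confinement": e_conf, "deformation": e_def,
        }
        total = float(sum(comps.values()))
        if not np.isfinite(total):
            bad = np.flatnonzero(~np.isfinite(forces).all(axis=1))
            if bad.size == 0:
                bad = np.flatnonzero(~np.isfinite(positions).all(axis=1))
            where = f" (particle {int(bad[0])})" if bad.size else ""
            raise FloatingPointError("non-finite energy encountered" + where)
        if return_components:
            return total, forces, comps
        return total, forces

    def speckle_flip_delta(self, positions: np.ndarray, state: np.ndarray,
                           particle: int) -> float:
        """Energy change of flipping the chemical state of one speckle."""
        p = self.params
        rc, eta, fshift, rcut = self._contact_args
        return float(_speckle_flip_delta(
            positions, particle, self.cat, state, self.hap_bead, self.spk_c,
            rc, eta, fshift, rcut, self.has_cs,
            p.lj_eps_speckle, p.lj_eps_repulsive, p.lj_sigma, p.lj_cutoff,
            self.lj_shift_ss, self.wca_cut))


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def contact_indicator(distance, contact: ContactFunction | None = None):
    """Smooth probability-like contact weight in (0, 1); 1/2 at r_c."""
    c = contact or ContactFunction()
    return c.value(distance)


def chromatin_pair_energy(r: float, params: ForceFieldParameters,
                          separation: int | None = None,
                          comp_i: int = 0, comp_j: int = 0,
                          hap_i: int = 0, hap_j: int = 0) -> float:
    """Coupling energy of one chromatin pair (no excluded volume).

    ``separation`` given means an intra-chain pair (ideal + compartment);
    ``None`` means an inter-chain pair (compartment + chromosome-pair).
    """
    f = float(params.contact.truncated(r))
    if separation is not None:
        s = min(abs(int(separation)), len(params.alpha_ideal) - 1)
        if abs(int(separation)) <= 1:
            return 0.0
        return (params.alpha_ideal[s] + params.alpha_comp[comp_i, comp_j]) * f
    return (params.alpha_comp[comp_i, comp_j]
            + params.chrom_pair[hap_i, hap_j]) * f


def body_pair_energy(r: float, params: ForceFieldParameters,
                     cat_i: int, cat_j: int,
                     state_i: int = STATE_DP, state_j: int = STATE_DP) -> float:
    """Condensation energy of one body pair (LJ or repulsive branch)."""
    cap = _LJ_CAP_FACTOR * params.lj_sigma
    sig = params.lj_sigma
    x6 = (sig / params.lj_cutoff) ** 6
    wca_cut = 2.0 ** (1.0 / 6.0) * sig
    if cat_i == NUCLEOLUS and cat_j == NUCLEOLUS:
        shift = 4.0 * params.lj_eps_nucleolus * (x6 * x6 - x6)
        e, _ = _lj_pair(float(r), params.lj_eps_nucleolus, sig,
                        params.lj_cutoff, shift, cap)
        return e
    if cat_i == SPECKLE and cat_j == SPECKLE and state_i == STATE_DP \
            and state_j == STATE_DP:
        shift = 4.0 * params.lj_eps_speckle * (x6 * x6 - x6)
        e, _ = _lj_pair(float(r), params.lj_eps_speckle, sig,
                        params.lj_cutoff, shift, cap)
        return e
    e, _ = _lj_pair(float(r), params.lj_eps_repulsive, sig, wca_cut,
                    -params.lj_eps_repulsive, cap)
    return e


def landmark_coupling_energy(r: float, coupling: float,
                             contact: ContactFunction | None = None,
                             dp_state: int = STATE_DP) -> float:
    """Per-bead landmark coupling energy (dP-gated for speckles)."""
    c = contact or ContactFunction()
    if dp_state != STATE_DP:
        return 0.0
    return float(coupling * c.truncated(r))


def total_energy_forces(configuration: Configuration,
                        topology: NucleusTopology,
                        params: ForceFieldParameters,
                        frozen_lamina: bool = True,
                        deformation_k: float = 0.0,
                        return_components: bool = False):
    """One-shot energy/force evaluation for a configuration."""
    ff = ForceField(topology, params, frozen_lamina=frozen_lamina,
                    deformation_k=deformation_k)
    return ff.energy_forces(configuration.positions,
                            configuration.speckle_states,
                            return_components=return_components)
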