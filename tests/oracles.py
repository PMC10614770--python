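"""Independent brute-force reference implementations.

Deliberately naive (double loops, no neighbour lists, no shared kernel
code with the package) so they can serve as oracles for the optimized
paths.  The only shared ingredient is the elementary contact/LJ formula,
restated here from its definition.
"""

from __future__ import annotations

import numpy as np


def contact_f(r, r_c, eta, pad):
    """Shifted-truncated tanh contact indicator, restated."""
    cutoff = r_c + pad / eta
    shift = 0.5 * (1.0 + np.tanh(-pad))
    if r >= cutoff:
        return 0.0
    return max(0.5 * (1.0 + np.tanh(eta * (r_c - r))) - shift, 0.0)


def lj_energy(r, eps, sigma, cutoff, shift, cap):
    if r >= cutoff:
        return 0.0
    rr = max(r, cap)
    x6 = (sigma / rr) ** 6
    e = 4.0 * eps * (x6 * x6 - x6) - shift
    if r < cap:
        de = -4.0 * eps * (12.0 * x6 * x6 - 6.0 * x6) / rr
        e += de * (r - cap)
    return e


def naive_total_energy(positions, topology, params, speckle_states):
    """All-pairs re-summation of every energy term; returns a dict."""
    from nucsim.genome_model import CHROMATIN, NUCLEOLUS, SPECKLE, LAMINA

    ann = topology.annotation
    n = len(positions)
    cat = topology.categories
    chain = topology.chain_id
    comp = topology.compartments
    wci = np.zeros(n, dtype=int)
    hapc = np.zeros(n, dtype=int)
    hapb = np.zeros(n, dtype=int)
    if ann is not None:
        wci[:ann.n_beads] = ann.within_chain_index
        hapc[:ann.n_beads] = ann.haploid_index[ann.chain_of_bead]
        hapb[:ann.n_beads] = ann.bead_haploid_id
    state = np.zeros(n, dtype=int)
    sp = np.flatnonzero(cat == SPECKLE)
    state[sp] = speckle_states

    c = params.contact
    rc, eta, pad = c.r_c, c.eta, c.cutoff_pad
    sig = params.lj_sigma
    lj_cut = params.lj_cutoff
    cap = 0.7 * sig
    x6c = (sig / lj_cut) ** 6
    shift_nn = 4.0 * params.lj_eps_nucleolus * (x6c * x6c - x6c)
    shift_ss = 4.0 * params.lj_eps_speckle * (x6c * x6c - x6c)
    wca_cut = 2.0 ** (1.0 / 6.0) * sig

    E = {k: 0.0 for k in ("bond_backbone", "bond_lamina", "excluded_volume",
                          "ideal", "compartment", "chrom_pair",
                          "lamina_coupling", "speckle_coupling",
                          "nucleolus_coupling", "lj_body", "confinement",
                          "deformation")}

    for b in range(len(topology.bonds)):
        i, j = topology.bonds[b]
        r = np.linalg.norm(positions[i] - positions[j])
        if topology.bond_kinds[b] == 0:
            E["bond_backbone"] += 0.5 * params.bond_k * (r - params.bond_r0) ** 2
        else:
            r0 = topology.bond_rest_lengths[b]
            E["bond_lamina"] += 0.5 * params.lamina_bond_k * (r - r0) ** 2

    s_last = len(params.alpha_ideal) - 1
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(positions[i] - positions[j])
            ci, cj = cat[i], cat[j]
            if ci == NUCLEOLUS and cj == NUCLEOLUS:
                E["lj_body"] += lj_energy(r, params.lj_eps_nucleolus, sig,
                                          lj_cut, shift_nn, cap)
                continue
            if ci == SPECKLE and cj == SPECKLE:
                if state[i] == 1 and state[j] == 1:
                    E["lj_body"] += lj_energy(r, params.lj_eps_speckle, sig,
                                              lj_cut, shift_ss, cap)
                else:
                    E["lj_body"] += lj_energy(r, params.lj_eps_repulsive,
                                              sig, wca_cut,
                                              -params.lj_eps_repulsive, cap)
                continue
            d = 0.5 * (params.diameters[ci] + params.diameters[cj])
            bonded = (ci == CHROMATIN and cj == CHROMATIN
                      and chain[i] == chain[j]
                      and abs(wci[i] - wci[j]) == 1)
            if r < d and not bonded:
                E["excluded_volume"] += 0.5 * params.excluded_volume_k \
                    * (d - r) ** 2
            f = contact_f(r, rc, eta, pad)
            if ci == CHROMATIN and cj == CHROMATIN:
                if chain[i] == chain[j]:
                    s = abs(wci[i] - wci[j])
                    if s >= 2:
                        E["ideal"] += params.alpha_ideal[min(s, s_last)] * f
                        E["compartment"] += params.alpha_comp[comp[i],
                                                              comp[j]] * f
                else:
                    E["compartment"] += params.alpha_comp[comp[i], comp[j]] * f
                    E["chrom_pair"] += params.chrom_pair[hapc[i], hapc[j]] * f
            elif {ci, cj} == {CHROMATIN, LAMINA}:
                b = i if ci == CHROMATIN else j
                if params.lamina_coupling.size:
                    E["lamina_coupling"] += params.lamina_coupling[hapb[b]] * f
            elif {ci, cj} == {CHROMATIN, SPECKLE}:
                b, spk = (i, j) if ci == CHROMATIN else (j, i)
                if state[spk] == 1 and params.speckle_coupling.size:
                    E["speckle_coupling"] += params.speckle_coupling[hapb[b]] * f
            elif {ci, cj} == {CHROMATIN, NUCLEOLUS}:
                b = i if ci == CHROMATIN else j
                if params.nucleolus_coupling.size:
                    E["nucleolus_coupling"] += params.nucleolus_coupling[hapb[b]] * f

    r_conf = params.confinement_radius
    if r_conf is None and topology.lamina_mesh is not None:
        r_conf = topology.lamina_mesh.radius - 0.1
    if r_conf is not None and params.confinement_k > 0:
        for i in range(n):
            if cat[i] != LAMINA:
                over = np.linalg.norm(positions[i]) - r_conf
                if over > 0:
                    E["confinement"] += 0.5 * params.confinement_k * over ** 2
    return E


def naive_contact_map(traj_positions, n_chrom, contact):
    """Frame-averaged all-pairs contact matrix."""
    F = len(traj_positions)
    out = np.zeros((n_chrom, n_chrom))
    for f in range(F):
        pos = traj_positions[f]
        for i in range(n_chrom):
            out[i, i] += float(contact.truncated(0.0))
            for j in range(i + 1, n_chrom):
                v = float(contact.truncated(
                    np.linalg.norm(pos[i] - pos[j])))
                out[i, j] += v
                out[j, i] += v
    return out / F


def naive_profile(traj_positions, landmark_sets, n_chrom, contact):
    """Soft-OR landmark contact frequency, frame-averaged.

    ``landmark_sets`` is one array of landmark indices per frame."""
    F = len(traj_positions)
    out = np.zeros(n_chrom)
    for f in range(F):
        pos = traj_positions[f]
        for b in range(n_chrom):
            miss = 1.0
            for j in landmark_sets[f]:
                miss *= 1.0 - float(contact.truncated(
                    np.linalg.norm(pos[b] - pos[j])))
            out[b] += 1.0 - miss
    return out / F


def naive_constraints(traj_positions, traj_states, topology, contact,
                      s_max):
    """Full re-derivation of the five constraint blocks."""
    from nucsim.genome_model import LAMINA, SPECKLE

    ann = topology.annotation
    nc = ann.n_beads
    chain = ann.chain_of_bead
    wci = ann.within_chain_index
    comp = ann.compartments
    hapc = ann.haploid_index[chain]
    F = len(traj_positions)
    n_hap = ann.n_haploid

    sum_ideal = np.zeros(s_max + 1)
    cnt_ideal = np.zeros(s_max + 1)
    sum_comp = np.zeros((3, 3))
    cnt_comp = np.zeros((3, 3))
    sum_cp = np.zeros((n_hap, n_hap))
    cnt_cp = np.zeros((n_hap, n_hap))
    for f in range(F):
        pos = traj_positions[f]
        for i in range(nc):
            for j in range(i + 1, nc):
                v = float(contact.truncated(np.linalg.norm(pos[i] - pos[j])))
                if chain[i] == chain[j]:
                    s = abs(int(wci[i]) - int(wci[j]))
                    if s >= 2:
                        s = min(s, s_max)
                        sum_ideal[s] += v
                        cnt_ideal[s] += 1
                        a, b = sorted((comp[i], comp[j]))
                        sum_comp[a, b] += v
                        cnt_comp[a, b] += 1
                else:
                    a, b = sorted((comp[i], comp[j]))
                    sum_comp[a, b] += v
                    cnt_comp[a, b] += 1
                    a, b = sorted((hapc[i], hapc[j]))
                    sum_cp[a, b] += v
                    cnt_cp[a, b] += 1
    ideal = np.where(cnt_ideal > 0, sum_ideal / np.maximum(cnt_ideal, 1), 0)
    compartment = np.where(cnt_comp > 0, sum_comp / np.maximum(cnt_comp, 1), 0)
    compartment = np.triu(compartment) + np.triu(compartment, 1).T
    cpair = np.where(cnt_cp > 0, sum_cp / np.maximum(cnt_cp, 1), 0)
    cpair = np.triu(cpair) + np.triu(cpair, 1).T

    lam = np.flatnonzero(topology.categories == LAMINA)
    spk = np.flatnonzero(topology.categories == SPECKLE)
    damid_d = naive_profile(traj_positions, [lam] * F, nc, contact)
    tsa_d = naive_profile(traj_positions,
                          [spk[traj_states[f] == 1] for f in range(F)],
                          nc, contact)
    hapb = ann.bead_haploid_id
    nhb = ann.n_haploid_beads
    damid = np.zeros(nhb)
    tsa = np.zeros(nhb)
    copies = np.zeros(nhb)
    for b in range(nc):
        damid[hapb[b]] += damid_d[b]
        tsa[hapb[b]] += tsa_d[b]
        copies[hapb[b]] += 1
    return {"ideal": ideal, "compartment": compartment, "chrom_pair": cpair,
            "damid": damid / copies, "tsaseq": tsa / copies}


def naive_clusters(points, cutoff, min_size):
    """Union-find single-linkage cluster count."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    roots = [find(i) for i in range(n)]
    sizes = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    return sum(1 for s in sizes.values() if s >= min_size)


def naive_pearson_matrix(vectors):
    k = len(vectors)
    out = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            x, y = vectors[a], vectors[b]
            xm, ym = x - x.mean(), y - y.mean()
            out[a, b] = (xm * ym).sum() / np.sqrt((xm * xm).sum()
                                                  * (ym * ym).sum())
    return out


def naive_rebin(starts, values, native_res, target_res):
    """Group-mean rebinning of one chromosome, NaN-aware."""
    out = {}
    for s, v in zip(starts, values):
        b = s // target_res
        out.setdefault(b, []).append(v)
    result = {}
    for b, vals in out.items():
        vals = [v for v in vals if not np.isnan(v)]
        result[b] = np.mean(vals) if vals else np.nan
    return result
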