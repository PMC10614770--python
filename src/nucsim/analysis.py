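"""Observables computed from simulated trajectories.

Contact-based observables use the same smooth (shifted-truncated)
contact indicator as the force field, so that simulation and analysis
share one definition of "contact".  Profiles against nuclear landmarks
mimic the sequencing assays: the DamID-like signal is the per-bead
probability of touching at least one lamina particle, the TSA-Seq-like
signal the probability of touching at least one dP speckle particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .dynamics import Trajectory
from .forcefield import ContactFunction
from .genome_model import (LAMINA, SPECKLE, Configuration,
                           NucleusTopology, UnitSystem, DEFAULT_UNITS)
from .maxent import _landmark_profile


# ---------------------------------------------------------------------------
# contact maps


@dataclass
class ContactMap:
    """Frame-averaged pairwise contact probabilities of chromatin beads."""

    matrix: np.ndarray
    haploid: bool
    n_frames: int
    normalization: str = "contact_indicator"

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@njit(cache=True)
def _contact_map_kernel(pos, n_chrom, rc, eta, fshift, rcut, out):
    for i in range(n_chrom):
        out[i, i] += 0.5 * (1.0 + np.tanh(eta * rc)) - fshift
        for j in range(i + 1, n_chrom):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rcut:
                e = np.exp(-2.0 * eta * (rc - r))
                t = (1.0 - e) / (1.0 + e)
                f = 0.5 * (1.0 + t) - fshift
                if f > 0.0:
                    out[i, j] += f
                    out[j, i] += f


def compute_contact_map(trajectory: Trajectory,
                        topology: NucleusTopology,
                        contact: ContactFunction | None = None,
                        homolog_average: bool = False,
                        discard_steps: int = 0) -> ContactMap:
    """Frame-averaged chromatin contact map (optionally homolog-collapsed).

    Homolog averaging maps each diploid bead onto its haploid bin and
    averages the contact over all copy-pair combinations.
    """
    ann = topology.annotation
    if ann is None:
        raise ValueError("contact map needs a genome annotation")
    contact = contact or ContactFunction()
    traj = trajectory.after_discard(discard_steps)
    if traj.n_frames == 0:
        raise ValueError("no frames left after discard")
    n = ann.n_beads
    acc = np.zeros((n, n))
    for fidx in range(traj.n_frames):
        _contact_map_kernel(traj.positions[fidx], n, contact.r_c,
                            contact.eta, float(contact.shift),
                            contact.cutoff, acc)
    acc /= traj.n_frames
    if not homolog_average:
        return ContactMap(acc, haploid=False, n_frames=traj.n_frames)
    hap = ann.bead_haploid_id
    nh = ann.n_haploid_beads
    sums = np.zeros((nh, nh))
    counts = np.zeros((nh, nh))
    np.add.at(sums, (hap[:, None].repeat(n, 1), hap[None, :].repeat(n, 0)),
              acc)
    np.add.at(counts, (hap[:, None].repeat(n, 1), hap[None, :].repeat(n, 0)),
              1.0)
    return ContactMap(sums / np.maximum(counts, 1.0), haploid=True,
                      n_frames=traj.n_frames)


def homolog_average_map(cmap: ContactMap,
                        topology: NucleusTopology) -> ContactMap:
    """Collapse a diploid map onto haploid bins (idempotent on haploid)."""
    if cmap.haploid:
        return ContactMap(cmap.matrix.copy(), True, cmap.n_frames,
                          cmap.normalization)
    ann = topology.annotation
    hap = ann.bead_haploid_id
    n = ann.n_beads
    nh = ann.n_haploid_beads
    sums = np.zeros((nh, nh))
    counts = np.zeros((nh, nh))
    np.add.at(sums, (hap[:, None].repeat(n, 1), hap[None, :].repeat(n, 0)),
              cmap.matrix)
    np.add.at(counts, (hap[:, None].repeat(n, 1), hap[None, :].repeat(n, 0)),
              1.0)
    return ContactMap(sums / np.maximum(counts, 1.0), True, cmap.n_frames,
                      cmap.normalization)


def contact_scaling(cmap: ContactMap, topology: NucleusTopology,
                    log_bins: bool = False) -> pd.DataFrame:
    """Mean intra-chromosomal contact versus genomic separation.

    Averages over all intra-chain bead pairs at each separation; with
    ``log_bins`` the separations are pooled into logarithmic bins.
    """
    ann = topology.annotation
    if cmap.haploid:
        lengths = ann.haploid_beads_per_chrom
        offsets = ann.haploid_offsets
    else:
        lengths = ann.beads_per_chain
        offsets = ann.chain_offsets
    smax = int(lengths.max()) - 1
    sums = np.zeros(smax + 1)
    counts = np.zeros(smax + 1)
    for o, m in zip(offsets, lengths):
        block = cmap.matrix[o:o + m, o:o + m]
        for s in range(1, m):
            sums[s] += np.trace(block, offset=s)
            counts[s] += m - s
    valid = counts > 0
    s_vals = np.arange(smax + 1)[valid][1:]
    mean = (sums[valid] / counts[valid])[1:]
    df = pd.DataFrame({"separation": s_vals, "mean_contact": mean})
    if log_bins:
        edges = np.unique(np.geomspace(1, max(s_vals.max(), 2), 30).astype(int))
        idx = np.digitize(df["separation"], edges)
        df = df.groupby(idx).agg(
            separation=("separation", "mean"),
            mean_contact=("mean_contact", "mean")).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# linear profiles


@dataclass
class LinearProfile:
    """Per-haploid-bin landmark-contact signal (DamID- or TSA-like)."""

    values: np.ndarray
    kind: str                      # "damid" | "tsaseq"
    resolution: int = 100_000
    normalization: str = "raw"

    def zscored(self) -> "LinearProfile":
        v = self.values
        sd = np.std(v)
        z = (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)
        return LinearProfile(z, self.kind, self.resolution, "zscore")


def insilico_profile(trajectory: Trajectory, topology: NucleusTopology,
                     kind: str, contact: ContactFunction | None = None,
                     discard_steps: int = 0) -> LinearProfile:
    """In-silico DamID (lamina) or TSA-Seq (dP speckles) profile."""
    ann = topology.annotation
    if ann is None:
        raise ValueError("profiles need a genome annotation")
    if kind == "damid":
        land = topology.indices(LAMINA).astype(np.int64)
    elif kind == "tsaseq":
        land = topology.indices(SPECKLE).astype(np.int64)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if land.size == 0:
        raise ValueError(f"topology has no particles for kind {kind!r}")
    contact = contact or ContactFunction()
    traj = trajectory.after_discard(discard_steps)
    if traj.n_frames == 0:
        raise ValueError("no frames left after discard")
    n = ann.n_beads
    bead_idx = np.arange(n, dtype=np.int64)
    acc = np.zeros(n)
    for fidx in range(traj.n_frames):
        if kind == "tsaseq":
            sel = land[traj.speckle_states[fidx] == 1]
            if sel.size == 0:
                continue
        else:
            sel = land
        _landmark_profile(traj.positions[fidx], bead_idx, sel, contact.r_c,
                          contact.eta, float(contact.shift), contact.cutoff,
                          acc)
    acc /= traj.n_frames
    hap = ann.bead_haploid_id
    out = np.zeros(ann.n_haploid_beads)
    copies = np.zeros(ann.n_haploid_beads)
    np.add.at(out, hap, acc)
    np.add.at(copies, hap, 1.0)
    return LinearProfile(out / np.maximum(copies, 1.0), kind)


# ---------------------------------------------------------------------------
# mean-squared displacement


@dataclass
class MSDResult:
    """Time-origin-averaged MSD with a power-law fit MSD = D_a * t^alpha."""

    lag_seconds: np.ndarray
    msd_um2: np.ndarray            # pooled over particles
    per_particle: np.ndarray       # (n_particles, n_lags)
    alpha: float | None = None
    d_alpha: float | None = None   # um^2 s^-alpha
    fit_window: tuple[float, float] | None = None


def compute_msd(trajectory: Trajectory, particle_ids,
                units: UnitSystem = DEFAULT_UNITS,
                fit_window: tuple[float, float] = (10.0, 1000.0),
                discard_steps: int = 0) -> MSDResult:
    """Time-origin-averaged MSD of selected particles with power-law fit.

    Lag times are mapped to seconds through the Brownian time unit and
    displacements to micrometres; the anomalous exponent comes from a
    log-log linear fit over ``fit_window`` (in seconds).  The fit is
    only attempted with at least 5 lag points in the window.
    """
    traj = trajectory.after_discard(discard_steps)
    if traj.n_frames < 2:
        raise ValueError("MSD needs at least two frames")
    ids = np.asarray(particle_ids, dtype=int)
    pos = traj.positions[:, ids, :]          # (F, P, 3)
    F = len(pos)
    lags = np.arange(1, F)
    per = np.empty((ids.size, lags.size))
    for li, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        per[:, li] = np.mean(np.sum(d * d, axis=2), axis=0)
    pooled = per.mean(axis=0)
    frame_dt = np.diff(traj.steps)
    if not np.all(frame_dt == frame_dt[0]):
        raise ValueError("MSD needs a uniform recording interval")
    lag_red = lags * frame_dt[0] * traj.dt
    lag_s = units.time_to_seconds(lag_red)
    msd_um2 = pooled * units.length_to_um(1.0) ** 2
    per_um2 = per * units.length_to_um(1.0) ** 2

    res = MSDResult(lag_seconds=lag_s, msd_um2=msd_um2, per_particle=per_um2,
                    fit_window=fit_window)
    sel = (lag_s >= fit_window[0]) & (lag_s <= fit_window[1]) & (msd_um2 > 0)
    if np.sum(sel) >= 5:
        slope, intercept = np.polyfit(np.log(lag_s[sel]),
                                      np.log(msd_um2[sel]), 1)
        res.alpha = float(slope)
        res.d_alpha = float(np.exp(intercept))
    return res


def fit_msd_powerlaw(lag_s: np.ndarray, msd: np.ndarray,
                     window: tuple[float, float]) -> tuple[float, float] | None:
    """(alpha, D_alpha) from a log-log fit, or None with <5 points."""
    sel = (lag_s >= window[0]) & (lag_s <= window[1]) & (msd > 0)
    if np.sum(sel) < 5:
        return None
    slope, intercept = np.polyfit(np.log(lag_s[sel]), np.log(msd[sel]), 1)
    return float(slope), float(np.exp(intercept))


# ---------------------------------------------------------------------------
# chromosome geometry


@dataclass
class ChromosomeGeometry:
    """Per-chain radius of gyration and normalized radial positions."""

    radius_of_gyration_um: np.ndarray       # (n_chains,) trajectory mean
    radial_position: np.ndarray             # (n_chains,) r_COM / R_nucleus
    bead_radial_position: np.ndarray        # (n_beads,)
    per_frame_rg: np.ndarray                # (F, n_chains) reduced units


def chromosome_geometry(trajectory: Trajectory, topology: NucleusTopology,
                        units: UnitSystem = DEFAULT_UNITS,
                        nucleus_radius: float | None = None,
                        discard_steps: int = 0) -> ChromosomeGeometry:
    """Equal-mass R_g per chain and radial positions over the trajectory."""
    ann = topology.annotation
    traj = trajectory.after_discard(discard_steps)
    if nucleus_radius is None:
        nucleus_radius = (topology.lamina_mesh.radius
                          if topology.lamina_mesh is not None
                          else units.nucleus_radius)
    F = traj.n_frames
    nch = ann.n_chains
    rg = np.empty((F, nch))
    rad = np.empty((F, nch))
    offs, lens = ann.chain_offsets, ann.beads_per_chain
    bead_rad = np.zeros(ann.n_beads)
    for f in range(F):
        pos = traj.positions[f]
        for c in range(nch):
            chain = pos[offs[c]:offs[c] + lens[c]]
            com = chain.mean(axis=0)
            rg[f, c] = np.sqrt(np.mean(np.sum((chain - com) ** 2, axis=1)))
            rad[f, c] = np.linalg.norm(com) / nucleus_radius
        bead_rad += np.linalg.norm(pos[:ann.n_beads], axis=1) / nucleus_radius
    return ChromosomeGeometry(
        radius_of_gyration_um=units.length_to_um(rg.mean(axis=0)),
        radial_position=rad.mean(axis=0),
        bead_radial_position=bead_rad / F,
        per_frame_rg=rg)


# ---------------------------------------------------------------------------
# droplet clustering


@dataclass
class ClusterResult:
    labels: np.ndarray             # cluster label per selected particle
    n_clusters: int                # clusters with size >= min_size
    sizes: np.ndarray              # sizes of counted clusters
    centroids: np.ndarray          # (n_clusters, 3)
    particle_indices: np.ndarray   # global indices of selected particles


def cluster_droplets(configuration: Configuration,
                     topology: NucleusTopology,
                     category: int,
                     cutoff: float,
                     state_filter: int | None = None,
                     min_size: int = 2) -> ClusterResult:
    """Single-linkage droplet detection under a distance cutoff.

    Particles of ``category`` (optionally restricted to one speckle
    chemical state) are linked when closer than ``cutoff``; connected
    components of size >= ``min_size`` count as droplets.
    """
    idx = topology.indices(category)
    if state_filter is not None and category == SPECKLE:
        idx = idx[configuration.speckle_states == state_filter]
    if idx.size == 0:
        raise ValueError("no particles of the requested category/state")
    pts = configuration.positions[idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(pts)
    if pairs.size:
        adj = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    sizes_all = np.bincount(labels)
    keep = np.flatnonzero(sizes_all >= min_size)
    centroids = np.array([pts[labels == c].mean(axis=0) for c in keep]) \
        if keep.size else np.empty((0, 3))
    return ClusterResult(labels=labels, n_clusters=int(keep.size),
                         sizes=sizes_all[keep], centroids=centroids,
                         particle_indices=idx)


# ---------------------------------------------------------------------------
# ensemble correlations


def ensemble_correlations(items) -> tuple[np.ndarray, float]:
    """Pairwise Pearson matrix over contact maps or profiles.

    Maps contribute their flattened upper triangle (diagonal excluded),
    profiles their full vector.  Returns the correlation matrix and the
    mean of its off-diagonal entries.
    """
    if len(items) < 2:
        raise ValueError("need at least two inputs")
    vectors = []
    for it in items:
        if isinstance(it, ContactMap):
            iu = np.triu_indices(it.n_bins, k=1)
            vectors.append(it.matrix[iu])
        elif isinstance(it, LinearProfile):
            vectors.append(it.values)
        else:
            vectors.append(np.asarray(it, dtype=float).ravel())
    shapes = {v.shape for v in vectors}
    if len(shapes) != 1:
        raise ValueError("inputs have differing shapes")
    mat = np.corrcoef(np.stack(vectors))
    off = mat[~np.eye(len(vectors), dtype=bool)]
    return mat, float(off.mean())


# ---------------------------------------------------------------------------
# exports


def contact_map_to_dense_text(cmap: ContactMap, path) -> None:
    np.savetxt(path, cmap.matrix, fmt="%.8g")


def contact_map_to_sparse_text(cmap: ContactMap, topology: NucleusTopology,
                               path, threshold: float = 0.0) -> None:
    """Sparse bin-pair text: chrom-offset header then `i j value` rows."""
    ann = topology.annotation
    if cmap.haploid:
        names = ann.haploid_names
        lens = ann.haploid_beads_per_chrom
    else:
        names = ann.chain_names
        lens = ann.beads_per_chain
    with open(path, "w") as fh:
        off = 0
        for nm, ln in zip(names, lens):
            fh.write(f"# {nm}\t{off}\t{off + int(ln)}\n")
            off += int(ln)
        iu = np.triu_indices(cmap.n_bins)
        vals = cmap.matrix[iu]
        keep = vals > threshold
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{v:.8g}\n")


def profile_to_bedgraph(profile: LinearProfile, topology: NucleusTopology,
                        path) -> None:
    ann = topology.annotation
    res = profile.resolution
    with open(path, "w") as fh:
        pos = 0
        for h, nm in enumerate(ann.haploid_names):
            ln = int(ann.haploid_beads_per_chrom[h])
            for b in range(ln):
                v = profile.values[pos]
                fh.write(f"{nm}\t{b * res}\t{(b + 1) * res}\t{v:.8g}\n")
                pos += 1


def msd_to_csv(result: MSDResult, path) -> None:
    df = pd.DataFrame({"lag_seconds": result.lag_seconds,
                       "msd_um2": result.msd_um2})
    df.to_csv(path, index=False)


def geometry_to_csv(geom: ChromosomeGeometry, topology: NucleusTopology,
                    path) -> None:
    ann = topology.annotation
    df = pd.DataFrame({"chain": ann.chain_names,
                       "rg_um": geom.radius_of_gyration_um,
                       "radial_position": geom.radial_position})
    df.to_csv(path, index=False)
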