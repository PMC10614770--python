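"""Particle-based representation of the interphase nucleus.

The genome is a diploid set of beads-on-a-string polymers at 100-KB
resolution.  Each bead carries a compartment label (A = euchromatin,
B = heterochromatin, C = pericentromeric).  Nucleoli and speckles are
free coarse-grained particles, and the nuclear envelope is a spherical
mesh of lamina particles bonded to their nearest neighbours.

All geometry lives in reduced units; :class:`UnitSystem` performs the
conversion to physical units (sigma = 385 nm, tau = 0.65 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

# ---------------------------------------------------------------------------
# constants

BIN_SIZE = 100_000  # bp per chromatin bead

# particle categories
CHROMATIN, NUCLEOLUS, SPECKLE, LAMINA = 0, 1, 2, 3
CATEGORY_NAMES = {CHROMATIN: "chromatin", NUCLEOLUS: "nucleolus",
                  SPECKLE: "speckle", LAMINA: "lamina"}

# compartment labels
COMP_A, COMP_B, COMP_C = 0, 1, 2
COMP_NAMES = {COMP_A: "A", COMP_B: "B", COMP_C: "C"}
COMP_CODES = {"A": COMP_A, "B": COMP_B, "C": COMP_C}

# speckle chemical states
STATE_P, STATE_DP = 0, 1

NUCLEUS_RADIUS_UM = 5.0  # 10 um diameter envelope


class PlacementError(RuntimeError):
    """Raised when a random initial configuration cannot be placed."""


# ---------------------------------------------------------------------------
# unit system


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit conversions.

    One reduced length is ``sigma_nm`` nanometres and one reduced time
    (for Brownian dynamics) is ``tau_s`` seconds.  Reduced temperature
    is 1 by convention.
    """

    sigma_nm: float = 385.0
    tau_s: float = 0.65
    temperature: float = 1.0

    def length_to_nm(self, x):
        return np.asarray(x, dtype=float) * self.sigma_nm

    def length_from_nm(self, x):
        return np.asarray(x, dtype=float) / self.sigma_nm

    def length_to_um(self, x):
        return np.asarray(x, dtype=float) * (self.sigma_nm / 1000.0)

    def length_from_um(self, x):
        return np.asarray(x, dtype=float) / (self.sigma_nm / 1000.0)

    def time_to_seconds(self, t):
        return np.asarray(t, dtype=float) * self.tau_s

    def time_from_seconds(self, t):
        return np.asarray(t, dtype=float) / self.tau_s

    @property
    def nucleus_radius(self) -> float:
        """Nuclear radius (5 um) in reduced units."""
        return 1000.0 * NUCLEUS_RADIUS_UM / self.sigma_nm


DEFAULT_UNITS = UnitSystem()


# ---------------------------------------------------------------------------
# genome annotation


@dataclass
class GenomeAnnotation:
    """Chain layout and per-bead compartment labels of the model genome.

    Chains are stored in order; ``haploid_index`` maps every chain to its
    haploid chromosome so that homologous copies can be averaged.
    ``compartments`` concatenates the per-bead labels of all chains.
    """

    chain_names: list[str]
    haploid_names: list[str]
    haploid_index: np.ndarray        # (n_chains,) int
    beads_per_chain: np.ndarray      # (n_chains,) int
    compartments: np.ndarray         # (n_beads,) int8

    def __post_init__(self) -> None:
        self.haploid_index = np.asarray(self.haploid_index, dtype=np.int32)
        self.beads_per_chain = np.asarray(self.beads_per_chain, dtype=np.int64)
        self.compartments = np.asarray(self.compartments, dtype=np.int8)
        if np.any(self.beads_per_chain <= 0):
            raise ValueError("every chain needs at least one bead")
        if self.compartments.size != int(self.beads_per_chain.sum()):
            raise ValueError("compartment vector does not match bead count")
        bad = set(np.unique(self.compartments)) - {COMP_A, COMP_B, COMP_C}
        if bad:
            raise ValueError(f"unknown compartment codes: {sorted(bad)}")
        # homologous chains must agree in length and labels
        for h in range(self.n_haploid):
            chains = np.flatnonzero(self.haploid_index == h)
            if chains.size == 0:
                raise ValueError(f"haploid chromosome {h} has no chain")
            ref = chains[0]
            for c in chains[1:]:
                if self.beads_per_chain[c] != self.beads_per_chain[ref]:
                    raise ValueError(
                        f"homologs of {self.haploid_names[h]} differ in length")
                if not np.array_equal(self.chain_compartments(c),
                                      self.chain_compartments(ref)):
                    raise ValueError(
                        f"homologs of {self.haploid_names[h]} differ in labels")

    # -- derived layout -----------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.beads_per_chain)

    @property
    def n_beads(self) -> int:
        return int(self.beads_per_chain.sum())

    @property
    def n_haploid(self) -> int:
        return int(self.haploid_index.max()) + 1

    @property
    def chain_offsets(self) -> np.ndarray:
        """Start index of each chain in the concatenated bead arrays."""
        return np.concatenate([[0], np.cumsum(self.beads_per_chain)])[:-1]

    @property
    def chain_of_bead(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains, dtype=np.int32),
                         self.beads_per_chain)

    @property
    def within_chain_index(self) -> np.ndarray:
        return (np.arange(self.n_beads, dtype=np.int64)
                - self.chain_offsets[self.chain_of_bead])

    @property
    def haploid_beads_per_chrom(self) -> np.ndarray:
        out = np.zeros(self.n_haploid, dtype=np.int64)
        for c in range(self.n_chains):
            out[self.haploid_index[c]] = self.beads_per_chain[c]
        return out

    @property
    def n_haploid_beads(self) -> int:
        return int(self.haploid_beads_per_chrom.sum())

    @property
    def haploid_offsets(self) -> np.ndarray:
        return np.concatenate([[0],
                               np.cumsum(self.haploid_beads_per_chrom)])[:-1]

    @property
    def bead_haploid_id(self) -> np.ndarray:
        """Flat haploid bead index for every (diploid) bead."""
        hap = self.haploid_index[self.chain_of_bead].astype(np.int64)
        return self.haploid_offsets[hap] + self.within_chain_index

    @property
    def telomere_beads(self) -> np.ndarray:
        """First and last bead of every chain (global indices)."""
        off = self.chain_offsets
        return np.sort(np.concatenate([off, off + self.beads_per_chain - 1]))

    def chain_compartments(self, chain: int) -> np.ndarray:
        o = self.chain_offsets[chain]
        return self.compartments[o:o + self.beads_per_chain[chain]]

    def centromere_ranges(self, chain: int) -> list[tuple[int, int]]:
        """Half-open within-chain bead ranges labelled C."""
        labels = self.chain_compartments(chain)
        ranges, start = [], None
        for i, lab in enumerate(labels):
            if lab == COMP_C and start is None:
                start = i
            elif lab != COMP_C and start is not None:
                ranges.append((start, i))
                start = None
        if start is not None:
            ranges.append((start, len(labels)))
        return ranges

    def haploid_compartments(self) -> np.ndarray:
        """Per-haploid-bead labels (taken from the first copy)."""
        out = np.empty(self.n_haploid_beads, dtype=np.int8)
        seen = set()
        for c in range(self.n_chains):
            h = int(self.haploid_index[c])
            if h in seen:
                continue
            seen.add(h)
            o = self.haploid_offsets[h]
            out[o:o + self.beads_per_chain[c]] = self.chain_compartments(c)
        return out


def build_genome_annotation(
    chrom_lengths: Mapping[str, int] | pd.DataFrame,
    compartment_track: pd.DataFrame | Mapping[str, Sequence[str]],
    diploid: bool = True,
    haploid_chroms: Sequence[str] = ("chrX", "chrY"),
    bin_size: int = BIN_SIZE,
) -> GenomeAnnotation:
    """Bin chromosomes into 100-KB beads and attach compartment labels.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp, or a DataFrame with
        columns ``chrom`` and ``length``.  Order is preserved.
    compartment_track
        Either a BED-like DataFrame (``chrom, start, end, label``) whose
        intervals must cover every bin, or a mapping chromosome ->
        per-bin label sequence.
    diploid
        Duplicate every chromosome except those in ``haploid_chroms``
        (sex chromosomes of a male karyotype keep one copy each).

    Bins follow the 0-based half-open convention: bead ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)`` and a trailing partial bin is kept
    as a full bead (ceiling rule).
    """
    if isinstance(chrom_lengths, pd.DataFrame):
        chrom_lengths = dict(zip(chrom_lengths["chrom"],
                                 chrom_lengths["length"]))
    names = list(chrom_lengths)
    lengths = {c: int(chrom_lengths[c]) for c in names}
    for c, L in lengths.items():
        if L <= 0:
            raise ValueError(f"chromosome {c} has non-positive length {L}")
    n_bins = {c: -(-lengths[c] // bin_size) for c in names}

    labels_per_chrom: dict[str, np.ndarray] = {}
    if isinstance(compartment_track, pd.DataFrame):
        for c in names:
            sub = compartment_track[compartment_track["chrom"] == c]
            labels = np.full(n_bins[c], -1, dtype=np.int8)
            for _, row in sub.iterrows():
                lab = str(row["label"]).strip().upper()
                if lab not in COMP_CODES:
                    raise ValueError(
                        f"unknown compartment label {row['label']!r} on {c}")
                b0 = int(row["start"]) // bin_size
                b1 = -(-int(row["end"]) // bin_size)
                labels[b0:b1] = COMP_CODES[lab]
            missing = np.flatnonzero(labels < 0)
            if missing.size:
                bins = ", ".join(f"{c}:{i * bin_size}-{(i + 1) * bin_size}"
                                 for i in missing[:10])
                raise ValueError(f"compartment track misses bins: {bins}")
            labels_per_chrom[c] = labels
    else:
        for c in names:
            seq = compartment_track.get(c)
            if seq is None or len(seq) < n_bins[c]:
                raise ValueError(f"compartment track misses bins on {c}")
            labels_per_chrom[c] = np.array(
                [COMP_CODES[str(s).upper()] for s in seq[:n_bins[c]]],
                dtype=np.int8)

    chain_names, hap_index, beads, comp_blocks = [], [], [], []
    for h, c in enumerate(names):
        copies = 1 if (diploid and c in haploid_chroms) else (2 if diploid else 1)
        for k in range(copies):
            suffix = "_ab"[k + 1] if copies > 1 else ""
            chain_names.append(c + (f"_{suffix}" if suffix else ""))
            hap_index.append(h)
            beads.append(n_bins[c])
            comp_blocks.append(labels_per_chrom[c])
    return GenomeAnnotation(
        chain_names=chain_names,
        haploid_names=names,
        haploid_index=np.array(hap_index),
        beads_per_chain=np.array(beads),
        compartments=np.concatenate(comp_blocks),
    )


# ---------------------------------------------------------------------------
# lamina mesh


@dataclass
class LaminaMesh:
    """Spherical shell of lamina particles bonded to nearest neighbours."""

    vertices: np.ndarray          # (n, 3)
    edges: np.ndarray             # (m, 2), canonical u < v, unique
    radius: float
    frozen: bool = True
    k_neighbors: int = 6

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edge_rest_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_vertices)

    def is_connected(self) -> bool:
        n = self.n_vertices
        data = np.ones(len(self.edges))
        adj = csr_matrix((data, (self.edges[:, 0], self.edges[:, 1])),
                         shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1


def build_lamina_mesh(radius: float, n_vertices: int,
                      k_neighbors: int = 6) -> LaminaMesh:
    """Quasi-uniform spherical mesh via the deterministic generalized spiral.

    Vertices follow the golden-angle spiral; each vertex is linked to its
    ``k_neighbors`` nearest neighbours and the edge set is symmetrized.
    """
    if radius <= 0:
        raise ValueError("mesh radius must be positive")
    if n_vertices < 12:
        raise ValueError("need at least 12 lamina vertices")
    i = np.arange(n_vertices, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    verts = radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z],
                              axis=1)
    tree = cKDTree(verts)
    _, idx = tree.query(verts, k=k_neighbors + 1)
    u = np.repeat(np.arange(n_vertices), k_neighbors)
    v = idx[:, 1:].ravel()
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    edges = edges[edges[:, 0] != edges[:, 1]]
    mesh = LaminaMesh(vertices=verts, edges=edges.astype(np.int64),
                      radius=float(radius), k_neighbors=k_neighbors)
    if not mesh.is_connected():
        raise ValueError("lamina mesh is not connected; increase k_neighbors")
    return mesh


# ---------------------------------------------------------------------------
# topology


@dataclass
class NucleusTopology:
    """Full particle table: chromatin, nucleoli, speckles, lamina.

    Particles are ordered chromatin first (chain by chain), then
    nucleolus, speckle, and lamina particles.  ``bonds`` holds the
    chromatin backbone followed by the lamina mesh edges.
    """

    categories: np.ndarray               # (N,) int8
    chain_id: np.ndarray                 # (N,) int32, -1 for non-chromatin
    bonds: np.ndarray                    # (nb, 2) int64
    bond_kinds: np.ndarray               # (nb,) int8: 0 backbone, 1 lamina
    bond_rest_lengths: np.ndarray        # (nb,) float; NaN = use default
    annotation: GenomeAnnotation | None = None
    lamina_mesh: LaminaMesh | None = None

    @property
    def n_particles(self) -> int:
        return len(self.categories)

    def count(self, category: int) -> int:
        return int(np.sum(self.categories == category))

    @property
    def n_chromatin(self) -> int:
        return self.count(CHROMATIN)

    @property
    def n_nucleolus(self) -> int:
        return self.count(NUCLEOLUS)

    @property
    def n_speckle(self) -> int:
        return self.count(SPECKLE)

    @property
    def n_lamina(self) -> int:
        return self.count(LAMINA)

    def indices(self, category: int) -> np.ndarray:
        return np.flatnonzero(self.categories == category)

    @property
    def compartments(self) -> np.ndarray:
        """Per-particle compartment label; -1 for non-chromatin."""
        out = np.full(self.n_particles, -1, dtype=np.int8)
        if self.annotation is not None:
            out[:self.n_chromatin] = self.annotation.compartments
        return out


def build_topology(annotation: GenomeAnnotation,
                   n_nucleolus: int = 0,
                   n_speckle: int = 0,
                   lamina_mesh: LaminaMesh | None = None) -> NucleusTopology:
    """Assemble the nucleus particle table from its components."""
    if n_nucleolus < 0 or n_speckle < 0:
        raise ValueError("body particle counts must be non-negative")
    n_chrom = annotation.n_beads
    if n_chrom == 0:
        raise ValueError("topology needs at least one chromatin bead")
    n_lam = lamina_mesh.n_vertices if lamina_mesh is not None else 0
    n = n_chrom + n_nucleolus + n_speckle + n_lam

    categories = np.empty(n, dtype=np.int8)
    categories[:n_chrom] = CHROMATIN
    categories[n_chrom:n_chrom + n_nucleolus] = NUCLEOLUS
    categories[n_chrom + n_nucleolus:n_chrom + n_nucleolus + n_speckle] = SPECKLE
    categories[n_chrom + n_nucleolus + n_speckle:] = LAMINA

    chain_id = np.full(n, -1, dtype=np.int32)
    chain_id[:n_chrom] = annotation.chain_of_bead

    # backbone bonds: consecutive beads of the same chain
    offs = annotation.chain_offsets
    bb = []
    for c in range(annotation.n_chains):
        o, m = int(offs[c]), int(annotation.beads_per_chain[c])
        idx = np.arange(o, o + m - 1)
        bb.append(np.stack([idx, idx + 1], axis=1))
    backbone = (np.concatenate(bb) if bb else
                np.empty((0, 2), dtype=np.int64))
    backbone = backbone[backbone[:, 0] < backbone[:, 1]] if backbone.size else backbone

    if lamina_mesh is not None:
        lam0 = n_chrom + n_nucleolus + n_speckle
        lam_edges = lamina_mesh.edges + lam0
        bonds = np.concatenate([backbone, lam_edges]).astype(np.int64)
        kinds = np.concatenate([np.zeros(len(backbone), dtype=np.int8),
                                np.ones(len(lam_edges), dtype=np.int8)])
        rest = np.concatenate([np.full(len(backbone), np.nan),
                               lamina_mesh.edge_rest_lengths])
    else:
        bonds = backbone.astype(np.int64)
        kinds = np.zeros(len(backbone), dtype=np.int8)
        rest = np.full(len(backbone), np.nan)

    return NucleusTopology(categories=categories, chain_id=chain_id,
                           bonds=bonds, bond_kinds=kinds,
                           bond_rest_lengths=rest,
                           annotation=annotation, lamina_mesh=lamina_mesh)


# ---------------------------------------------------------------------------
# configurations


@dataclass
class Configuration:
    """Positions (reduced units) plus speckle chemical states."""

    positions: np.ndarray            # (N, 3) float64
    speckle_states: np.ndarray       # (n_speckle,) int8, P=0 / dP=1
    seed: int | str | None = None
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.speckle_states = np.asarray(self.speckle_states, dtype=np.int8)

    def validate(self, topology: NucleusTopology) -> None:
        if len(self.positions) != topology.n_particles:
            raise ValueError("position array does not match particle count")
        if len(self.speckle_states) != topology.n_speckle:
            raise ValueError("speckle state array does not match count")

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(),
                             self.speckle_states.copy(),
                             seed=self.seed, step=self.step)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def generate_initial_configuration(
    topology: NucleusTopology,
    seed: int,
    radius: float | None = None,
    bond_length: float = 1.0,
    margin: float = 0.5,
    dp_fraction: float = 0.5,
) -> Configuration:
    """Random territory-like starting structure.

    Every chain is laid down as a compact random walk confined to a ball
    whose radius matches the mean chromatin density, centred at a point
    drawn uniformly (by volume) inside the nucleus; bodies are placed
    uniformly at random.  Deterministic for a given seed.
    """
    if radius is None:
        if topology.lamina_mesh is None:
            raise ValueError("radius required when topology has no lamina mesh")
        radius = topology.lamina_mesh.radius
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1C0]))
    r_int = radius - min(margin, 0.15 * radius)
    if r_int <= 0:
        raise PlacementError("nucleus radius too small for the margin")
    n = topology.n_particles
    pos = np.zeros((n, 3))

    ann = topology.annotation
    if ann is not None and ann.n_beads:
        density = ann.n_beads / (4.0 / 3.0 * np.pi * r_int ** 3)
        if density > 60.0:
            raise PlacementError(
                f"chromatin density {density:.1f} beads/sigma^3 too high "
                "to place without overlap")
        for c in range(ann.n_chains):
            m = int(ann.beads_per_chain[c])
            r_chain = (3.0 * m / (4.0 * np.pi * density)) ** (1.0 / 3.0)
            r_chain = min(r_chain, r_int)
            r_place = max(r_int - r_chain, 0.0)
            center = _uniform_ball(rng, 1, r_place)[0]
            # collapsed globule: a free random walk recentred on its own
            # centroid and shrunk radially into the chain ball; compressed
            # bonds relax within a brief equilibration
            steps = rng.standard_normal((m - 1, 3)) if m > 1 \
                else np.zeros((0, 3))
            if m > 1:
                steps *= bond_length / np.linalg.norm(steps, axis=1,
                                                      keepdims=True)
            walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            walk -= walk.mean(axis=0)
            extent = float(np.max(np.linalg.norm(walk, axis=1))) or 1.0
            walk *= min(1.0, r_chain / extent)
            walk += center
            # project any straggler back inside the envelope
            rads = np.linalg.norm(walk, axis=1)
            out = rads > r_int
            if np.any(out):
                walk[out] *= (0.99 * r_int / rads[out])[:, None]
            o = int(ann.chain_offsets[c])
            pos[o:o + m] = walk

    for cat in (NUCLEOLUS, SPECKLE):
        idx = topology.indices(cat)
        if idx.size:
            pos[idx] = _uniform_ball(rng, idx.size, r_int)

    lam = topology.indices(LAMINA)
    if lam.size:
        pos[lam] = topology.lamina_mesh.vertices

    states = (rng.random(topology.n_speckle) < dp_fraction).astype(np.int8)
    return Configuration(positions=pos, speckle_states=states, seed=int(seed))


# ---------------------------------------------------------------------------
# starting-configuration selection


@dataclass
class SelectionResult:
    indices: np.ndarray
    objective: float
    trace: list[float]


def _selection_objective(sum_prof, sum_map, k, target_prof, target_map,
                         w_prof, w_map) -> float:
    dp = sum_prof / k - target_prof
    dm = sum_map / k - target_map
    return float(w_prof * np.mean(dp * dp) + w_map * np.mean(dm * dm))


def select_starting_configurations(
    lamina_profiles: np.ndarray,
    chrom_pair_maps: np.ndarray,
    target_profile: np.ndarray,
    target_map: np.ndarray,
    k: int,
    seed: int = 0,
    weight_profile: float = 1.0,
    weight_map: float = 1.0,
    n_init: int = 20,
    max_proposals: int = 20_000,
) -> SelectionResult:
    """Pick ``k`` candidates whose ensemble average best matches targets.

    Stochastic greedy-swap descent on a weighted sum of squared
    deviations between the subset average and the target lamina-contact
    profile / chromosome-pair contact matrix: from each of ``n_init``
    random subsets, repeatedly apply the best improving member/non-member
    swap until none exists, and keep the best local optimum.  The
    objective is monotonically non-increasing across accepted swaps and
    never worse than the best random starting subset.
    """
    profiles = np.asarray(lamina_profiles, dtype=float)
    maps = np.asarray(chrom_pair_maps, dtype=float).reshape(len(profiles), -1)
    tgt_p = np.asarray(target_profile, dtype=float)
    tgt_m = np.asarray(target_map, dtype=float).ravel()
    n_cand = len(profiles)
    if k > n_cand:
        raise ValueError(f"k={k} exceeds number of candidates {n_cand}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E1]))

    if k == n_cand:
        obj = _selection_objective(profiles.sum(0), maps.sum(0), k,
                                   tgt_p, tgt_m, weight_profile, weight_map)
        return SelectionResult(np.arange(n_cand), obj, [obj])

    def descend(start_idx):
        """Steepest-descent swap passes until a local optimum."""
        chosen = list(int(i) for i in start_idx)
        sum_p = profiles[chosen].sum(0)
        sum_m = maps[chosen].sum(0)
        obj = _selection_objective(sum_p, sum_m, k, tgt_p, tgt_m,
                                   weight_profile, weight_map)
        trace = [obj]
        for _ in range(max_proposals):
            outside = np.array(sorted(set(range(n_cand)) - set(chosen)))
            if outside.size == 0:
                break
            best = None
            for pos_i, a in enumerate(chosen):
                base_p = sum_p - profiles[a]
                base_m = sum_m - maps[a]
                dp = (base_p + profiles[outside]) / k - tgt_p
                dm = (base_m + maps[outside]) / k - tgt_m
                objs = (weight_profile * np.mean(dp * dp, axis=1)
                        + weight_map * np.mean(dm * dm, axis=1))
                j = int(np.argmin(objs))
                if objs[j] < obj - 1e-15 and \
                        (best is None or objs[j] < best[0]):
                    best = (float(objs[j]), pos_i, int(outside[j]))
            if best is None:
                break
            obj, pos_i, b = best
            a = chosen[pos_i]
            sum_p = sum_p - profiles[a] + profiles[b]
            sum_m = sum_m - maps[a] + maps[b]
            chosen[pos_i] = b
            trace.append(obj)
        return np.array(sorted(chosen)), obj, trace

    best_res = None
    for _ in range(max(1, n_init)):
        start = rng.choice(n_cand, size=k, replace=False)
        idx, obj, trace = descend(start)
        if best_res is None or obj < best_res[1]:
            best_res = (idx, obj, trace)
    return SelectionResult(*best_res)
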