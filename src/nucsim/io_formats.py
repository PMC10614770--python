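"""Readers and writers for every on-disk format the tool touches.

Configurations are exchanged as PDB (small systems) or mmCIF (beyond
legacy PDB field limits), with residue names encoding the particle
category (CHR/NUC/SPK/LAM) and one chain per polymer.  A JSON sidecar
carries everything the coordinate formats cannot: compartment labels,
chain layout, body counts, the lamina-mesh recipe (which is
deterministic and therefore rebuildable), speckle chemical states and
seed provenance.

Experimental 1D tracks (DamID / TSA-Seq style) travel as bedGraph at
their native resolution (typically 25 KB) and are averaged onto the
100-KB model grid here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile
from biotite.structure.io.pdbx import get_structure as cif_get_structure
from biotite.structure.io.pdbx import set_structure as cif_set_structure

from .genome_model import (CHROMATIN, LAMINA, NUCLEOLUS, SPECKLE,
                           COMP_NAMES, COMP_CODES, Configuration,
                           GenomeAnnotation, NucleusTopology,
                           build_lamina_mesh, build_topology)

logger = logging.getLogger("nucsim")

CATEGORY_RESNAME = {CHROMATIN: "CHR", NUCLEOLUS: "NUC",
                    SPECKLE: "SPK", LAMINA: "LAM"}

_PDB_MAX_ATOMS = 99_999
_PDB_MAX_RESID = 9_999
_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def config_hash(obj) -> str:
    """Stable hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# genome inputs


def read_genome_table(path) -> pd.DataFrame:
    """Tab-separated (chrom, length) table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"])
    df["length"] = df["length"].astype(int)
    return df


def read_compartment_bed(path) -> pd.DataFrame:
    """BED with a label column: chrom, start, end, label (A/B/C)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"])
    return df


# ---------------------------------------------------------------------------
# configurations


def _topology_sidecar(topology: NucleusTopology) -> dict:
    ann = topology.annotation
    d: dict = {"n_nucleolus": topology.n_nucleolus,
               "n_speckle": topology.n_speckle}
    if ann is not None:
        d["annotation"] = {
            "chain_names": ann.chain_names,
            "haploid_names": ann.haploid_names,
            "haploid_index": ann.haploid_index.tolist(),
            "beads_per_chain": ann.beads_per_chain.tolist(),
            "compartments": "".join(COMP_NAMES[c] for c in ann.compartments),
        }
    if topology.lamina_mesh is not None:
        mesh = topology.lamina_mesh
        d["lamina_mesh"] = {"radius": mesh.radius,
                            "n_vertices": mesh.n_vertices,
                            "k_neighbors": mesh.k_neighbors,
                            "frozen": mesh.frozen}
    return d


def _topology_from_sidecar(d: dict) -> NucleusTopology:
    ann = None
    if "annotation" in d:
        a = d["annotation"]
        ann = GenomeAnnotation(
            chain_names=list(a["chain_names"]),
            haploid_names=list(a["haploid_names"]),
            haploid_index=np.array(a["haploid_index"]),
            beads_per_chain=np.array(a["beads_per_chain"]),
            compartments=np.array([COMP_CODES[ch]
                                   for ch in a["compartments"]],
                                  dtype=np.int8))
    mesh = None
    if "lamina_mesh" in d:
        m = d["lamina_mesh"]
        mesh = build_lamina_mesh(m["radius"], m["n_vertices"],
                                 k_neighbors=m.get("k_neighbors", 6))
        mesh.frozen = bool(m.get("frozen", True))
    return build_topology(ann, d.get("n_nucleolus", 0),
                          d.get("n_speckle", 0), mesh)


def _chain_labels(topology: NucleusTopology, short: bool) -> np.ndarray:
    """Chain identifier per particle; 1-char for PDB, multi-char for CIF."""
    n = topology.n_particles
    labels = np.empty(n, dtype="U4")
    ann = topology.annotation
    cat = topology.categories
    if short:
        def code(i):
            return (_CHAIN_ALPHABET[i] if i < len(_CHAIN_ALPHABET)
                    else "?")
        nch = ann.n_chains if ann is not None else 0
        for c in range(nch):
            labels[topology.chain_id == c] = code(c)
        labels[cat == NUCLEOLUS] = code(nch)
        labels[cat == SPECKLE] = code(nch + 1)
        labels[cat == LAMINA] = code(nch + 2)
    else:
        nch = ann.n_chains if ann is not None else 0
        for c in range(nch):
            labels[topology.chain_id == c] = f"C{c}"
        labels[cat == NUCLEOLUS] = "NUC"
        labels[cat == SPECKLE] = "SPK"
        labels[cat == LAMINA] = "LAM"
    return labels


def _pdb_fits(topology: NucleusTopology) -> bool:
    ann = topology.annotation
    n_chains = (ann.n_chains if ann is not None else 0) + 3
    max_res = max(
        int(ann.beads_per_chain.max()) if ann is not None else 0,
        topology.n_nucleolus, topology.n_speckle, topology.n_lamina)
    return (topology.n_particles <= _PDB_MAX_ATOMS
            and n_chains <= len(_CHAIN_ALPHABET)
            and max_res <= _PDB_MAX_RESID)


def _atom_array(topology: NucleusTopology, positions: np.ndarray,
                short_chains: bool) -> struc.AtomArray:
    n = topology.n_particles
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(positions, dtype=np.float32)
    arr.chain_id = _chain_labels(topology, short_chains)
    res_id = np.empty(n, dtype=int)
    ann = topology.annotation
    if ann is not None:
        res_id[:ann.n_beads] = ann.within_chain_index + 1
    for cat in (NUCLEOLUS, SPECKLE, LAMINA):
        idx = topology.indices(cat)
        res_id[idx] = np.arange(1, idx.size + 1)
    arr.res_id = res_id
    arr.res_name = np.array([CATEGORY_RESNAME[c]
                             for c in topology.categories])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    return arr


def write_configuration(path, configuration: Configuration,
                        topology: NucleusTopology,
                        sidecar_path=None, fmt: str | None = None) -> str:
    """Write a configuration as PDB/mmCIF plus its JSON sidecar.

    The format is chosen automatically: PDB while atom counts, residue
    ids and chain labels fit the legacy fixed columns, mmCIF otherwise.
    Returns the format used.
    """
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if _pdb_fits(topology) else "cif"
    arr = _atom_array(topology, configuration.positions, fmt == "pdb")
    if fmt == "pdb":
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        f = CIFFile()
        cif_set_structure(f, arr)
        f.write(str(path))
    sidecar = {
        "format": fmt,
        "topology": _topology_sidecar(topology),
        "speckle_states": configuration.speckle_states.tolist(),
        "seed": configuration.seed,
        "step": configuration.step,
    }
    sidecar["config_hash"] = config_hash(sidecar["topology"])
    sc_path = Path(sidecar_path) if sidecar_path is not None \
        else path.with_suffix(path.suffix + ".json")
    sc_path.write_text(json.dumps(sidecar))
    return fmt


def read_configuration(path, sidecar_path=None
                       ) -> tuple[Configuration, NucleusTopology]:
    """Read a configuration written by :func:`write_configuration`."""
    path = Path(path)
    sc_path = Path(sidecar_path) if sidecar_path is not None \
        else path.with_suffix(path.suffix + ".json")
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    topology = _topology_from_sidecar(sidecar["topology"])
    fmt = sidecar.get("format", "pdb")
    try:
        if fmt == "pdb":
            arr = PDBFile.read(str(path)).get_structure(model=1)
        else:
            arr = cif_get_structure(CIFFile.read(str(path)), model=1)
    except Exception as exc:  # noqa: BLE001 - wrap with file context
        raise ValueError(f"malformed configuration file {path}: {exc}") from exc
    if arr.array_length() != topology.n_particles:
        raise ValueError(
            f"{path}: particle count {arr.array_length()} does not match "
            f"sidecar topology ({topology.n_particles})")
    config = Configuration(
        positions=np.asarray(arr.coord, dtype=np.float64),
        speckle_states=np.array(sidecar["speckle_states"], dtype=np.int8),
        seed=sidecar.get("seed"), step=int(sidecar.get("step", 0)))
    config.validate(topology)
    return config, topology


# ---------------------------------------------------------------------------
# experimental tracks


@dataclass
class ExperimentalTrack:
    """A 1D genomic signal: sorted, non-overlapping fixed-width bins."""

    data: pd.DataFrame            # chrom, start, end, value
    resolution: int
    provenance: str = ""

    def __post_init__(self) -> None:
        d = self.data
        for c in ("chrom", "start", "end", "value"):
            if c not in d.columns:
                raise ValueError(f"track missing column {c!r}")
        for chrom, sub in d.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["end"].values[:-1] > s["start"].values[1:]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
        self.data = d.sort_values(["chrom", "start"]).reset_index(drop=True)

    @classmethod
    def from_bedgraph(cls, path, resolution: int,
                      provenance: str = "") -> "ExperimentalTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        return cls(df, resolution, provenance or str(path))

    def to_bedgraph(self, path) -> None:
        self.data.to_csv(path, sep="\t", header=False, index=False,
                         float_format="%.8g")


def rebin_track(track: ExperimentalTrack,
                target_resolution: int) -> ExperimentalTrack:
    """Average native bins onto a coarser grid (e.g. 25 KB -> 100 KB).

    Native bins with missing (NaN) values are excluded from each mean;
    a target bin with no informative native bin stays NaN.
    """
    if target_resolution % track.resolution != 0:
        raise ValueError(
            f"target resolution {target_resolution} is not a multiple of "
            f"native resolution {track.resolution}")
    d = track.data.copy()
    d["bin"] = d["start"] // target_resolution
    grouped = d.groupby(["chrom", "bin"], sort=False)["value"].mean()
    out = grouped.reset_index()
    out["start"] = out["bin"] * target_resolution
    out["end"] = out["start"] + target_resolution
    out = out[["chrom", "start", "end", "value"]]
    return ExperimentalTrack(out, target_resolution,
                             provenance=f"rebinned({track.provenance})")


def merge_replicates(tracks: list[ExperimentalTrack]) -> ExperimentalTrack:
    """Bin-wise mean of replicate tracks on an identical grid."""
    if not tracks:
        raise ValueError("no tracks given")
    res = tracks[0].resolution
    ref = tracks[0].data[["chrom", "start", "end"]]
    values = []
    for t in tracks:
        if t.resolution != res:
            raise ValueError("replicates differ in resolution")
        if not t.data[["chrom", "start", "end"]].equals(ref):
            raise ValueError("replicates are on different genomic grids")
        values.append(t.data["value"].values)
    out = ref.copy()
    out["value"] = np.mean(values, axis=0)
    prov = "merged(" + ", ".join(t.provenance for t in tracks) + ")"
    return ExperimentalTrack(out, res, provenance=prov)


def track_to_profile_values(track: ExperimentalTrack, chrom_order,
                            n_bins_per_chrom) -> np.ndarray:
    """Flatten a track onto the concatenated haploid model grid."""
    out = np.full(int(np.sum(n_bins_per_chrom)), np.nan)
    offset = 0
    for chrom, n in zip(chrom_order, n_bins_per_chrom):
        sub = track.data[track.data["chrom"] == chrom]
        idx = (sub["start"] // track.resolution).astype(int)
        ok = idx < n
        out[offset + idx[ok].values] = sub["value"].values[ok]
        offset += int(n)
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated description of a single command-line run."""

    mode: str
    seed: int
    configuration: str | None = None
    parameters: str | None = None
    targets: str | None = None
    output: str | None = None
    n_steps: int = 100_000
    record_interval: int = 2_000
    discard_steps: int = 0
    integrator: str = "langevin"
    dt: float = 0.005
    gamma_inv: float | None = None
    extra: dict = field(default_factory=dict)

    MODES = ("build", "simulate", "optimize", "analyze", "fixtures")

    def validate(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        for attr in ("configuration", "parameters", "targets"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls(**d)
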