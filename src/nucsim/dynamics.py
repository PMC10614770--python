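"""Propagation of the nucleus model.

Two stochastic integrators operate in reduced units at T = 1:

* ``langevin`` -- BAOAB splitting with unit particle masses and the
  default damping gamma^-1 = 10 (fast conformational sampling),
* ``brownian`` -- overdamped Euler-Maruyama with gamma^-1 = 0.01,
  whose first-passage statistics map onto physical time through the
  Brownian time unit tau = 0.65 s.

Speckle particles additionally undergo semi-grand canonical Monte Carlo
chemistry: every 4000 steps, N_Sp attempts each select a speckle at
random, propose flipping its P/dP state with probability 0.2, and accept
by the Metropolis criterion on the energy change (detailed balance at
zero chemical-potential difference; unconditional flipping is available
as a flag).  Lamina particles are frozen unless a deformation run
unfreezes them, in which case a harmonic force along z compresses the
envelope mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .forcefield import ForceField, ForceFieldParameters
from .genome_model import SPECKLE, Configuration, NucleusTopology

DEFAULT_GAMMA_INV = {"langevin": 10.0, "brownian": 0.01}


@dataclass(frozen=True)
class IntegratorSpec:
    """Stochastic integration scheme in reduced units."""

    scheme: str = "langevin"
    dt: float = 0.005
    gamma_inv: float | None = None   # damping: 10.0 (langevin) / 0.01 (brownian)
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme not in DEFAULT_GAMMA_INV:
            raise ValueError(f"unknown integrator scheme {self.scheme!r}")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.gamma_inv is not None and self.gamma_inv <= 0:
            raise ValueError("damping must be positive")

    @property
    def resolved_gamma_inv(self) -> float:
        return (self.gamma_inv if self.gamma_inv is not None
                else DEFAULT_GAMMA_INV[self.scheme])

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "dt": self.dt,
                "gamma_inv": self.resolved_gamma_inv,
                "temperature": self.temperature}


@dataclass(frozen=True)
class SpeckleReactionSpec:
    """Semi-grand MC chemistry for speckle P <-> dP transitions."""

    interval: int = 4000
    probability: float = 0.2
    metropolis: bool = True
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("reaction interval must be >= 1 step")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("switch probability must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"interval": self.interval, "probability": self.probability,
                "metropolis": self.metropolis, "enabled": self.enabled}


@dataclass(frozen=True)
class DeformationSpec:
    """Harmonic z-compression of a dynamic lamina mesh."""

    force_k: float
    lamina_dynamic: bool = True

    def __post_init__(self) -> None:
        if self.force_k < 0:
            raise ValueError("deformation force strength must be >= 0")


def apply_deformation(topology: NucleusTopology,
                      spec: DeformationSpec) -> NucleusTopology:
    """Validate and unfreeze the lamina for a deformation run.

    Returns the topology with a dynamic lamina mesh; the compression
    term itself is added by :class:`Simulation` from the spec.
    """
    if topology.lamina_mesh is None or len(topology.lamina_mesh.edges) == 0:
        raise ValueError("deformation requires a bonded lamina mesh")
    if not spec.lamina_dynamic:
        raise ValueError("deformation requested with a frozen lamina")
    topology.lamina_mesh.frozen = False
    return topology


def minimize_energy(topology: NucleusTopology,
                    params: ForceFieldParameters,
                    configuration: Configuration,
                    max_iterations: int = 300,
                    max_step: float = 0.05,
                    force_tol: float = 20.0) -> Configuration:
    """Brief clipped-gradient relaxation of an initial structure.

    Removes placement overlaps and compressed bonds before dynamics;
    per-particle moves are capped at ``max_step`` so capped soft-core
    overlaps cannot catapult particles.  Frozen lamina particles stay.
    """
    ff = ForceField(topology, params)
    pos = configuration.positions.copy()
    mobile = ~ff.frozen
    pairs = ff.build_pairs(pos, skin=0.3)
    for it in range(max_iterations):
        if it % 10 == 0:
            pairs = ff.build_pairs(pos, skin=0.3)
        _, forces = ff.energy_forces(pos, configuration.speckle_states,
                                     pairs=pairs)
        fmag = np.linalg.norm(forces[mobile], axis=1)
        fmax = fmag.max() if fmag.size else 0.0
        if fmax < force_tol:
            break
        scale = min(1e-3, max_step / max(fmax, 1e-12))
        pos[mobile] += scale * forces[mobile]
    out = configuration.copy()
    out.positions = pos
    return out


# ---------------------------------------------------------------------------
# trajectory container


@dataclass
class Trajectory:
    """Recorded frames of one run plus full reproducibility metadata."""

    positions: np.ndarray        # (F, N, 3)
    speckle_states: np.ndarray   # (F, n_speckle) int8
    steps: np.ndarray            # (F,) simulation step of each frame
    dt: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Configuration:
        return Configuration(self.positions[i].copy(),
                             self.speckle_states[i].copy(),
                             seed=self.metadata.get("seed"),
                             step=int(self.steps[i]))

    def times(self) -> np.ndarray:
        """Frame times in reduced units."""
        return self.steps * self.dt

    def after_discard(self, discard_steps: int) -> "Trajectory":
        keep = self.steps >= discard_steps
        return Trajectory(self.positions[keep], self.speckle_states[keep],
                          self.steps[keep], self.dt, dict(self.metadata))

    def save(self, path) -> None:
        with h5py.File(path, "w", track_order=True) as h:
            for name, arr in (("positions", self.positions),
                              ("speckle_states", self.speckle_states),
                              ("steps", self.steps)):
                h.create_dataset(name, data=arr, track_times=False)
            h.attrs["dt"] = self.dt
            h.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as h:
            return cls(positions=h["positions"][...],
                       speckle_states=h["speckle_states"][...],
                       steps=h["steps"][...],
                       dt=float(h.attrs["dt"]),
                       metadata=json.loads(h.attrs["metadata"]))


# ---------------------------------------------------------------------------
# simulation driver


class Simulation:
    """Owns the mutable dynamical state of one run.

    Random numbers come from two named streams (thermostat, chemistry)
    spawned from the run seed, so trajectories are bit-reproducible and
    checkpoint/restart continues the identical stream.
    """

    def __init__(self, topology: NucleusTopology,
                 params: ForceFieldParameters,
                 configuration: Configuration,
                 integrator: IntegratorSpec | None = None,
                 reactions: SpeckleReactionSpec | None = None,
                 deformation: DeformationSpec | None = None,
                 seed: int = 0,
                 skin: float = 0.5):
        configuration.validate(topology)
        self.topology = topology
        self.params = params
        self.integrator = integrator or IntegratorSpec()
        self.reactions = reactions or SpeckleReactionSpec()
        self.deformation = deformation
        self.seed = int(seed)
        self.skin = float(skin)

        frozen_lamina = True
        deformation_k = 0.0
        if deformation is not None:
            apply_deformation(topology, deformation)
            frozen_lamina = False
            deformation_k = deformation.force_k
        elif topology.lamina_mesh is not None and not topology.lamina_mesh.frozen:
            frozen_lamina = False
        self.ff = ForceField(topology, params, frozen_lamina=frozen_lamina,
                             deformation_k=deformation_k)
        self.mobile = ~self.ff.frozen
        # frozen lamina occupies a contiguous tail; a slice keeps the
        # per-step updates as in-place views instead of masked copies
        n_mob = int(np.sum(self.mobile))
        if np.all(self.mobile[:n_mob]):
            self._mob = slice(0, n_mob)
        else:
            self._mob = np.flatnonzero(self.mobile)

        self.positions = configuration.positions.copy()
        self.velocities = np.zeros_like(self.positions)
        self.state = np.zeros(topology.n_particles, dtype=np.int8)
        self._speckle_idx = topology.indices(SPECKLE)
        self.state[self._speckle_idx] = configuration.speckle_states
        self.step_count = 0
        self.flip_counts: list[int] = []

        ss = np.random.SeedSequence([self.seed, 0xD1CE])
        thermo_ss, chem_ss = ss.spawn(2)
        self.rng_thermo = np.random.default_rng(thermo_ss)
        self.rng_chem = np.random.default_rng(chem_ss)

        self._ref_positions = self.positions.copy()
        self._pairs = self._build_pairs()
        self._forces = self._eval_forces()

        g_inv = self.integrator.resolved_gamma_inv
        T = self.integrator.temperature
        dt = self.integrator.dt
        if self.integrator.scheme == "langevin":
            gamma = 1.0 / g_inv
            self._c1 = np.exp(-gamma * dt)
            self._c2 = np.sqrt(T * (1.0 - self._c1 ** 2))
        else:
            self._mobility = g_inv            # 1 / (m * gamma), m = 1
            self._noise = np.sqrt(2.0 * T * g_inv * dt)

    # -- internals ----------------------------------------------------------

    def _build_pairs(self):
        return self.ff.build_pairs(self.positions, skin=self.skin,
                                   prune=True, skip_frozen=True)

    def _maybe_rebuild(self) -> None:
        disp = self.positions[self._mob] - self._ref_positions[self._mob]
        if disp.size and np.max(np.abs(disp)) > 0.5 * self.skin / np.sqrt(3):
            self._ref_positions = self.positions.copy()
            self._pairs = self._build_pairs()

    def _check_finite(self, forces: np.ndarray) -> None:
        if not np.all(np.isfinite(forces)):
            bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
            raise FloatingPointError(
                f"non-finite force on particle {bad} at step {self.step_count}")

    # -- public API ---------------------------------------------------------

    @property
    def configuration(self) -> Configuration:
        return Configuration(self.positions.copy(),
                             self.state[self._speckle_idx].copy(),
                             seed=self.seed, step=self.step_count)

    def kinetic_temperature(self) -> float:
        v = self.velocities[self.mobile]
        if v.size == 0:
            return 0.0
        return float(np.mean(v * v))

    def step(self, n: int = 1) -> None:
        """Advance ``n`` integration steps (plus due reaction sweeps)."""
        dt = self.integrator.dt
        mob = self._mob
        langevin = self.integrator.scheme == "langevin"
        for _ in range(n):
            if langevin:
                self.velocities[mob] += 0.5 * dt * self._forces[mob]
                self.positions[mob] += 0.5 * dt * self.velocities[mob]
                xi = self.rng_thermo.standard_normal(self.velocities[mob].shape)
                self.velocities[mob] = (self._c1 * self.velocities[mob]
                                        + self._c2 * xi)
                self.positions[mob] += 0.5 * dt * self.velocities[mob]
                self._maybe_rebuild()
                forces = self._eval_forces()
                self.velocities[mob] += 0.5 * dt * forces[mob]
            else:
                xi = self.rng_thermo.standard_normal(self.positions[mob].shape)
                self.positions[mob] += (dt * self._mobility *
                                        self._forces[mob] + self._noise * xi)
                self._maybe_rebuild()
                forces = self._eval_forces()
            self._forces = forces
            self.step_count += 1
            if (self.reactions.enabled and self._speckle_idx.size
                    and self.step_count % self.reactions.interval == 0):
                self.speckle_sweep()

    def _eval_forces(self) -> np.ndarray:
        _, forces = self.ff.energy_forces(
            self.positions, self.state[self._speckle_idx], pairs=self._pairs)
        self._check_finite(forces)
        return forces

    def speckle_sweep(self) -> int:
        """One semi-grand MC sweep: N_Sp flip attempts; returns #flips."""
        n_sp = self._speckle_idx.size
        flips = 0
        T = self.integrator.temperature
        for _ in range(n_sp):
            pick = int(self.rng_chem.integers(n_sp))
            if self.rng_chem.random() >= self.reactions.probability:
                continue
            p = int(self._speckle_idx[pick])
            accept = True
            if self.reactions.metropolis:
                de = self.ff.speckle_flip_delta(self.positions, self.state, p)
                if de > 0 and self.rng_chem.random() >= np.exp(-de / T):
                    accept = False
            if accept:
                self.state[p] = 1 - self.state[p]
                flips += 1
        self.flip_counts.append(flips)
        # state change alters dP-gated forces
        self._forces = self._eval_forces()
        return flips

    def run(self, n_steps: int, record_interval: int = 2000,
            trajectory_path=None, checkpoint_path=None,
            checkpoint_interval: int | None = None) -> Trajectory:
        """Propagate and record a trajectory.

        The initial frame is always recorded; afterwards one frame per
        ``record_interval`` steps.  Equilibration discard is left to the
        analysis layer.  Deterministic for a given seed.
        """
        n_frames = 1 + n_steps // record_interval
        N = self.topology.n_particles
        pos_out = np.empty((n_frames, N, 3))
        st_out = np.empty((n_frames, self._speckle_idx.size), dtype=np.int8)
        steps_out = np.empty(n_frames, dtype=np.int64)
        pos_out[0] = self.positions
        st_out[0] = self.state[self._speckle_idx]
        steps_out[0] = self.step_count
        frame = 1
        done = 0
        try:
            while done < n_steps:
                chunk = min(record_interval, n_steps - done)
                self.step(chunk)
                done += chunk
                if done % record_interval == 0:
                    pos_out[frame] = self.positions
                    st_out[frame] = self.state[self._speckle_idx]
                    steps_out[frame] = self.step_count
                    frame += 1
                if (checkpoint_path is not None and checkpoint_interval
                        and done % checkpoint_interval == 0):
                    self.checkpoint(checkpoint_path)
        except FloatingPointError:
            if checkpoint_path is not None:
                self.checkpoint(checkpoint_path)
            raise
        traj = Trajectory(
            positions=pos_out[:frame], speckle_states=st_out[:frame],
            steps=steps_out[:frame], dt=self.integrator.dt,
            metadata={"seed": self.seed,
                      "integrator": self.integrator.to_dict(),
                      "reactions": self.reactions.to_dict(),
                      "n_steps": int(self.step_count),
                      "record_interval": int(record_interval),
                      "deformation_k": (self.deformation.force_k
                                        if self.deformation else 0.0)})
        if trajectory_path is not None:
            traj.save(trajectory_path)
        return traj

    # -- checkpointing ------------------------------------------------------

    def checkpoint(self, path) -> None:
        with h5py.File(path, "w") as h:
            for name, arr in (("positions", self.positions),
                              ("velocities", self.velocities),
                              ("state", self.state),
                              ("ref_positions", self._ref_positions),
                              ("forces", self._forces)):
                h.create_dataset(name, data=arr, track_times=False)
            h.attrs["step_count"] = self.step_count
            h.attrs["seed"] = self.seed
            h.attrs["rng_thermo"] = json.dumps(
                self.rng_thermo.bit_generator.state)
            h.attrs["rng_chem"] = json.dumps(
                self.rng_chem.bit_generator.state)
            h.attrs["flip_counts"] = json.dumps(self.flip_counts)

    def restore(self, path) -> None:
        """Resume bit-exactly from a checkpoint written by this setup."""
        with h5py.File(path, "r") as h:
            self.positions[:] = h["positions"][...]
            self.velocities[:] = h["velocities"][...]
            self.state[:] = h["state"][...]
            self._ref_positions = h["ref_positions"][...]
            self._forces = h["forces"][...]
            self.step_count = int(h.attrs["step_count"])
            self.rng_thermo.bit_generator.state = json.loads(
                h.attrs["rng_thermo"])
            self.rng_chem.bit_generator.state = json.loads(
                h.attrs["rng_chem"])
            self.flip_counts = list(json.loads(h.attrs["flip_counts"]))
        saved_ref = self._ref_positions
        live = self.positions
        self.positions = self._ref_positions
        self._pairs = self._build_pairs()
        self.positions = live
        self._ref_positions = saved_ref


# ---------------------------------------------------------------------------
# module-level operations matching the workflow


def integrate_step(sim: Simulation) -> Configuration:
    """Advance one step and return the new configuration."""
    sim.step(1)
    return sim.configuration


def speckle_reaction_sweep(configuration: Configuration,
                           spec: SpeckleReactionSpec,
                           forcefield: ForceField,
                           rng: np.random.Generator,
                           temperature: float = 1.0) -> tuple[Configuration, int]:
    """One stand-alone reaction sweep on a static configuration.

    N_Sp attempts; each picks a speckle uniformly, proposes a state flip
    with the configured probability, and (optionally) applies the
    Metropolis criterion.  Positions and particle counts are untouched.
    """
    topo = forcefield.topology
    sp_idx = topo.indices(SPECKLE)
    state = np.zeros(topo.n_particles, dtype=np.int8)
    state[sp_idx] = configuration.speckle_states
    flips = 0
    for _ in range(sp_idx.size):
        pick = int(rng.integers(sp_idx.size))
        if rng.random() >= spec.probability:
            continue
        p = int(sp_idx[pick])
        accept = True
        if spec.metropolis:
            de = forcefield.speckle_flip_delta(configuration.positions,
                                               state, p)
            if de > 0 and rng.random() >= np.exp(-de / temperature):
                accept = False
        if accept:
            state[p] = 1 - state[p]
            flips += 1
    out = configuration.copy()
    out.speckle_states = state[sp_idx]
    return out, flips


def run_simulation(topology: NucleusTopology,
                   params: ForceFieldParameters,
                   configuration: Configuration,
                   n_steps: int,
                   integrator: IntegratorSpec | None = None,
                   reactions: SpeckleReactionSpec | None = None,
                   deformation: DeformationSpec | None = None,
                   record_interval: int = 2000,
                   seed: int = 0,
                   trajectory_path=None) -> Trajectory:
    """Convenience driver: build a :class:`Simulation` and run it."""
    sim = Simulation(topology, params, configuration, integrator=integrator,
                     reactions=reactions, deformation=deformation, seed=seed)
    return sim.run(n_steps, record_interval=record_interval,
                   trajectory_path=trajectory_path)
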