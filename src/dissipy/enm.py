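"""Harmonic (elastic) network simulation of kinetic-energy perturbations.

A distance-cutoff elastic network is built on the C-alpha beads and
integrated with velocity Verlet.  The production (dissipation) phase is
strictly microcanonical; equilibration uses a deterministic
velocity-rescaling thermostat so that paired perturbed/reference runs
are bit-identical up to the perturbation itself.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .errors import IndexErrorInput, InputError, IntegrationError
from .structures import ProteinStructure
from .units import INTERNAL_TO_KCAL_MOL, KB_INTERNAL, KCAL_MOL_TO_INTERNAL

logger = logging.getLogger(__name__)


@dataclass
class HarmonicNetwork:
    """Beads plus harmonic springs at native separations.

    Spring rest lengths equal the build-time inter-bead distances, so the
    initial potential energy is exactly zero.
    """

    masses: np.ndarray          # (N,) amu
    positions: np.ndarray       # (N, 3) Angstrom, build-time coordinates
    spring_i: np.ndarray        # (S,) 0-based bead indices, i < j
    spring_j: np.ndarray
    stiffness: np.ndarray       # (S,) kcal/mol/A^2
    rest_length: np.ndarray     # (S,) Angstrom

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_springs(self) -> int:
        return len(self.spring_i)

    def degree(self) -> np.ndarray:
        """Number of springs incident on each bead."""
        deg = np.zeros(self.n_beads, dtype=int)
        np.add.at(deg, self.spring_i, 1)
        np.add.at(deg, self.spring_j, 1)
        return deg


@dataclass
class SimulationConfig:
    timestep: float = 1.0          # fs
    n_steps: int = 1000
    save_interval: int = 10        # frames saved every this many steps
    temperature: float = 310.0     # K
    seed: int = 0
    cutoff: float = 10.0           # Angstrom
    stiffness: float = 1.0         # kcal/mol/A^2
    equilibration_steps: int = 0
    rescale_interval: int = 50     # thermostat period during equilibration

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise InputError("timestep must be > 0")
        if self.save_interval < 1:
            raise InputError("save_interval must be >= 1")
        if self.cutoff <= 0:
            raise InputError("cutoff must be > 0")


@dataclass
class Perturbation:
    """Scale the velocity vectors of selected residues by a common factor.

    ``residue_indices`` are 1-based.  ``velocity_factor`` f multiplies the
    velocity (kinetic energy scales by f^2); f = 1 is the null control.
    """

    residue_indices: frozenset[int]
    velocity_factor: float

    def __post_init__(self) -> None:
        self.residue_indices = frozenset(int(i) for i in self.residue_indices)
        if not self.residue_indices:
            raise InputError("perturbation needs at least one residue index")
        if self.velocity_factor <= 0:
            raise InputError("velocity_factor must be > 0")


@dataclass
class SystemState:
    positions: np.ndarray   # (N, 3) Angstrom
    velocities: np.ndarray  # (N, 3) Angstrom/fs
    time: float = 0.0       # fs

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(), self.time)


@dataclass
class EnergyTrace:
    """Per-residue energy time series for one trajectory."""

    times: np.ndarray       # (F,) fs
    energies: np.ndarray    # (N, F) kcal/mol
    meta: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return self.energies.shape[0]

    @property
    def n_frames(self) -> int:
        return self.energies.shape[1]


def build_network(structure: ProteinStructure, cutoff: float = 10.0,
                  stiffness: float = 1.0) -> HarmonicNetwork:
    """Connect every bead pair within `cutoff` Angstrom by a spring.

    Rest lengths are the build-time distances.  Isolated beads (zero
    springs) are legal but warned about: they can never respond.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be > 0")
    pos = structure.positions
    tree = cKDTree(pos)
    pairs = sorted(tree.query_pairs(cutoff))
    if pairs:
        i = np.array([p[0] for p in pairs], dtype=int)
        j = np.array([p[1] for p in pairs], dtype=int)
        r0 = np.linalg.norm(pos[j] - pos[i], axis=1)
    else:
        i = j = np.empty(0, dtype=int)
        r0 = np.empty(0)
    net = HarmonicNetwork(
        masses=structure.masses,
        positions=pos,
        spring_i=i,
        spring_j=j,
        stiffness=np.full(len(i), float(stiffness)),
        rest_length=r0,
    )
    isolated = np.flatnonzero(net.degree() == 0)
    for b in isolated:
        logger.warning("bead %d has no springs (isolated); it can never respond",
                       b + 1)
    return net


def init_state(network: HarmonicNetwork, temperature: float = 310.0,
               seed: int = 0) -> SystemState:
    """Maxwell-Boltzmann velocities at `temperature`, net momentum removed."""
    if temperature < 0:
        raise InputError("temperature must be >= 0")
    n = network.n_beads
    if temperature == 0:
        vel = np.zeros((n, 3))
    else:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(KB_INTERNAL * temperature / network.masses)
        vel = rng.standard_normal((n, 3)) * sigma[:, None]
        p = (network.masses[:, None] * vel).sum(axis=0)
        vel -= p / network.masses.sum()
    return SystemState(positions=network.positions.copy(), velocities=vel, time=0.0)


def _forces(network: HarmonicNetwork, x: np.ndarray) -> np.ndarray:
    """Spring forces in internal units (amu*A/fs^2)."""
    i, j = network.spring_i, network.spring_j
    d = x[j] - x[i]
    r = np.linalg.norm(d, axis=1)
    k_int = network.stiffness * KCAL_MOL_TO_INTERNAL
    coef = k_int * (r - network.rest_length) / r
    f_ij = coef[:, None] * d
    forces = np.zeros_like(x)
    np.add.at(forces, i, f_ij)
    np.add.at(forces, j, -f_ij)
    return forces


def kinetic_energy(network: HarmonicNetwork, state: SystemState) -> np.ndarray:
    """Per-bead kinetic energy, kcal/mol."""
    ke_int = 0.5 * network.masses * (state.velocities ** 2).sum(axis=1)
    return ke_int * INTERNAL_TO_KCAL_MOL


def spring_energies(network: HarmonicNetwork, x: np.ndarray) -> np.ndarray:
    """Per-spring potential energy, kcal/mol."""
    d = x[network.spring_j] - x[network.spring_i]
    r = np.linalg.norm(d, axis=1)
    return 0.5 * network.stiffness * (r - network.rest_length) ** 2


def per_residue_energy(network: HarmonicNetwork, state: SystemState) -> np.ndarray:
    """Residue energy = kinetic + half of each incident spring's potential.

    The vector sums to the total system energy exactly (up to float
    round-off), kcal/mol.
    """
    e = kinetic_energy(network, state)
    pe = spring_energies(network, state.positions)
    np.add.at(e, network.spring_i, 0.5 * pe)
    np.add.at(e, network.spring_j, 0.5 * pe)
    return e


def total_energy(network: HarmonicNetwork, state: SystemState) -> float:
    """Total system energy, kcal/mol."""
    return float(kinetic_energy(network, state).sum()
                 + spring_energies(network, state.positions).sum())


def apply_perturbation(state: SystemState,
                       perturbation: Perturbation) -> SystemState:
    """Return a new state with selected velocity vectors scaled by f."""
    n = len(state.positions)
    idx = np.array(sorted(perturbation.residue_indices), dtype=int) - 1
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexErrorInput(
            f"perturbation indices outside 1..{n}: {sorted(perturbation.residue_indices)}"
        )
    out = state.copy()
    out.velocities[idx] *= perturbation.velocity_factor
    return out


def _check_finite(x: np.ndarray, v: np.ndarray, step: int) -> None:
    if not (np.isfinite(x).all() and np.isfinite(v).all()):
        raise IntegrationError(f"non-finite state at step {step}")


def _velocity_verlet(network: HarmonicNetwork, state: SystemState, n_steps: int,
                     dt: float, on_frame, save_interval: int,
                     rescale_every: int = 0, target_temperature: float = 0.0):
    """Shared velocity-Verlet stepper.

    `on_frame(step, state)` is called at step 0 and every `save_interval`
    steps.  If `rescale_every` > 0 a deterministic velocity-rescaling
    thermostat to `target_temperature` is applied at that period.
    """
    x = state.positions.copy()
    v = state.velocities.copy()
    m = network.masses[:, None]
    f = _forces(network, x)
    cur = SystemState(x, v, state.time)
    on_frame(0, cur)
    for step in range(1, n_steps + 1):
        v = v + 0.5 * dt * f / m
        x = x + dt * v
        f = _forces(network, x)
        v = v + 0.5 * dt * f / m
        if rescale_every and step % rescale_every == 0:
            ke_int = 0.5 * (network.masses[:, None] * v ** 2).sum()
            target = 1.5 * network.n_beads * KB_INTERNAL * target_temperature
            if ke_int > 0:
                v = v * np.sqrt(target / ke_int)
        _check_finite(x, v, step)
        if step % save_interval == 0:
            cur = SystemState(x.copy(), v.copy(), state.time + step * dt)
            on_frame(step, cur)
    return SystemState(x, v, state.time + n_steps * dt)


def equilibrate(network: HarmonicNetwork, state: SystemState,
                config: SimulationConfig) -> SystemState:
    """Velocity-Verlet with periodic velocity rescaling to the target T.

    Fully deterministic given the input state; returns the final state
    with the clock reset to 0 (the dissipation phase starts fresh).
    """
    if config.equilibration_steps == 0:
        return state.copy()
    final = _velocity_verlet(
        network, state, config.equilibration_steps, config.timestep,
        on_frame=lambda step, s: None, save_interval=config.equilibration_steps,
        rescale_every=config.rescale_interval,
        target_temperature=config.temperature,
    )
    final.time = 0.0
    return final


def integrate(network: HarmonicNetwork, state: SystemState,
              config: SimulationConfig) -> list[SystemState]:
    """Microcanonical (NVE) velocity-Verlet run; returns saved frames.

    Frame 0 is the initial state; frames follow every
    ``config.save_interval`` steps.  No randomness is involved.
    """
    frames: list[SystemState] = []
    _velocity_verlet(
        network, state, config.n_steps, config.timestep,
        on_frame=lambda step, s: frames.append(s),
        save_interval=config.save_interval,
    )
    return frames


def _run_trace(network: HarmonicNetwork, state: SystemState,
               config: SimulationConfig, meta: dict) -> EnergyTrace:
    times: list[float] = []
    rows: list[np.ndarray] = []

    def record(step: int, s: SystemState) -> None:
        times.append(s.time)
        rows.append(per_residue_energy(network, s))

    _velocity_verlet(network, state, config.n_steps, config.timestep,
                     on_frame=record, save_interval=config.save_interval)
    return EnergyTrace(times=np.array(times), energies=np.column_stack(rows),
                       meta=meta)


def run_pair(network: HarmonicNetwork, initial_state: SystemState,
             perturbation: Perturbation,
             config: SimulationConfig) -> tuple[EnergyTrace, EnergyTrace]:
    """Paired perturbed/reference NVE runs from the identical initial state.

    The only difference between the two trajectories is the velocity
    scaling applied at time 0 in the perturbed run; both share the exact
    time grid and integration code path.
    """
    base_meta = {
        "timestep": config.timestep,
        "n_steps": config.n_steps,
        "save_interval": config.save_interval,
        "temperature": config.temperature,
        "seed": config.seed,
    }
    perturbed_state = apply_perturbation(initial_state, perturbation)
    perturbed = _run_trace(
        network, perturbed_state, config,
        meta=dict(base_meta,
                  perturbation={"residues": sorted(perturbation.residue_indices),
                                "velocity_factor": perturbation.velocity_factor}),
    )
    reference = _run_trace(network, initial_state.copy(), config,
                           meta=dict(base_meta, perturbation=None))
    return perturbed, reference
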