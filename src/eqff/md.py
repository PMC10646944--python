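"""NVT molecular dynamics with the BAOAB Langevin integrator.

Units follow the package policy: positions Angstrom, velocities Angstrom/fs,
masses amu, energies kcal/mol, temperature K. The BAOAB splitting is
half-kick (B), half-drift (A), exact Ornstein-Uhlenbeck velocity update (O),
half-drift (A), half-kick (B); the O-step uses the exact exponential
coefficients so the scheme samples the target temperature accurately for
any friction.

A potential is any callable system -> (energy, forces, info_dict); the
info dict may carry per-atom charges (used for dipole spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import ACC_UNIT, KBOLTZ, mass
from .geometry import AtomicSystem


@dataclass
class MDState:
    system: AtomicSystem
    velocities: np.ndarray  # (n, 3) Angstrom/fs
    masses: np.ndarray  # (n,) amu
    temperature: float  # K
    friction: float  # 1/fs
    time: float = 0.0  # fs
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def kinetic_energy(self) -> float:
        """kcal/mol."""
        return 0.5 * float(
            np.sum(self.masses[:, None] * self.velocities**2)
        ) / ACC_UNIT


def initialize_state(
    system: AtomicSystem,
    temperature: float,
    friction: float = 0.01,
    masses=None,
    seed: int = 0,
) -> MDState:
    """Maxwell-Boltzmann velocities at the target temperature."""
    rng = np.random.default_rng(seed)
    m = (
        np.asarray(masses, dtype=float)
        if masses is not None
        else np.array([mass(int(z)) for z in system.species])
    )
    sigma = np.sqrt(KBOLTZ * temperature / m * ACC_UNIT)
    v = rng.normal(size=(system.n_atoms, 3)) * sigma[:, None]
    return MDState(
        system=system, velocities=v, masses=m,
        temperature=temperature, friction=friction, rng=rng,
    )


def baoab_step(state: MDState, potential, dt: float, forces=None) -> tuple:
    """One BAOAB step; returns (new_state, energy, forces, info).

    `forces` may carry the forces at the current positions to avoid
    recomputing them (standard reuse between successive steps).
    """
    if dt <= 0:
        raise ValueError("timestep must be positive")
    m = state.masses[:, None]
    if forces is None:
        _, forces, _ = potential(state.system)
    _check_finite(forces)
    v = state.velocities + 0.5 * dt * forces / m * ACC_UNIT
    x = state.system.positions + 0.5 * dt * v
    c1 = np.exp(-state.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KBOLTZ * state.temperature / state.masses * ACC_UNIT)
    v = c1 * v + c2[:, None] * state.rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    new_system = AtomicSystem(
        state.system.species, x, state.system.cell, state.system.periodic
    )
    energy, forces_new, info = potential(new_system)
    _check_finite(forces_new)
    v = v + 0.5 * dt * forces_new / m * ACC_UNIT
    new_state = MDState(
        system=new_system, velocities=v, masses=state.masses,
        temperature=state.temperature, friction=state.friction,
        time=state.time + dt, rng=state.rng,
    )
    return new_state, energy, forces_new, info


def _check_finite(forces):
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.all(np.isfinite(forces), axis=1))[0][0])
        raise RuntimeError(f"non-finite force on atom {bad}")


@dataclass
class Trajectory:
    """Sampled frames of an MD run (positions unwrapped; wrap on demand)."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    species: np.ndarray
    dt: float  # fs between stored frames
    cell: np.ndarray | None = None
    periodic: bool = False
    velocities: np.ndarray | None = None
    charges: np.ndarray | None = None  # (n_frames, n_atoms)
    energies: np.ndarray | None = None
    kinetic: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def wrapped_frames(self) -> np.ndarray:
        if not self.periodic:
            return self.frames
        inv = np.linalg.inv(self.cell)
        frac = self.frames @ inv
        return (frac % 1.0) @ self.cell


def simulate_nvt(
    state: MDState, potential, n_steps: int, dt: float = 0.5, stride: int = 1
) -> Trajectory:
    """Repeated BAOAB steps, sampling every `stride` steps.

    Positions are kept unwrapped internally (dipoles and transport need
    continuous coordinates); `Trajectory.wrapped_frames` wraps for
    structural analyses. n_steps = 0 yields a single-frame trajectory.
    """
    frames, vels, charges, energies, kinetic = [], [], [], [], []
    energy, forces, info = potential(state.system)

    def record():
        frames.append(state.system.positions.copy())
        vels.append(state.velocities.copy())
        charges.append(np.asarray(info["charges"]) if "charges" in info else None)
        energies.append(energy)
        kinetic.append(state.kinetic_energy)

    record()
    for step in range(n_steps):
        state, energy, forces, info = baoab_step(state, potential, dt, forces)
        if (step + 1) % stride == 0:
            record()
    has_q = all(q is not None for q in charges)
    return Trajectory(
        frames=np.asarray(frames),
        species=state.system.species,
        dt=dt * stride,
        cell=state.system.cell,
        periodic=state.system.periodic,
        velocities=np.asarray(vels),
        charges=np.asarray(charges) if has_q else None,
        energies=np.asarray(energies),
        kinetic=np.asarray(kinetic),
    )


def model_potential(model):
    """Adapt a Model into the potential callable used by the integrator."""

    def potential(system: AtomicSystem):
        bd = model.compute(system, forces=True)
        return bd.e_total, bd.forces, {"charges": bd.charges}

    return potential
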