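"""BAOAB dynamics, radial distribution functions, dipole spectra."""

import numpy as np
import pytest
from scipy import stats

from eqff.elements import ACC_UNIT, KBOLTZ
from eqff.geometry import AtomicSystem
from eqff.md import (
    MDState,
    Trajectory,
    baoab_step,
    initialize_state,
    model_potential,
    simulate_nvt,
)
from eqff.analysis import (
    coordination_number,
    dipole_spectrum,
    radial_distribution,
    total_dipole,
)


def _harmonic(k=0.5):
    def pot(system):
        x = system.positions
        return 0.5 * k * np.sum(x**2), -k * x, {}

    return pot


def test_zero_temperature_harmonic_oscillator_relaxes_monotonically():
    state = MDState(
        system=AtomicSystem(["H"], [[1.5, 0.0, 0.0]]),
        velocities=np.zeros((1, 3)), masses=np.array([1.008]),
        temperature=0.0, friction=0.05, rng=np.random.default_rng(0),
    )
    pot = _harmonic()
    energies = []
    forces = pot(state.system)[1]
    for _ in range(3000):
        state, e, forces, _ = baoab_step(state, pot, 1.0, forces)
        energies.append(e + state.kinetic_energy)
    energies = np.asarray(energies)
    assert energies[-1] < 1e-4 * energies[0]
    assert np.all(np.diff(energies[::50]) <= 1e-12)


def test_tiny_timestep_changes_nothing_but_the_rng():
    state = initialize_state(
        AtomicSystem(["H"], [[0.3, 0.0, 0.0]]), 300.0, friction=0.1, seed=1
    )
    x0, v0 = state.system.positions.copy(), state.velocities.copy()
    new, *_ = baoab_step(state, _harmonic(), 1e-12)
    assert np.allclose(new.system.positions, x0, atol=1e-10)
    assert np.allclose(new.velocities, v0, atol=1e-6)


def test_equipartition_at_300K():
    """<KE> per degree of freedom approaches kT/2 (short-run check; the
    long-run two-percent check runs in the acceptance suite)."""
    state = initialize_state(
        AtomicSystem(["H"], [[0.5, 0.0, 0.0]]), 300.0, friction=0.1, seed=42
    )
    pot = _harmonic()
    ke = 0.0
    n = 60_000
    forces = pot(state.system)[1]
    for _ in range(n):
        state, _, forces, _ = baoab_step(state, pot, 0.5, forces)
        ke += state.kinetic_energy
    ratio = ke / n / 3 / (KBOLTZ * 300.0 / 2)
    assert abs(ratio - 1.0) < 0.05


def test_nonfinite_forces_abort_with_the_atom_index():
    def bad(system):
        f = np.zeros_like(system.positions)
        f[0, 0] = np.nan
        return 0.0, f, {}

    state = initialize_state(AtomicSystem(["H"], [[0, 0, 0]]), 300.0, seed=0)
    with pytest.raises(RuntimeError, match="atom 0"):
        baoab_step(state, bad, 0.5)


def test_simulate_nvt_zero_steps_gives_single_frame():
    state = initialize_state(AtomicSystem(["H"], [[0, 0, 0]]), 300.0, seed=0)
    traj = simulate_nvt(state, _harmonic(), 0)
    assert traj.n_frames == 1


def test_free_particles_sample_maxwell_boltzmann():
    """Speeds of noninteracting thermostated particles follow the
    Maxwell-Boltzmann distribution (KS test)."""

    def free(system):
        return 0.0, np.zeros_like(system.positions), {}

    n_atoms, temp, m = 48, 300.0, 1.008
    system = AtomicSystem(["H"] * n_atoms, np.zeros((n_atoms, 3)))
    state = initialize_state(system, temp, friction=0.2, seed=3)
    speeds = []
    forces = np.zeros((n_atoms, 3))
    for step in range(800):
        state, _, forces, _ = baoab_step(state, free, 0.5, forces)
        if step % 40 == 0:
            speeds.append(np.linalg.norm(state.velocities, axis=1))
    speeds = np.concatenate(speeds)
    sigma = np.sqrt(KBOLTZ * temp / m * ACC_UNIT)
    ks = stats.kstest(speeds, stats.maxwell(scale=sigma).cdf)
    assert ks.statistic < 0.05


def test_thermostated_momentum_has_no_systematic_drift():
    def free(system):
        return 0.0, np.zeros_like(system.positions), {}

    n = 32
    state = initialize_state(
        AtomicSystem(["H"] * n, np.zeros((n, 3))), 300.0, friction=0.1, seed=7
    )
    forces = np.zeros((n, 3))
    drifts = []
    for _ in range(2000):
        state, _, forces, _ = baoab_step(state, free, 0.5, forces)
        drifts.append(state.velocities.mean(axis=0))
    mean_drift = np.asarray(drifts).mean(axis=0)
    thermal = np.sqrt(KBOLTZ * 300.0 / 1.008 * ACC_UNIT)
    assert np.abs(mean_drift).max() < thermal / np.sqrt(n) * 0.2


def test_model_potential_stable_for_a_water_pair_smoke(reduced_model):
    pos = np.array([
        [0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0],
        [3.0, 0.2, 0.1], [3.9, 0.4, 0.1], [2.8, 1.1, 0.2],
    ])
    system = AtomicSystem(["O", "H", "H", "O", "H", "H"], pos)
    state = initialize_state(system, 300.0, friction=0.1, seed=11)
    traj = simulate_nvt(state, model_potential(reduced_model), 300, dt=0.5)
    assert np.all(np.isfinite(traj.frames))
    assert np.all(np.isfinite(traj.energies))
    assert traj.charges is not None


# ------------------------------------------------------------------------- RDF

def _ideal_gas_traj(rng, n_atoms=60, n_frames=40, box=10.0):
    frames = rng.uniform(0, box, size=(n_frames, n_atoms, 3))
    return Trajectory(
        frames=frames, species=np.full(n_atoms, 18), dt=1.0,
        cell=np.eye(3) * box, periodic=True,
    )


def test_ideal_gas_rdf_is_flat_at_one(rng):
    traj = _ideal_gas_traj(rng)
    centers, g = radial_distribution(traj, ("Ar", "Ar"), 4.9, n_bins=24)
    # skip the first bin (few counts); 3-sigma counting-noise band
    n_pairs = 60 * 59 / 2 * traj.n_frames
    shell = 4 * np.pi * centers**2 * (centers[1] - centers[0]) / 10.0**3
    sigma = 1.0 / np.sqrt(n_pairs * shell)
    assert np.all(np.abs(g[1:] - 1.0) < 3.5 * sigma[1:])


def test_two_fixed_atoms_occupy_a_single_bin():
    d = 2.3
    frames = np.tile(
        np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), (5, 1, 1)
    )
    traj = Trajectory(frames=frames, species=np.array([8, 8]), dt=1.0,
                      cell=np.eye(3) * 12.0, periodic=True)
    centers, g = radial_distribution(traj, ("O", "O"), 5.0, n_bins=25)
    occupied = np.nonzero(g > 0)[0]
    assert len(occupied) == 1
    assert abs(centers[occupied[0]] - d) <= (centers[1] - centers[0])


def test_rdf_counting_identity(rng):
    """Integrating rho g 4 pi r^2 recovers the mean neighbor count."""
    traj = _ideal_gas_traj(rng, n_atoms=40, n_frames=30, box=9.0)
    centers, g = radial_distribution(traj, ("Ar", "Ar"), 4.4, n_bins=44)
    rho = (40 - 1) / 9.0**3  # neighbor density around a given atom
    count = coordination_number(centers, g, rho, 4.4)
    # direct recount
    direct = 0.0
    inv = np.linalg.inv(traj.cell)
    for frame in traj.frames:
        diff = frame[:, None] - frame[None, :]
        frac = diff @ inv
        frac -= np.round(frac)
        dd = np.linalg.norm(frac @ traj.cell, axis=-1)
        direct += ((dd > 0) & (dd <= 4.4)).sum() / 40
    direct /= traj.n_frames
    assert abs(count - direct) / direct < 1e-6


def test_rdf_range_and_species_validation(rng):
    traj = _ideal_gas_traj(rng)
    with pytest.raises(ValueError, match="half"):
        radial_distribution(traj, ("Ar", "Ar"), 8.0)
    with pytest.raises(ValueError, match="species"):
        radial_distribution(traj, ("O", "O"), 4.0)


# ----------------------------------------------------------------- dipole/IR

def _oscillating_dipole_traj(nu_cm=1600.0, n_frames=4096, dt=0.5):
    from eqff.analysis import C_CM_PER_FS

    t = np.arange(n_frames) * dt
    freq = nu_cm * C_CM_PER_FS  # cycles/fs
    x = 0.3 * np.sin(2 * np.pi * freq * t)
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 0, 0] = x
    frames[:, 1, 0] = -x
    charges = np.tile(np.array([0.4, -0.4]), (n_frames, 1))
    return Trajectory(frames=frames, species=np.array([1, 9]), dt=dt,
                      charges=charges)


def test_constant_dipole_has_only_zero_frequency_weight():
    traj = _oscillating_dipole_traj()
    traj.frames = np.ones_like(traj.frames)
    nu, spec = dipole_spectrum(traj)
    assert spec[1:].max() <= 1e-20 * max(spec[0], 1e-30) + 1e-20


def test_oscillating_charge_peaks_at_the_injected_frequency():
    nu_in = 1600.0
    traj = _oscillating_dipole_traj(nu_in)
    nu, spec = dipole_spectrum(traj)
    peak = nu[np.argmax(spec[1:]) + 1]
    assert abs(peak - nu_in) <= nu[1] - nu[0]


def test_doubling_the_trajectory_keeps_the_peak_within_one_bin():
    nu_in = 1600.0
    t1 = _oscillating_dipole_traj(nu_in, n_frames=2048)
    t2 = _oscillating_dipole_traj(nu_in, n_frames=4096)
    peaks = []
    for t in (t1, t2):
        nu, spec = dipole_spectrum(t)
        peaks.append(nu[np.argmax(spec[1:]) + 1])
    assert abs(peaks[0] - peaks[1]) <= max(
        np.diff(dipole_spectrum(t1)[0])[0], np.diff(dipole_spectrum(t2)[0])[0]
    )


def test_dipole_is_origin_independent_for_neutral_systems():
    traj = _oscillating_dipole_traj()
    m0 = total_dipole(traj)
    traj_shifted = _oscillating_dipole_traj()
    traj_shifted.frames = traj_shifted.frames + 42.0
    m1 = total_dipole(traj_shifted)
    assert np.allclose(m0, m1, atol=1e-10)


def test_dipole_requires_charges(rng):
    traj = _ideal_gas_traj(rng)
    with pytest.raises(ValueError, match="charges"):
        dipole_spectrum(traj)
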