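"""Independent oracles used by the test suite.

These deliberately avoid the package's internal coupling/Wigner machinery:
the rotation representation acting on spherical-harmonic blocks is
reconstructed numerically by least squares from sampled directions, and
lattice sums are evaluated by brute force.
"""

import numpy as np

from eqff.elements import COULOMB_CONSTANT
from eqff.geometry import real_spherical_harmonics


def wigner_block(l: int, rotation: np.ndarray, seed: int = 0) -> np.ndarray:
    """Matrix D with Y_l(R v) = D Y_l(v), solved from sampled directions."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(12 * (l + 1), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    y0 = real_spherical_harmonics(dirs, l)[:, l * l:(l + 1) * (l + 1)]
    y1 = real_spherical_harmonics(dirs @ rotation.T, l)[:, l * l:(l + 1) * (l + 1)]
    d, *_ = np.linalg.lstsq(y0, y1, rcond=None)
    return d.T


def brute_force_image_pairs(position, cell, r_c):
    """Count images of a single atom within r_c by scanning a large grid."""
    count = 0
    nmax = int(np.ceil(r_c / np.min(np.linalg.norm(cell, axis=1)))) + 2
    for nx in range(-nmax, nmax + 1):
        for ny in range(-nmax, nmax + 1):
            for nz in range(-nmax, nmax + 1):
                if nx == ny == nz == 0:
                    continue
                r = np.linalg.norm(np.array([nx, ny, nz]) @ cell)
                if r < r_c:
                    count += 1
    return count


def direct_lattice_sum(positions, charges, cell, n_shells: int) -> float:
    """Charge-grouped direct Coulomb lattice sum over whole cells.

    Summing complete (neutral, low-multipole) cells in an expanding cube
    converges quickly for ionic lattices; kcal/mol.
    """
    total = 0.0
    q = np.asarray(charges, dtype=float)
    for nx in range(-n_shells, n_shells + 1):
        for ny in range(-n_shells, n_shells + 1):
            for nz in range(-n_shells, n_shells + 1):
                shift = np.array([nx, ny, nz]) @ cell
                d = positions[None, :, :] + shift - positions[:, None, :]
                r = np.linalg.norm(d, axis=-1)
                if nx == ny == nz == 0:
                    np.fill_diagonal(r, np.inf)
                total += 0.5 * COULOMB_CONSTANT * np.sum(
                    q[:, None] * q[None, :] / r
                )
    return total


def random_cluster(rng, symbols=("O", "H", "H", "C", "H"), spread=1.6,
                   min_dist=0.75):
    """Random compact cluster with a minimum interatomic distance."""
    n = len(symbols)
    while True:
        pos = rng.normal(scale=spread, size=(n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            return list(symbols), pos
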