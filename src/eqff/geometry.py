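"""Atomic systems, neighbor graphs and local geometric fingerprints.

The fingerprint functions (Bessel radial basis, polynomial cutoff envelope,
real spherical harmonics) are written once and dispatch on the input type:
plain numpy arrays for analysis, or autodiff Tensors when called inside the
model so that forces are exact gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import autodiff as ad
from .elements import species_array

OVERLAP_FLOOR = 1e-6  # Angstrom; closer pairs are treated as input errors


@dataclass
class AtomicSystem:
    """Chemical species + Cartesian coordinates, optionally periodic.

    positions are in Angstrom; cell rows are the lattice vectors.
    """

    species: np.ndarray
    positions: np.ndarray
    cell: np.ndarray | None = None
    periodic: bool = False

    def __post_init__(self):
        self.species = species_array(self.species)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (len(self.species), 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.periodic:
            if self.cell is None:
                raise ValueError("periodic system requires a cell")
            self.cell = np.asarray(self.cell, dtype=np.float64)
            if self.cell.shape != (3, 3) or abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("cell must be an invertible 3x3 matrix")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def cell_heights(self) -> np.ndarray:
        """Perpendicular heights of the cell (limits for minimum image)."""
        vol = abs(np.linalg.det(self.cell))
        cross = np.cross(np.roll(self.cell, -1, axis=0), np.roll(self.cell, -2, axis=0))
        return vol / np.linalg.norm(cross, axis=1)

    def wrapped(self) -> "AtomicSystem":
        """Copy with positions wrapped into the primary cell."""
        if not self.periodic:
            return self
        frac = self.positions @ np.linalg.inv(self.cell)
        return AtomicSystem(
            self.species, (frac % 1.0) @ self.cell, self.cell, True
        )


@dataclass
class PairGraph:
    """Directed neighbor pairs within the cutoff.

    Every pair (i, j, shift) has its reverse (j, i, -shift); displacements
    point from src to dst and satisfy displacement = R_dst - R_src + shift@cell.
    """

    src: np.ndarray
    dst: np.ndarray
    displacement: np.ndarray
    distance: np.ndarray
    cutoff: float
    n_atoms: int
    shifts: np.ndarray | None = None
    _reverse: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.src)

    def reverse_index(self) -> np.ndarray:
        """Index of the reverse pair (j, i, -shift) for each pair."""
        if self._reverse is None:
            shifts = (
                self.shifts
                if self.shifts is not None
                else np.zeros((self.n_pairs, 3), dtype=np.intp)
            )
            lookup = {
                (int(i), int(j), *map(int, s)): k
                for k, (i, j, s) in enumerate(zip(self.src, self.dst, shifts))
            }
            rev = np.empty(self.n_pairs, dtype=np.intp)
            for k, (i, j, s) in enumerate(zip(self.src, self.dst, shifts)):
                rev[k] = lookup[(int(j), int(i), *map(int, -s))]
            self._reverse = rev
        return self._reverse


def build_pair_graph(
    system: AtomicSystem,
    r_c: float,
    replicate: bool = True,
    floor: float = OVERLAP_FLOOR,
) -> PairGraph:
    """All directed pairs with 0 < R_ij < r_c (half-open, self excluded).

    For periodic systems lattice images are enumerated explicitly, which
    also covers cells smaller than 2 r_c when `replicate` is true.
    Ordering is deterministic: sorted by (src, dst, image).
    """
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    pos = system.positions
    n = system.n_atoms

    if system.periodic:
        heights = system.cell_heights()
        if not replicate and r_c >= 0.5 * heights.min():
            raise ValueError(
                "cutoff exceeds half the smallest cell height; "
                "enable image replication"
            )
        nmax = np.ceil(r_c / heights).astype(int)
        shift_list = [
            np.array(s)
            for s in product(*(range(-m, m + 1) for m in nmax))
        ]
    else:
        shift_list = [np.zeros(3, dtype=int)]

    srcs, dsts, disps, shifts = [], [], [], []
    for shift in shift_list:
        offset = shift @ system.cell if system.periodic else np.zeros(3)
        diff = pos[None, :, :] - pos[:, None, :] + offset  # (i, j) -> R_j - R_i
        dist = np.linalg.norm(diff, axis=-1)
        mask = dist < r_c
        if not shift.any():
            np.fill_diagonal(mask, False)
            close = (dist < floor) & ~np.eye(n, dtype=bool)
        else:
            close = dist < floor
        if close.any():
            i, j = np.argwhere(close)[0]
            raise ValueError(
                f"atoms {int(i)} and {int(j)} overlap "
                f"(distance below {floor} Angstrom)"
            )
        i, j = np.nonzero(mask)
        srcs.append(i)
        dsts.append(j)
        disps.append(diff[i, j])
        shifts.append(np.broadcast_to(shift, (len(i), 3)))

    src = np.concatenate(srcs).astype(np.intp)
    dst = np.concatenate(dsts).astype(np.intp)
    disp = np.concatenate(disps)
    shift = np.concatenate(shifts).astype(np.intp)
    order = np.lexsort((shift[:, 2], shift[:, 1], shift[:, 0], dst, src))
    src, dst, disp, shift = src[order], dst[order], disp[order], shift[order]
    return PairGraph(
        src=src,
        dst=dst,
        displacement=disp,
        distance=np.linalg.norm(disp, axis=-1),
        cutoff=float(r_c),
        n_atoms=n,
        shifts=shift if system.periodic else None,
    )


# ---------------------------------------------------------------------------
# fingerprints (backend-generic: numpy arrays or autodiff Tensors)

def _is_tensor(x) -> bool:
    return isinstance(x, ad.Tensor)


def _sin(x):
    return ad.sin(x) if _is_tensor(x) else np.sin(x)


def polynomial_envelope(r, r_c: float, p: int = 3):
    """Smooth cutoff u(r/r_c): u(0)=1, u and its first p-1 derivatives
    vanish at r_c (polynomial envelope of the Bessel-basis construction)."""
    if p < 2:
        raise ValueError("envelope parameter p must be >= 2")
    d = r * (1.0 / r_c)
    a = (p + 1) * (p + 2) / 2.0
    b = float(p * (p + 2))
    c = p * (p + 1) / 2.0
    return 1.0 - a * d**p + b * d ** (p + 1) - c * d ** (p + 2)


def bessel_basis(r, r_c: float, n_basis: int, p: int = 3, with_envelope=True):
    """Spherical Bessel radial basis sqrt(2/r_c) sin(n pi r / r_c)/r,
    multiplied by the polynomial envelope. Shape (..., n_basis)."""
    if n_basis < 1:
        raise ValueError("need at least one basis function")
    freqs = np.arange(1, n_basis + 1) * np.pi / r_c
    if _is_tensor(r):
        rcol = ad.reshape(r, r.shape + (1,))
        out = _sin(rcol * ad.constant(freqs)) / rcol * np.sqrt(2.0 / r_c)
        if with_envelope:
            env = polynomial_envelope(rcol, r_c, p)
            out = out * env
        return out
    rcol = np.asarray(r)[..., None]
    out = np.sin(rcol * freqs) / rcol * np.sqrt(2.0 / r_c)
    if with_envelope:
        out = out * polynomial_envelope(rcol, r_c, p)
    return out


def real_spherical_harmonics(vectors, l_max: int):
    """Component-normalized real spherical harmonics of unit vectors.

    Returns shape (..., (l_max+1)^2), blocks ordered l = 0..l_max with
    m = -l..l inside each block; each block satisfies |Y_l|^2 = 2l+1
    (component normalization, i.e. sqrt(4 pi) times orthonormal real
    harmonics). Supported up to l_max = 2, which covers the model family.
    """
    if l_max < 0 or l_max > 2:
        raise ValueError("real_spherical_harmonics supports 0 <= l_max <= 2")
    tensor = _is_tensor(vectors)
    if tensor:
        norms = ad.norm(vectors, axis=-1).data
    else:
        vectors = np.asarray(vectors, dtype=np.float64)
        norms = np.linalg.norm(vectors, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no direction")
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("inputs must be unit vectors")

    if tensor:
        x = ad.narrow(vectors, vectors.ndim - 1, 0, 1)
        y = ad.narrow(vectors, vectors.ndim - 1, 1, 1)
        z = ad.narrow(vectors, vectors.ndim - 1, 2, 1)
        one = ad.constant(np.ones(x.shape))
        cat = ad.concatenate
    else:
        x, y, z = (vectors[..., k:k + 1] for k in range(3))
        one = np.ones_like(x)
        cat = lambda blocks, axis: np.concatenate(blocks, axis=axis)

    blocks = [one]
    if l_max >= 1:
        s3 = np.sqrt(3.0)
        blocks += [s3 * y, s3 * z, s3 * x]
    if l_max >= 2:
        s15 = np.sqrt(15.0)
        blocks += [
            s15 * (x * y),
            s15 * (y * z),
            np.sqrt(5.0) / 2.0 * (3.0 * (z * z) - 1.0),
            s15 * (x * z),
            s15 / 2.0 * (x * x - y * y),
        ]
    return cat(blocks, axis=-1 if not tensor else vectors.ndim - 1)


@dataclass
class RadialFingerprint:
    """Per-pair radial basis, cutoff envelope and spherical harmonics."""

    basis: np.ndarray  # (n_pairs, n_basis), includes the envelope
    envelope: np.ndarray  # (n_pairs,)
    harmonics: np.ndarray  # (n_pairs, (l_max+1)^2)


def radial_fingerprint(
    graph: PairGraph, n_basis: int = 10, p: int = 3, l_max: int = 2
) -> RadialFingerprint:
    """Numpy fingerprints of a pair graph (the model recomputes these with
    Tensors internally so forces can differentiate through them)."""
    r = graph.distance
    unit = graph.displacement / r[:, None]
    return RadialFingerprint(
        basis=bessel_basis(r, graph.cutoff, n_basis, p),
        envelope=polynomial_envelope(r, graph.cutoff, p),
        harmonics=real_spherical_harmonics(unit, l_max),
    )
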