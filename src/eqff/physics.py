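"""Physics module: charge handling, damped electrostatics, dispersion, Ewald.

The neural network predicts per-atom charges and volume ratios; this module
turns them into energies through physically-motivated terms:

* charge scaling by a universal factor eps (compensating the lack of
  higher-order multipoles);
* a smooth "valence hole" correction that prevents an atom from losing
  more than a fraction (default 95%) of its valence electrons, conserving
  total charge exactly by transferring charge back from the neighbors that
  drained it, proportionally to the drained amount;
* a charge-penetration-corrected Coulomb term: valence populations N - q
  interact through damped factors f(r) = 1 - exp(-k r), reducing to the
  bare point-charge k_e q_i q_j / R at long range;
* Tkatchenko-Scheffler pairwise dispersion -C6_ij/R^6 with homonuclear C6
  and polarizabilities scaled by the predicted volume ratios, the standard
  combination rule, and a sigmoid damping based on volume-scaled van der
  Waals radii;
* Ewald summation for point-charge electrostatics under periodic boundary
  conditions.

All energy-producing functions accept autodiff Tensors so forces are exact
gradients; scalars/ndarrays work too for quick evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcinv

from . import autodiff as ad
from .autodiff import Tensor
from .elements import COULOMB_CONSTANT, load_free_atom_table, symbol
from .geometry import AtomicSystem, PairGraph, build_pair_graph


@dataclass
class FFParameters:
    """Universal physics parameters + free-atom table.

    eps scales all NN charges; alpha, beta (1/Angstrom) are the Coulomb
    damping rates; gamma, s parameterize the dispersion damping sigmoid.
    The defaults for gamma and s are the constants of the original TS
    damping; alpha and beta default to bond-scale damping; all five are
    trainable in the last training stage.
    """

    eps: float = 1.0
    alpha: float = 4.0
    beta: float = 4.0
    gamma: float = 20.0
    s: float = 0.94
    valence_fraction: float = 0.95
    valence_width: float = 0.05  # e; half-width of the smooth hinge
    dispersion_cutoff: float = 12.0  # Angstrom
    dispersion_switch_on: float = 10.0  # start of the smooth switch-off
    ewald_accuracy: float = 1e-5
    free_atoms: dict = field(default_factory=load_free_atom_table)

    def __post_init__(self):
        if self.eps <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("eps, alpha, beta must be positive")

    def atom_arrays(self, species) -> dict:
        """Free-atom parameter arrays aligned with a species array."""
        cols = ("n_valence", "alpha_free", "c6_free", "r_vdw_free", "v_free")
        out = {c: [] for c in cols}
        for z in np.asarray(species, dtype=np.intp):
            sym = symbol(int(z))
            if sym not in self.free_atoms:
                raise ValueError(f"no free-atom parameters for element {sym}")
            for c in cols:
                out[c].append(self.free_atoms[sym][c])
        return {c: np.asarray(v) for c, v in out.items()}


# ---------------------------------------------------------------------------
# charges

def scale_charges(q, eps):
    """q_i <- eps * q_i (preserves neutrality exactly)."""
    return q * eps


def correct_valence(
    q: Tensor,
    pair_drain: Tensor,
    graph: PairGraph,
    n_valence: np.ndarray,
    fraction: float = 0.95,
    width: float = 0.05,
):
    """Smoothly enforce q_i <= fraction * N_i, conserving total charge.

    pair_drain[k] for the directed pair k = (i, j) is the net charge atom i
    acquired through its exchange with j (positive means j took electrons
    from i). The smooth valence hole h_i = hinge(q_i - fraction*N_i) is
    given back to atom i by the neighbors that drained it, proportionally
    to the amount drained. If an atom has a hole but no neighbor drained
    charge (a degenerate input), its charge is left unchanged with a
    warning.
    """
    q = ad.astensor(q)
    pair_drain = ad.astensor(pair_drain)
    n = graph.n_atoms
    hole = ad.relu_smooth(q - ad.constant(fraction * n_valence), width)
    drained = ad.relu_smooth(pair_drain, width)
    denom = ad.segment_sum(drained, graph.src, n)

    need = hole.data > 0.0
    ok = need & (denom.data > 1e-12)
    if np.any(need & ~ok):
        warnings.warn(
            "valence hole with no draining neighbor; charge left unchanged",
            stacklevel=2,
        )
    sel = ok.astype(float)
    hole_sel = hole * ad.constant(sel)
    inv_denom = ad.power(denom + ad.constant(1.0 - sel), -1.0)
    give = ad.take(hole_sel * inv_denom, graph.src, 0) * drained
    return q + (-hole_sel) + ad.segment_sum(give, graph.dst, n), hole_sel


# ---------------------------------------------------------------------------
# pairwise terms

def damping(r, rate):
    """f(r) = 1 - exp(-rate * r); monotone, 0 at r=0, -> 1 at infinity."""
    if isinstance(r, Tensor):
        return 1.0 - ad.exp(r * (-rate))
    return 1.0 - np.exp(-rate * np.asarray(r, dtype=float))


def coulomb_point(q_i, q_j, r):
    """Bare point-charge Coulomb energy k_e q_i q_j / r (kcal/mol)."""
    return COULOMB_CONSTANT * q_i * q_j / r


def coulomb_cp(q_i, q_j, n_i, n_j, r, alpha, beta):
    """Charge-penetration Coulomb pair energy (kcal/mol).

    Valence nuclei +N and electron populations -(N - q) interact with
    damped factors; symmetric in (i <-> j) and asymptotically equal to
    the bare point-charge energy.
    """
    rdata = r.data if isinstance(r, Tensor) else np.asarray(r, dtype=float)
    if np.any(rdata <= 0):
        raise ValueError("pair distance must be positive")
    fa = damping(r, alpha)
    fb = damping(r, beta)
    core = (
        n_i * n_j
        - n_i * (n_j - q_j) * fa
        - n_j * (n_i - q_i) * fa
        + (n_i - q_i) * (n_j - q_j) * fb * fb
    )
    return COULOMB_CONSTANT * core / r


def vdw_radius(volume_ratio, r_vdw_free):
    """Environment-scaled vdW radius: cube-root volume scaling."""
    data = (
        volume_ratio.data
        if isinstance(volume_ratio, Tensor)
        else np.asarray(volume_ratio, dtype=float)
    )
    if np.any(data <= 0):
        raise ValueError("volume ratio must be positive")
    return volume_ratio ** (1.0 / 3.0) * r_vdw_free


def ts_combination_rule(c6_ii, c6_jj, alpha_i, alpha_j):
    """Heteronuclear C6 from homonuclear C6 and polarizabilities."""
    return 2.0 * c6_ii * c6_jj / (
        (alpha_j / alpha_i) * c6_ii + (alpha_i / alpha_j) * c6_jj
    )


def dispersion_sigmoid(r, r0, gamma, s):
    """TS damping: 1/(1 + exp(-gamma (r/(s r0) - 1))); 0 at r=0, 1 at inf."""
    return ad.sigmoid(ad.astensor(gamma * (r / (s * r0) - 1.0))) \
        if isinstance(r, Tensor) or isinstance(r0, Tensor) \
        else 1.0 / (1.0 + np.exp(-gamma * (r / (s * r0) - 1.0)))


def ts_dispersion(
    ratio_i, ratio_j, r,
    c6_i, c6_j, alpha_free_i, alpha_free_j, rvdw_i, rvdw_j,
    gamma: float, s: float,
):
    """Pairwise TS dispersion energy -damp(r) C6_ij / r^6 (kcal/mol).

    Homonuclear coefficients are volume-scaled: C6_ii = ratio^2 C6_free,
    alpha_i = ratio * alpha_free; vdW radii scale with the cube root.
    """
    c6_ii = ratio_i * ratio_i * c6_i
    c6_jj = ratio_j * ratio_j * c6_j
    a_i = ratio_i * alpha_free_i
    a_j = ratio_j * alpha_free_j
    c6_ij = ts_combination_rule(c6_ii, c6_jj, a_i, a_j)
    r0 = vdw_radius(ratio_i, rvdw_i) + vdw_radius(ratio_j, rvdw_j)
    damp = dispersion_sigmoid(r, r0, gamma, s)
    return -damp * c6_ij * r ** -6.0


def ts_dispersion_elements(ratio_i, ratio_j, elements_i, elements_j, r,
                           params: FFParameters):
    """Element-resolved wrapper around ts_dispersion."""
    ai = params.atom_arrays(np.atleast_1d(elements_i))
    aj = params.atom_arrays(np.atleast_1d(elements_j))
    return ts_dispersion(
        ratio_i, ratio_j, r,
        ai["c6_free"], aj["c6_free"],
        ai["alpha_free"], aj["alpha_free"],
        ai["r_vdw_free"], aj["r_vdw_free"],
        params.gamma, params.s,
    )


def dispersion_switch(r, r_on: float, r_off: float):
    """C2 smoothstep from 1 (r <= r_on) to 0 (r >= r_off)."""
    rdata = r.data if isinstance(r, Tensor) else np.asarray(r, dtype=float)
    t_raw = (r - r_on) * (1.0 / (r_off - r_on))
    t_data = np.clip((rdata - r_on) / (r_off - r_on), 0.0, 1.0)
    if isinstance(r, Tensor):
        t = ad.where(t_data <= 0.0, ad.constant(np.zeros(rdata.shape)),
                     ad.where(t_data >= 1.0, ad.constant(np.ones(rdata.shape)),
                              t_raw))
    else:
        t = t_data
    s = t * t * t * (10.0 + t * (-15.0 + 6.0 * t))
    return 1.0 - s


@lru_cache(maxsize=8)
def dispersion_tail_integral(r_on: float, r_off: float) -> float:
    """Integral of (1 - switch(r)) / r^4 from r_on to infinity.

    Used for the analytic tail correction of periodic dispersion:
    E_tail = -(2 pi / V) * sum_ij C6_ij * I, assuming g(r) = 1 beyond the
    switching region.
    """
    inner, _ = quad(
        lambda r: (1.0 - dispersion_switch(r, r_on, r_off)) / r**4,
        r_on, r_off,
    )
    return inner + 1.0 / (3.0 * r_off**3)


# ---------------------------------------------------------------------------
# Ewald summation

def ewald_parameters(cell: np.ndarray, accuracy: float, r_cut: float | None = None):
    """Splitting parameter, real-space cutoff and k-space cutoff from the
    requested relative accuracy."""
    heights = np.abs(np.linalg.det(cell)) / np.linalg.norm(
        np.cross(np.roll(cell, -1, axis=0), np.roll(cell, -2, axis=0)), axis=1
    )
    if r_cut is None:
        r_cut = max(6.0, min(10.0, 0.49 * heights.min()))
    # the per-term truncation threshold is set two orders below the target
    # so that accumulated truncation error stays within it
    strict = 0.01 * accuracy
    eta = erfcinv(strict) / r_cut
    k_cut = 2.0 * eta * np.sqrt(-np.log(strict))
    return float(eta), float(r_cut), float(k_cut)


def _k_vectors(cell: np.ndarray, k_cut: float) -> np.ndarray:
    recip = 2.0 * np.pi * np.linalg.inv(cell).T
    nmax = np.ceil(k_cut / np.linalg.norm(recip, axis=1) * 1.5).astype(int) + 1
    grids = np.meshgrid(*(np.arange(-m, m + 1) for m in nmax), indexing="ij")
    ints = np.stack([g.ravel() for g in grids], axis=1)
    ints = ints[np.any(ints != 0, axis=1)]
    k = ints @ recip
    return k[np.linalg.norm(k, axis=1) < k_cut]


def ewald_coulomb(
    system: AtomicSystem,
    charges,
    accuracy: float = 1e-5,
    eta: float | None = None,
    positions: Tensor | None = None,
) -> Tensor:
    """Point-charge Coulomb energy of a neutral periodic cell (kcal/mol).

    Real-space, reciprocal and self terms; cutoffs are chosen from the
    accuracy target and the result is independent of the splitting
    parameter within that target. `positions` may be supplied as a Tensor
    to differentiate through (defaults to the system's coordinates).
    """
    if not system.periodic:
        raise ValueError("Ewald summation requires a periodic system")
    q = ad.astensor(charges)
    if abs(q.data.sum()) > 1e-8 * max(1.0, np.abs(q.data).max()):
        raise ValueError("Ewald summation requires a neutral cell")
    cell = system.cell
    vol = abs(np.linalg.det(cell))
    eta_auto, r_cut, k_cut = ewald_parameters(cell, accuracy)
    if eta is None:
        eta = eta_auto
    else:
        # keep the requested accuracy when the user overrides the splitting
        strict = 0.01 * accuracy
        r_cut = float(erfcinv(strict) / eta)
        k_cut = float(2.0 * eta * np.sqrt(-np.log(strict)))
    pos = positions if positions is not None else ad.constant(system.positions)

    # real space: directed image pairs within r_cut, counted half
    graph = build_pair_graph(system, r_cut, replicate=True)
    qi = ad.take(q, graph.src, 0)
    qj = ad.take(q, graph.dst, 0)
    disp = ad.take(pos, graph.dst, 0) + (-ad.take(pos, graph.src, 0))
    if graph.shifts is not None:
        disp = disp + ad.constant(graph.shifts @ cell)
    r = ad.norm(disp, axis=-1)
    e_real = 0.5 * COULOMB_CONSTANT * ad.tsum(qi * qj * ad.erfc(eta * r) / r)

    # reciprocal space
    kvecs = _k_vectors(cell, k_cut)
    k2 = np.sum(kvecs**2, axis=1)
    weights = np.exp(-k2 / (4.0 * eta**2)) / k2
    phase = ad.einsum("pd,kd->pk", pos, ad.constant(kvecs))
    re_s = ad.einsum("p,pk->k", q, ad.cos(phase))
    im_s = ad.einsum("p,pk->k", q, ad.sin(phase))
    e_recip = (2.0 * np.pi / vol) * COULOMB_CONSTANT * ad.tsum(
        ad.constant(weights) * (re_s * re_s + im_s * im_s)
    )

    e_self = -COULOMB_CONSTANT * eta / np.sqrt(np.pi) * ad.tsum(q * q)
    return e_real + e_recip + e_self
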