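"""Synthetic labeled datasets emulating coupled-cluster-style records.

Real training data for this kind of model consists of (species,
coordinates, total energy, forces, per-atom charges, per-atom volume
ratios) records for monomers, plus dimer interaction energies. At desk
scale those are produced here by an analytic surrogate oracle:

* energy = sum of isolated-atom reference constants
         + Morse terms over template bonds
         + damped point-charge Coulomb over all pairs
         + damped -C6/r^6 dispersion over all pairs;
* forces = exact analytic gradient (via the autodiff engine);
* charges from a fixed per-bond charge-transfer rule modulated by a
  smooth envelope of the bond length (neutral per molecule, zero at
  dissociation);
* volume ratios = smooth decreasing function of a coordination number.

Geometries are template molecules with Gaussian internal deformations
(including large stretches into the dissociation region) and random rigid
placement; dimer records carry the monomer partition and the surrogate
interaction energy. Everything is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .elements import COULOMB_CONSTANT
from .geometry import AtomicSystem, polynomial_envelope
from .training import TrainingRecord

# isolated-atom reference energies of the surrogate (kcal/mol)
SURROGATE_REFERENCES = {"H": -313.6, "O": -900.0, "F": -1200.0}

# Morse parameters per bond type: (well depth kcal/mol, width 1/A, r0 A)
MORSE = {
    ("H", "H"): (109.5, 1.94, 0.741),
    ("O", "H"): (118.0, 2.20, 0.960),
    ("O", "O"): (120.0, 2.66, 1.208),
    ("H", "F"): (136.0, 2.22, 0.917),
}

# dispersion coefficients (kcal/mol A^6) per element pair
C6 = {
    ("H", "H"): 40.0,
    ("O", "H"): 90.0,
    ("O", "O"): 200.0,
    ("H", "F"): 60.0,
    ("F", "F"): 130.0,
    ("O", "F"): 160.0,
}

CHARGE_ENVELOPE_RANGE = 6.0  # Angstrom; bond charge transfer dies off here
COULOMB_DAMP = 2.5  # 1/A
DISPERSION_SOFTEN = 2.5  # A; -C6/(r^6 + d^6) regularization


def _pair_key(a: str, b: str):
    return (a, b) if (a, b) in MORSE or (a, b) in C6 else (b, a)


@dataclass(frozen=True)
class MoleculeTemplate:
    name: str
    symbols: tuple
    positions: np.ndarray  # equilibrium geometry (n, 3)
    bonds: tuple  # ((i, j, transfer), ...): transfer e moved from j to i


def _water():
    r, theta = 0.9572, np.deg2rad(104.52)
    return MoleculeTemplate(
        "H2O",
        ("O", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [r, 0.0, 0.0],
            [r * np.cos(theta), r * np.sin(theta), 0.0],
        ]),
        ((0, 1, 0.33), (0, 2, 0.33)),
    )


TEMPLATES = {
    "H2": MoleculeTemplate(
        "H2", ("H", "H"), np.array([[0.0, 0.0, 0.0], [0.741, 0.0, 0.0]]),
        ((0, 1, 0.0),),
    ),
    "OH": MoleculeTemplate(
        "OH", ("O", "H"), np.array([[0.0, 0.0, 0.0], [0.960, 0.0, 0.0]]),
        ((0, 1, 0.30),),
    ),
    "HF": MoleculeTemplate(
        "HF", ("H", "F"), np.array([[0.0, 0.0, 0.0], [0.917, 0.0, 0.0]]),
        ((1, 0, 0.40),),
    ),
    "O2": MoleculeTemplate(
        "O2", ("O", "O"), np.array([[0.0, 0.0, 0.0], [1.208, 0.0, 0.0]]),
        ((0, 1, 0.0),),
    ),
    "H2O": _water(),
}


class SurrogateOracle:
    """Analytic reference potential used to label synthetic records."""

    def __init__(self, symbols, bonds):
        self.symbols = tuple(symbols)
        self.bonds = tuple(bonds)
        for s in self.symbols:
            if s not in SURROGATE_REFERENCES:
                raise ValueError(f"surrogate does not cover element {s}")

    def charges(self, positions) -> Tensor:
        """Per-atom charges from enveloped bond charge transfers."""
        pos = ad.astensor(positions)
        n = len(self.symbols)
        q = ad.constant(np.zeros(n))
        for i, j, t in self.bonds:
            if t == 0.0:
                continue
            d = pos[np.array([i])] + (-pos[np.array([j])])
            r = ad.norm(d, axis=-1)
            rdat = float(r.data[0])
            if rdat >= CHARGE_ENVELOPE_RANGE:
                continue
            dq = -t * polynomial_envelope(r, CHARGE_ENVELOPE_RANGE, 3)
            contrib = ad.scatter_add(
                ad.concatenate([dq, -dq]), np.array([i, j]), (n,)
            )
            q = q + contrib
        return q

    def volume_ratios(self, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        diff = pos[:, None, :] - pos[None, :, :]
        r2 = np.sum(diff**2, axis=-1)
        coord = np.exp(-r2 / 1.8**2).sum(axis=1) - 1.0
        return 0.5 + 0.5 * np.exp(-0.3 * coord)

    def energy(self, positions: Tensor) -> Tensor:
        pos = ad.astensor(positions)
        n = len(self.symbols)
        e = ad.constant(sum(SURROGATE_REFERENCES[s] for s in self.symbols))
        # bonded Morse terms
        for i, j, _ in self.bonds:
            key = _pair_key(self.symbols[i], self.symbols[j])
            de, a, r0 = MORSE[key]
            d = pos[np.array([i])] + (-pos[np.array([j])])
            r = ad.norm(d, axis=-1)
            x = ad.exp(-a * (r - r0))
            e = e + ad.tsum(de * (x * x - 2.0 * x))
        if n < 2:
            return e
        # nonbonded terms over all pairs
        iu, ju = np.triu_indices(n, 1)
        d = ad.take(pos, ju, 0) + (-ad.take(pos, iu, 0))
        r = ad.norm(d, axis=-1)
        q = self.charges(pos)
        qq = ad.take(q, iu, 0) * ad.take(q, ju, 0)
        damp = 1.0 - ad.exp(-COULOMB_DAMP * r)
        e = e + ad.tsum(COULOMB_CONSTANT * qq * damp / r)
        c6 = np.array(
            [C6[_pair_key(self.symbols[i], self.symbols[j])] for i, j in zip(iu, ju)]
        )
        e = e + ad.tsum(
            -ad.constant(c6) / (r ** 6.0 + DISPERSION_SOFTEN**6)
        )
        return e

    def energy_forces(self, positions):
        pos = Tensor(np.asarray(positions, dtype=float))
        e = self.energy(pos)
        f = -ad.grad(e, pos).data
        return float(e.data), f

    def label(self, positions) -> dict:
        e, f = self.energy_forces(positions)
        return {
            "energy": e,
            "forces": f,
            "charges": self.charges(positions).data.copy(),
            "volume_ratios": self.volume_ratios(positions),
        }


@dataclass
class SynthConfig:
    """What the generator produces (defaults define the study conditions)."""

    templates: tuple = ("H2", "OH")
    n_records: int = 2000
    dimer_fraction: float = 0.0  # fraction of records that are dimers
    stretch_sigma: float = 1.2  # A, dissociative bond-stretch scale
    near_eq_sigma: float = 0.08  # A, vibrational-scale deformation
    near_eq_fraction: float = 0.6
    dimer_separation: tuple = (2.5, 6.5)  # A, center-of-mass distance range
    polyatomic_jitter: float = 0.12  # A, Cartesian deformation for n>2


def _deform(template: MoleculeTemplate, rng, cfg: SynthConfig) -> np.ndarray:
    pos = template.positions.copy()
    if len(template.symbols) == 2:
        r0 = np.linalg.norm(pos[1] - pos[0])
        if rng.random() < cfg.near_eq_fraction:
            r = max(0.45 * r0, r0 + rng.normal(scale=cfg.near_eq_sigma))
        else:
            r = r0 + abs(rng.normal(scale=cfg.stretch_sigma))
        pos[1] = pos[0] + np.array([r, 0.0, 0.0])
    else:
        pos = pos + rng.normal(scale=cfg.polyatomic_jitter, size=pos.shape)
    return pos


def _rigid_place(pos, rng, offset=None):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    out = (pos - pos.mean(axis=0)) @ R.T
    if offset is not None:
        out = out + offset
    return out


def synthetic_dataset(config: SynthConfig, seed: int) -> list:
    """Generate labeled monomer/dimer records; deterministic per seed."""
    rng = np.random.default_rng(seed)
    for name in config.templates:
        if name not in TEMPLATES:
            raise ValueError(f"unknown molecule template {name!r}")
    records = []
    for _ in range(config.n_records):
        if rng.random() < config.dimer_fraction:
            records.append(_dimer_record(rng, config))
        else:
            records.append(_monomer_record(rng, config))
    return records


def _monomer_record(rng, cfg) -> TrainingRecord:
    template = TEMPLATES[rng.choice(cfg.templates)]
    pos = _rigid_place(_deform(template, rng, cfg), rng)
    oracle = SurrogateOracle(template.symbols, template.bonds)
    lab = oracle.label(pos)
    return TrainingRecord(
        system=AtomicSystem(list(template.symbols), pos),
        energy=lab["energy"],
        forces=lab["forces"],
        charges=lab["charges"],
        volume_ratios=lab["volume_ratios"],
        kind="total",
    )


def _dimer_record(rng, cfg) -> TrainingRecord:
    ta = TEMPLATES[rng.choice(cfg.templates)]
    tb = TEMPLATES[rng.choice(cfg.templates)]
    pa = _rigid_place(_deform(ta, rng, cfg), rng)
    sep = rng.uniform(*cfg.dimer_separation)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pb = _rigid_place(_deform(tb, rng, cfg), rng, offset=sep * direction)
    symbols = tuple(ta.symbols) + tuple(tb.symbols)
    na = len(ta.symbols)
    bonds = tuple(ta.bonds) + tuple(
        (i + na, j + na, t) for i, j, t in tb.bonds
    )
    pos = np.vstack([pa, pb])
    dimer = SurrogateOracle(symbols, bonds)
    mono_a = SurrogateOracle(ta.symbols, ta.bonds)
    mono_b = SurrogateOracle(tb.symbols, tb.bonds)
    e_d, f_d = dimer.energy_forces(pos)
    e_a, _ = mono_a.energy_forces(pa)
    e_b, _ = mono_b.energy_forces(pb)
    return TrainingRecord(
        system=AtomicSystem(list(symbols), pos),
        energy=e_d,
        forces=f_d,
        charges=dimer.charges(pos).data.copy(),
        volume_ratios=dimer.volume_ratios(pos),
        kind="interaction",
        monomer_partition=(np.arange(na), np.arange(na, len(symbols))),
        interaction_energy=e_d - e_a - e_b,
    )
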