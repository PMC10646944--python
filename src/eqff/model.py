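"""Full hybrid potential: embedding -> heads -> physics -> energy/forces.

The total energy of a configuration is

    V = sum_i E^NN_i  +  sum_(i<j) E^C_ij  +  sum_(i<j) E^D_ij  +  E_ref

where E^NN_i are the aggregated pairwise neural-network energies (strictly
local, cutoff r_c), E^C is the charge-penetration Coulomb term using the
scaled and valence-corrected NN charges, E^D the volume-scaled TS
dispersion, and E_ref the sum of isolated-atom reference energies. Forces
are exact gradients of the implemented energy via the autodiff engine.

Range policy: the bare point-charge Coulomb acts between all pairs (Ewald
under periodic boundary conditions); the charge-penetration correction
(E^C - bare), which decays exponentially, is applied within r_c only; the
dispersion sum uses a smooth switch-off ending at a dispersion cutoff,
plus an analytic tail correction in periodic systems. A fully dissociated
system (all pairs beyond every cutoff) therefore returns exactly the
reference-energy sum with zero forces.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .allegro import AllegroConfig, embed_pairs, init_allegro_params
from .autodiff import Tensor
from .elements import symbol
from .geometry import AtomicSystem, build_pair_graph
from .heads import (
    DEFAULT_HEAD_HIDDEN,
    OUTPUT_NAMES,
    aggregate,
    head_forward,
    init_head_params,
    reference_energy,
)
from .physics import (
    FFParameters,
    correct_valence,
    coulomb_cp,
    coulomb_point,
    dispersion_switch,
    dispersion_tail_integral,
    ewald_coulomb,
    scale_charges,
    ts_dispersion,
)

PHYSICS_PARAM_NAMES = ("eps", "alpha", "beta", "gamma", "s")


@dataclass
class EnergyBreakdown:
    """Energy decomposition and forces of one configuration (numpy)."""

    e_nn: float
    e_coulomb: float
    e_dispersion: float
    e_reference: float
    e_total: float
    forces: np.ndarray | None
    charges: np.ndarray
    volume_ratios: np.ndarray

    def as_dict(self) -> dict:
        d = {
            "E_NN": self.e_nn,
            "E_coulomb": self.e_coulomb,
            "E_dispersion": self.e_dispersion,
            "E_reference": self.e_reference,
            "E_total": self.e_total,
        }
        return d


@dataclass
class ModelConfig:
    allegro: AllegroConfig = field(default_factory=AllegroConfig)
    head_hidden: tuple = DEFAULT_HEAD_HIDDEN
    outputs: tuple = OUTPUT_NAMES
    reference_energies: dict = field(default_factory=dict)
    ff: FFParameters = field(default_factory=FFParameters)

    def to_dict(self) -> dict:
        d = {
            "allegro": asdict(self.allegro),
            "head_hidden": list(self.head_hidden),
            "outputs": list(self.outputs),
            "reference_energies": dict(self.reference_energies),
            "ff": {
                k: v
                for k, v in asdict(self.ff).items()
                if k != "free_atoms"
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        allegro = AllegroConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["allegro"].items()
        })
        return cls(
            allegro=allegro,
            head_hidden=tuple(d["head_hidden"]),
            outputs=tuple(d["outputs"]),
            reference_energies=dict(d["reference_energies"]),
            ff=FFParameters(**d["ff"]),
        )


class Model:
    """A hybrid NN/FF potential with named parameters and seeded init."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 params: dict | None = None):
        self.config = config if config is not None else ModelConfig()
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(seed)
            self.params = init_allegro_params(self.config.allegro, rng)
            self.params.update(
                init_head_params(
                    rng,
                    self.config.allegro.n_scalar,
                    self.config.head_hidden,
                    self.config.outputs,
                )
            )
            ff = self.config.ff
            for name in PHYSICS_PARAM_NAMES:
                self.params[f"physics.log_{name}"] = Tensor(
                    np.log(getattr(ff, name))
                )

    # -- bookkeeping --------------------------------------------------
    def parameter_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def parameter_groups(self) -> dict:
        groups = {"embedding": [], "output": [], "physics": []}
        for name in self.params:
            if name.startswith("head."):
                groups["output"].append(name)
            elif name.startswith("physics."):
                groups["physics"].append(name)
            else:
                groups["embedding"].append(name)
        return groups

    def ff_values(self) -> dict:
        """Current (possibly trained) universal physics parameters."""
        return {
            name: ad.exp(self.params[f"physics.log_{name}"])
            for name in PHYSICS_PARAM_NAMES
        }

    # -- forward ------------------------------------------------------
    def atomic_properties(self, system: AtomicSystem, positions=None):
        cfg = self.config.allegro
        graph = build_pair_graph(system, cfg.r_c)
        pos = positions if positions is not None else ad.constant(system.positions)
        emb = embed_pairs(self.params, cfg, system.species, graph, pos,
                          system.cell)
        outputs = head_forward(
            self.params, emb.x2b, emb.scalar, self.config.head_hidden,
            self.config.outputs,
        )
        props = aggregate(outputs, graph)
        return props, graph, emb, pos

    def _long_range(self, system, pos, graph, q, ratios):
        """Coulomb + dispersion energies (Tensors)."""
        ff = self.config.ff
        fv = self.ff_values()
        arrays = ff.atom_arrays(system.species)
        nval = arrays["n_valence"]
        n = system.n_atoms

        def pair_r(ii, jj, shifts=None):
            d = ad.take(pos, jj, 0) + (-ad.take(pos, ii, 0))
            if shifts is not None:
                d = d + ad.constant(shifts @ system.cell)
            return ad.norm(d, axis=-1)

        def cp_correction(ii, jj, r, factor):
            qi, qj = ad.take(q, ii, 0), ad.take(q, jj, 0)
            ni, nj = ad.constant(nval[ii]), ad.constant(nval[jj])
            full = coulomb_cp(qi, qj, ni, nj, r, fv["alpha"], fv["beta"])
            bare = coulomb_point(qi, qj, r)
            return factor * ad.tsum(full + (-bare))

        def dispersion_sum(ii, jj, r, factor):
            ri, rj = ad.take(ratios, ii, 0), ad.take(ratios, jj, 0)
            e = ts_dispersion(
                ri, rj, r,
                arrays["c6_free"][ii], arrays["c6_free"][jj],
                arrays["alpha_free"][ii], arrays["alpha_free"][jj],
                arrays["r_vdw_free"][ii], arrays["r_vdw_free"][jj],
                fv["gamma"], fv["s"],
            )
            sw = dispersion_switch(r, ff.dispersion_switch_on,
                                   ff.dispersion_cutoff)
            return factor * ad.tsum(e * sw)

        half = graph.src < graph.dst if graph.n_pairs else np.zeros(0, bool)

        if not system.periodic:
            iu, ju = np.triu_indices(n, 1)
            if len(iu):
                r_all = pair_r(iu, ju)
                e_c = ad.tsum(
                    coulomb_point(ad.take(q, iu, 0), ad.take(q, ju, 0), r_all)
                )
                mask = r_all.data < ff.dispersion_cutoff
                e_d = (
                    dispersion_sum(iu[mask], ju[mask], pair_r(iu[mask], ju[mask]), 1.0)
                    if mask.any()
                    else ad.constant(0.0)
                )
            else:
                e_c = ad.constant(0.0)
                e_d = ad.constant(0.0)
            if half.any():
                ii, jj = graph.src[half], graph.dst[half]
                e_c = e_c + cp_correction(ii, jj, pair_r(ii, jj), 1.0)
            return e_c, e_d

        # periodic: Ewald point charges + short-range CP correction,
        # switched dispersion with analytic tail
        e_c = ewald_coulomb(system, q, ff.ewald_accuracy, positions=pos)
        if graph.n_pairs:
            sh = graph.shifts
            r_g = pair_r(graph.src, graph.dst, sh)
            qi = ad.take(q, graph.src, 0)
            qj = ad.take(q, graph.dst, 0)
            ni = ad.constant(nval[graph.src])
            nj = ad.constant(nval[graph.dst])
            full = coulomb_cp(qi, qj, ni, nj, r_g, fv["alpha"], fv["beta"])
            bare = coulomb_point(qi, qj, r_g)
            e_c = e_c + 0.5 * ad.tsum(full + (-bare))

        dgraph = build_pair_graph(system, ff.dispersion_cutoff, replicate=True)
        if dgraph.n_pairs:
            r_d = pair_r(dgraph.src, dgraph.dst, dgraph.shifts)
            e_d = dispersion_sum(dgraph.src, dgraph.dst, r_d, 0.5)
        else:
            e_d = ad.constant(0.0)
        # tail correction: homogeneous background beyond the switch region
        vol = abs(np.linalg.det(system.cell))
        integral = dispersion_tail_integral(
            ff.dispersion_switch_on, ff.dispersion_cutoff
        )
        c6ii = ratios * ratios * ad.constant(arrays["c6_free"])
        a_eff = ratios * ad.constant(arrays["alpha_free"])
        ci = ad.reshape(c6ii, (n, 1))
        cj = ad.reshape(c6ii, (1, n))
        ai = ad.reshape(a_eff, (n, 1))
        aj = ad.reshape(a_eff, (1, n))
        c6_mat = 2.0 * ci * cj / (aj / ai * ci + ai / aj * cj)
        e_d = e_d + (-2.0 * np.pi / vol) * integral * ad.tsum(c6_mat)
        return e_c, e_d

    def energy_tensor(self, system: AtomicSystem, positions=None):
        """Total energy as a Tensor plus intermediate quantities."""
        props, graph, emb, pos = self.atomic_properties(system, positions)
        fv = self.ff_values()
        q_scaled = scale_charges(props.charge, fv["eps"])
        drain_scaled = scale_charges(props.pair_drain, fv["eps"])
        ff = self.config.ff
        q_corr, hole = correct_valence(
            q_scaled, drain_scaled, graph,
            self.config.ff.atom_arrays(system.species)["n_valence"],
            ff.valence_fraction, ff.valence_width,
        )
        e_nn = ad.tsum(props.local_energy)
        e_c, e_d = self._long_range(system, pos, graph, q_corr,
                                    props.volume_ratio)
        e_ref = reference_energy(system.species, self._reference_table())
        total = e_nn + e_c + e_d + e_ref
        return {
            "total": total, "e_nn": e_nn, "e_coulomb": e_c,
            "e_dispersion": e_d, "e_reference": e_ref, "charges": q_corr,
            "volume_ratios": props.volume_ratio, "positions": pos,
            "properties": props, "graph": graph, "embedding": emb,
        }

    def _reference_table(self) -> dict:
        if self.config.reference_energies:
            return self.config.reference_energies
        return {symbol(z): 0.0 for z in range(1, 55)}

    def compute(self, system: AtomicSystem, forces: bool = True) -> EnergyBreakdown:
        """Energy breakdown and (optionally) forces of one configuration."""
        pos = Tensor(system.positions)
        parts = self.energy_tensor(system, positions=pos)
        f = None
        if forces:
            g = ad.grad(parts["total"], pos)
            f = -g.data
        return EnergyBreakdown(
            e_nn=float(parts["e_nn"].data),
            e_coulomb=float(parts["e_coulomb"].data),
            e_dispersion=float(parts["e_dispersion"].data),
            e_reference=float(parts["e_reference"]),
            e_total=float(parts["total"].data),
            forces=f,
            charges=parts["charges"].data.copy(),
            volume_ratios=parts["volume_ratios"].data.copy(),
        )

    # -- persistence --------------------------------------------------
    def save(self, path):
        """Single-archive checkpoint: config (JSON) + named weight arrays."""
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(self.config.to_dict()))
            buf = io.BytesIO()
            np.savez(buf, **{k: v.data for k, v in self.params.items()})
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "Model":
        with zipfile.ZipFile(path) as zf:
            config = ModelConfig.from_dict(json.loads(zf.read("config.json")))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
                params = {k: Tensor(npz[k]) for k in npz.files}
        ref = cls(config, params={})
        expect = Model(config, seed=0).params
        if set(expect) != set(params):
            raise ValueError("checkpoint parameter names do not match config")
        for k in expect:
            if expect[k].shape != params[k].shape:
                raise ValueError(
                    f"checkpoint shape mismatch for {k}: "
                    f"{params[k].shape} vs {expect[k].shape}"
                )
        ref.params = params
        return ref


def total_energy_forces(system: AtomicSystem, model: Model) -> EnergyBreakdown:
    """Assemble the total energy and forces (physics-module entry point)."""
    return model.compute(system, forces=True)


def dissociation_scan(model: Model, element_a, element_b, distances):
    """Total energy of the A-B diatomic along a distance grid (kcal/mol)."""
    energies = []
    for r in distances:
        system = AtomicSystem(
            [element_a, element_b], [[0.0, 0.0, 0.0], [0.0, 0.0, float(r)]]
        )
        energies.append(model.compute(system, forces=False).e_total)
    return np.asarray(energies)
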