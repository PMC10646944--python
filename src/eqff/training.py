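"""Multi-stage training: losses, optimizer, scheduler, schedule runner.

The training procedure mirrors the staged recipe the model family needs:

* stage 1 trains the embedding + all heads on energies (NN term only),
  forces, charges and volume ratios with weights lambda_E = 0.001,
  lambda_F = 1, lambda_q = lambda_v = 1000, plus a covariance regularizer
  on the scalar embedding features;
* stage 2 freezes the embedding and the charge/volume heads, switches the
  energy target to the full physics-augmented energy, with
  lambda_E = 0.01, lambda_F = 0.1 (the end-of-stage-1 weights);
* stage 3 retrains the energy head on total energies plus dimer
  interaction energies (lambda_E = 0.1, lambda_DES = 5), optionally
  unfreezing everything including the physics parameters;
* stage 4 refines on extra (e.g. force-matching) records, configured like
  any other stage.

The optimizer is AdamW with decoupled weight decay (0.5 on the output
module, none on the embedding), with a reduce-on-plateau learning-rate
schedule (patience 10 epochs, factor 0.8) and stage-specific stopping
learning rates. Forces enter the loss as exact gradients of the model
energy, differentiated again with respect to the parameters (double
backward). Everything is deterministic given one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import AtomicSystem, PairGraph, build_pair_graph
from .heads import aggregate, head_forward, reference_energy
from .allegro import embed_pairs
from .physics import (
    correct_valence,
    coulomb_cp,
    coulomb_point,
    dispersion_switch,
    scale_charges,
    ts_dispersion,
)


@dataclass
class TrainingRecord:
    """One labeled configuration (energies kcal/mol, charges e)."""

    system: AtomicSystem
    energy: float
    forces: np.ndarray | None = None
    charges: np.ndarray | None = None
    volume_ratios: np.ndarray | None = None
    kind: str = "total"  # "total" or "interaction"
    monomer_partition: tuple | None = None  # (idx_a, idx_b) for dimers
    interaction_energy: float | None = None

    def __post_init__(self):
        n = self.system.n_atoms
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (n, 3):
                raise ValueError("forces must match the atom count")
        if self.kind == "interaction" and self.monomer_partition is None:
            raise ValueError("interaction records require monomer partitions")


# ---------------------------------------------------------------------------
# dataset files: JSON-lines primary, HDF5 alternative

def save_records_jsonl(records, path):
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(_record_to_dict(r)) + "\n")


def load_records_jsonl(path):
    with open(path) as fh:
        return [_record_from_dict(json.loads(line)) for line in fh if line.strip()]


def save_records_hdf5(records, path):
    import h5py

    with h5py.File(path, "w") as f:
        for k, r in enumerate(records):
            g = f.create_group(f"record_{k:07d}")
            d = _record_to_dict(r)
            g.attrs["kind"] = d["kind"]
            g.attrs["energy"] = d["energy"]
            if d.get("interaction_energy") is not None:
                g.attrs["interaction_energy"] = d["interaction_energy"]
            for key in ("species", "positions", "forces", "charges",
                        "volume_ratios", "partition_a", "partition_b"):
                if d.get(key) is not None:
                    g.create_dataset(key, data=np.asarray(d[key]))


def load_records_hdf5(path):
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            d = {
                "kind": g.attrs["kind"],
                "energy": float(g.attrs["energy"]),
                "interaction_energy": (
                    float(g.attrs["interaction_energy"])
                    if "interaction_energy" in g.attrs else None
                ),
            }
            for key in ("species", "positions", "forces", "charges",
                        "volume_ratios", "partition_a", "partition_b"):
                d[key] = g[key][...] if key in g else None
            records.append(_record_from_dict(d))
    return records


def _record_to_dict(r: TrainingRecord) -> dict:
    d = {
        "species": [int(z) for z in r.system.species],
        "positions": r.system.positions.tolist(),
        "energy": r.energy,
        "kind": r.kind,
        "interaction_energy": r.interaction_energy,
    }
    for key in ("forces", "charges", "volume_ratios"):
        v = getattr(r, key)
        d[key] = None if v is None else np.asarray(v).tolist()
    if r.monomer_partition is not None:
        d["partition_a"] = np.asarray(r.monomer_partition[0]).tolist()
        d["partition_b"] = np.asarray(r.monomer_partition[1]).tolist()
    return d


def _record_from_dict(d: dict) -> TrainingRecord:
    part = None
    if d.get("partition_a") is not None:
        part = (
            np.asarray(d["partition_a"], dtype=np.intp),
            np.asarray(d["partition_b"], dtype=np.intp),
        )
    return TrainingRecord(
        system=AtomicSystem(d["species"], np.asarray(d["positions"], float)),
        energy=float(d["energy"]),
        forces=None if d.get("forces") is None else np.asarray(d["forces"], float),
        charges=None if d.get("charges") is None else np.asarray(d["charges"], float),
        volume_ratios=(
            None if d.get("volume_ratios") is None
            else np.asarray(d["volume_ratios"], float)
        ),
        kind=str(d["kind"]),
        monomer_partition=part,
        interaction_energy=(
            None if d.get("interaction_energy") is None
            else float(d["interaction_energy"])
        ),
    )


# ---------------------------------------------------------------------------
# batching: many records merged into one graph (geometries are static, so
# neighbor lists and long-range pair lists are built once per batch)

class Batch:
    def __init__(self, records, model):
        self.records = records
        cfg = model.config.allegro
        species, positions, atom_rec = [], [], []
        g_src, g_dst = [], []
        lr_i, lr_j, lr_rec = [], [], []
        refs = []
        offset = 0
        table = model._reference_table()
        for k, rec in enumerate(records):
            sysk = rec.system
            n = sysk.n_atoms
            graph = build_pair_graph(sysk, cfg.r_c)
            species.append(sysk.species)
            positions.append(sysk.positions)
            atom_rec.append(np.full(n, k))
            g_src.append(graph.src + offset)
            g_dst.append(graph.dst + offset)
            iu, ju = np.triu_indices(n, 1)
            lr_i.append(iu + offset)
            lr_j.append(ju + offset)
            lr_rec.append(np.full(len(iu), k))
            refs.append(reference_energy(sysk.species, table))
            offset += n
        self.n_records = len(records)
        self.n_atoms = offset
        self.species = np.concatenate(species)
        self.positions = np.concatenate(positions)
        self.atom_record = np.concatenate(atom_rec)
        self.graph = PairGraph(
            src=np.concatenate(g_src).astype(np.intp),
            dst=np.concatenate(g_dst).astype(np.intp),
            displacement=np.zeros((0, 3)),  # recomputed from positions
            distance=np.zeros(0),
            cutoff=cfg.r_c,
            n_atoms=offset,
        )
        # displacement/distance fields are only used by the model through
        # the differentiable path; fill them for completeness
        d = self.positions[self.graph.dst] - self.positions[self.graph.src]
        self.graph.displacement = d
        self.graph.distance = np.linalg.norm(d, axis=1)
        self.lr_i = np.concatenate(lr_i).astype(np.intp)
        self.lr_j = np.concatenate(lr_j).astype(np.intp)
        self.lr_record = np.concatenate(lr_rec)
        self.reference = np.asarray(refs)

        self.energy_labels = np.asarray([r.energy for r in records])
        self.force_labels = (
            np.concatenate([r.forces for r in records])
            if all(r.forces is not None for r in records) else None
        )
        self.charge_labels = (
            np.concatenate([r.charges for r in records])
            if all(r.charges is not None for r in records) else None
        )
        self.volume_labels = (
            np.concatenate([r.volume_ratios for r in records])
            if all(r.volume_ratios is not None for r in records) else None
        )
        self.atoms_per_record = np.bincount(
            self.atom_record, minlength=self.n_records
        )

    def forward(self, model, physics: bool):
        """Per-record energies (Tensor) + per-atom predictions."""
        cfg = model.config.allegro
        pos = Tensor(self.positions)
        emb = embed_pairs(model.params, cfg, self.species, self.graph, pos)
        outputs = head_forward(
            model.params, emb.x2b, emb.scalar, model.config.head_hidden,
            model.config.outputs,
        )
        props = aggregate(outputs, self.graph)
        e_rec = ad.segment_sum(props.local_energy, self.atom_record,
                               self.n_records) + ad.constant(self.reference)
        out = {
            "positions": pos, "properties": props, "x_final": emb.scalar,
            "charges_nn": props.charge, "volumes": props.volume_ratio,
        }
        if physics:
            e_rec = e_rec + self._physics_energy(model, pos, props)
        out["energies"] = e_rec
        return out

    def _physics_energy(self, model, pos, props):
        ff = model.config.ff
        fv = model.ff_values()
        arrays = ff.atom_arrays(self.species)
        q_scaled = scale_charges(props.charge, fv["eps"])
        drain = scale_charges(props.pair_drain, fv["eps"])
        q, _ = correct_valence(
            q_scaled, drain, self.graph, arrays["n_valence"],
            ff.valence_fraction, ff.valence_width,
        )
        ii, jj = self.lr_i, self.lr_j
        d = ad.take(pos, jj, 0) + (-ad.take(pos, ii, 0))
        r = ad.norm(d, axis=-1)
        pair_e = coulomb_point(ad.take(q, ii, 0), ad.take(q, jj, 0), r)
        mask = r.data < ff.dispersion_cutoff
        if mask.any():
            im, jm = ii[mask], jj[mask]
            dm = ad.take(pos, jm, 0) + (-ad.take(pos, im, 0))
            rm = ad.norm(dm, axis=-1)
            ratios = props.volume_ratio
            e_disp = ts_dispersion(
                ad.take(ratios, im, 0), ad.take(ratios, jm, 0), rm,
                arrays["c6_free"][im], arrays["c6_free"][jm],
                arrays["alpha_free"][im], arrays["alpha_free"][jm],
                arrays["r_vdw_free"][im], arrays["r_vdw_free"][jm],
                fv["gamma"], fv["s"],
            ) * dispersion_switch(rm, ff.dispersion_switch_on,
                                  ff.dispersion_cutoff)
            disp_rec = ad.segment_sum(e_disp, self.lr_record[mask],
                                      self.n_records)
        else:
            disp_rec = ad.constant(np.zeros(self.n_records))
        coul_rec = ad.segment_sum(pair_e, self.lr_record, self.n_records)
        # short-range charge-penetration correction on graph pairs
        g = self.graph
        half = g.src < g.dst
        if half.any():
            hi, hj = g.src[half], g.dst[half]
            dh = ad.take(pos, hj, 0) + (-ad.take(pos, hi, 0))
            rh = ad.norm(dh, axis=-1)
            qi, qj = ad.take(q, hi, 0), ad.take(q, hj, 0)
            ni = ad.constant(arrays["n_valence"][hi])
            nj = ad.constant(arrays["n_valence"][hj])
            corr = coulomb_cp(qi, qj, ni, nj, rh, fv["alpha"], fv["beta"]) + (
                -coulomb_point(qi, qj, rh)
            )
            coul_rec = coul_rec + ad.segment_sum(
                corr, self.atom_record[hi], self.n_records
            )
        return coul_rec + disp_rec


# ---------------------------------------------------------------------------
# losses

def covariance_regularizer(features: Tensor) -> Tensor:
    """Sum of squared off-diagonal sample-covariance entries of the
    feature matrix (rows = samples). Zero for batches smaller than 2."""
    n, f = features.shape
    if n < 2:
        return ad.constant(0.0)
    mean = ad.tsum(features, axis=0, keepdims=True) * (1.0 / n)
    xc = features + (-ad.broadcast_to(mean, (n, f)))
    cov = ad.einsum("ni,nj->ij", xc, xc) * (1.0 / (n - 1))
    total = ad.tsum(cov * cov)
    diag = ad.tsum(cov * cov * ad.constant(np.eye(f)))
    return total + (-diag)


def _per_record_mean(values: Tensor, record_ids, n_records, counts):
    s = ad.segment_sum(values, record_ids, n_records)
    return s * ad.constant(1.0 / counts)


def stage1_loss(pred: dict, batch: Batch, weights: dict) -> tuple:
    """Weighted squared errors on energy, forces, charges, volume ratios.

    Per-record terms: (dE)^2; per-component mean of (dF)^2; per-atom means
    of (dq)^2 and (dv)^2; all averaged over the batch.
    """
    for label, name in ((batch.force_labels, "forces"),
                        (batch.charge_labels, "charges"),
                        (batch.volume_labels, "volume_ratios")):
        if label is None:
            raise ValueError(f"stage-1 records are missing {name}")
    comps = {}
    de = pred["energies"] + ad.constant(-batch.energy_labels)
    comps["energy"] = weights["lambda_E"] * ad.tsum(de * de) * (1.0 / batch.n_records)

    f_pred = -ad.grad(ad.tsum(pred["energies"]), pred["positions"])
    df = f_pred + ad.constant(-batch.force_labels)
    sq = ad.tsum(df * df, axis=1)
    per_rec = _per_record_mean(sq, batch.atom_record, batch.n_records,
                               3.0 * batch.atoms_per_record)
    comps["forces"] = weights["lambda_F"] * ad.tsum(per_rec) * (1.0 / batch.n_records)

    dq = pred["charges_nn"] + ad.constant(-batch.charge_labels)
    per_rec = _per_record_mean(dq * dq, batch.atom_record, batch.n_records,
                               batch.atoms_per_record.astype(float))
    comps["charges"] = weights["lambda_q"] * ad.tsum(per_rec) * (1.0 / batch.n_records)

    dv = pred["volumes"] + ad.constant(-batch.volume_labels)
    per_rec = _per_record_mean(dv * dv, batch.atom_record, batch.n_records,
                               batch.atoms_per_record.astype(float))
    comps["volumes"] = weights["lambda_v"] * ad.tsum(per_rec) * (1.0 / batch.n_records)

    w_cov = weights.get("lambda_cov", 0.0)
    if w_cov:
        comps["covariance"] = w_cov * covariance_regularizer(pred["x_final"])

    total = None
    for v in comps.values():
        total = v if total is None else total + v
    return total, comps


def stage2_loss(pred: dict, batch: Batch, weights: dict) -> tuple:
    """Energy + force matching of the full physics-augmented energy."""
    comps = {}
    de = pred["energies"] + ad.constant(-batch.energy_labels)
    comps["energy"] = weights["lambda_E"] * ad.tsum(de * de) * (1.0 / batch.n_records)
    if batch.force_labels is None:
        raise ValueError("stage-2 records are missing forces")
    f_pred = -ad.grad(ad.tsum(pred["energies"]), pred["positions"])
    df = f_pred + ad.constant(-batch.force_labels)
    sq = ad.tsum(df * df, axis=1)
    per_rec = _per_record_mean(sq, batch.atom_record, batch.n_records,
                               3.0 * batch.atoms_per_record)
    comps["forces"] = weights["lambda_F"] * ad.tsum(per_rec) * (1.0 / batch.n_records)
    total = comps["energy"] + comps["forces"]
    return total, comps


def stage3_loss(pred: dict, batch: Batch, weights: dict) -> tuple:
    """Total energies plus dimer interaction energies.

    Interaction energies are computed by the model itself: for each
    interaction record the two monomer sub-systems are appended to the
    batch by `collate_stage3`, and E_int = E_dimer - E_a - E_b.
    """
    comps = {}
    total_ids = np.asarray(
        [k for k, r in enumerate(batch.records) if r.kind == "total"],
        dtype=np.intp,
    )
    if len(total_ids):
        de = ad.take(pred["energies"], total_ids, 0) + ad.constant(
            -batch.energy_labels[total_ids]
        )
        comps["energy"] = (
            weights["lambda_E"] * ad.tsum(de * de) * (1.0 / len(total_ids))
        )
    triples = getattr(batch, "interaction_triples", [])
    if triples:
        d_idx = np.asarray([t[0] for t in triples], dtype=np.intp)
        a_idx = np.asarray([t[1] for t in triples], dtype=np.intp)
        b_idx = np.asarray([t[2] for t in triples], dtype=np.intp)
        e = pred["energies"]
        e_int = ad.take(e, d_idx, 0) + (-ad.take(e, a_idx, 0)) + (
            -ad.take(e, b_idx, 0)
        )
        labels = np.asarray([t[3] for t in triples])
        di = e_int + ad.constant(-labels)
        comps["interaction"] = (
            weights["lambda_DES"] * ad.tsum(di * di) * (1.0 / len(triples))
        )
    total = None
    for v in comps.values():
        total = v if total is None else total + v
    if total is None:
        raise ValueError("stage-3 batch contains no usable records")
    return total, comps


def collate_stage3(records, model) -> Batch:
    """Batch where each interaction record also contributes its monomers."""
    expanded, triples = [], []
    for rec in records:
        if rec.kind == "interaction":
            if rec.monomer_partition is None:
                raise ValueError("interaction record lacks monomer partitions")
            ia, ib = rec.monomer_partition
            sys_d = rec.system
            mono = [
                TrainingRecord(
                    system=AtomicSystem(
                        sys_d.species[idx], sys_d.positions[idx]
                    ),
                    energy=0.0, kind="total",
                )
                for idx in (ia, ib)
            ]
            d_pos = len(expanded)
            expanded.append(rec)
            expanded.extend(mono)
            triples.append(
                (d_pos, d_pos + 1, d_pos + 2, rec.interaction_energy)
            )
        else:
            expanded.append(rec)
    batch = Batch(expanded, model)
    batch.interaction_triples = triples
    return batch


LOSSES = {"stage1": stage1_loss, "stage2": stage2_loss, "stage3": stage3_loss}
PHYSICS_ON = {"stage1": False, "stage2": True, "stage3": True}


# ---------------------------------------------------------------------------
# optimizer + scheduler

class AdamW:
    """Adam with decoupled weight decay; per-parameter decay factors."""

    def __init__(self, params: dict, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay: dict | None = None):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay or {}
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = {k: 0 for k in params}

    def step(self, grads: dict):
        b1, b2 = self.betas
        for name, g in grads.items():
            p = self.params[name]
            self.t[name] += 1
            t = self.t[name]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**t)
            vhat = self.v[name] / (1 - b2**t)
            wd = self.weight_decay.get(name, 0.0)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + wd * p.data
            )


class ReduceLROnPlateau:
    def __init__(self, lr, patience=10, factor=0.8):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric) -> float:
        if metric < self.best * (1 - 1e-6):
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


# ---------------------------------------------------------------------------
# schedule

@dataclass
class StageConfig:
    name: str
    loss: str  # "stage1" | "stage2" | "stage3"
    weights: dict
    frozen: tuple = ()  # parameter-group names or name prefixes
    lr: float = 1e-3
    lr_patience: int = 10
    lr_factor: float = 0.8
    lr_stop: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 256
    weight_decay: dict = field(default_factory=lambda: {"output": 0.5})

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("loss weights must be non-negative")
        if self.lr_stop >= self.lr:
            raise ValueError("stop threshold must be below the initial rate")


def default_stage1(**over) -> StageConfig:
    base = dict(
        name="stage1", loss="stage1",
        weights={"lambda_E": 0.001, "lambda_F": 1.0, "lambda_q": 1000.0,
                 "lambda_v": 1000.0, "lambda_cov": 1e-3},
        frozen=("physics",),
    )
    base.update(over)
    return StageConfig(**base)


def default_stage2(**over) -> StageConfig:
    base = dict(
        name="stage2", loss="stage2",
        weights={"lambda_E": 0.01, "lambda_F": 0.1},
        frozen=("embedding", "physics", "head.charge", "head.volume"),
    )
    base.update(over)
    return StageConfig(**base)


def default_stage3(**over) -> StageConfig:
    base = dict(
        name="stage3", loss="stage3",
        weights={"lambda_E": 0.1, "lambda_DES": 5.0},
        frozen=("embedding", "head.charge", "head.volume"),
        lr_stop=1e-5, batch_size=64,
    )
    base.update(over)
    return StageConfig(**base)


def _trainable_names(model, frozen) -> list:
    groups = model.parameter_groups()
    frozen_names = set()
    for f in frozen:
        if f in groups:
            frozen_names.update(groups[f])
        else:
            frozen_names.update(n for n in model.params if n.startswith(f))
    return [n for n in model.params if n not in frozen_names]


def _decay_map(model, stage: StageConfig) -> dict:
    groups = model.parameter_groups()
    out = {}
    for gname, wd in stage.weight_decay.items():
        for n in groups.get(gname, []):
            out[n] = wd
    return out


def run_schedule(model, records, stages, seed=0, val_fraction=0.1,
                 verbose=False):
    """Execute the staged training; returns the per-epoch history.

    The validation split is a fixed random fraction of the records chosen
    once from the seed and reused across stages.
    """
    if not records:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_val = max(1, int(round(val_fraction * len(records)))) if len(records) > 1 else 0
    val_ids, train_ids = perm[:n_val], perm[n_val:]
    train = [records[i] for i in train_ids]
    val = [records[i] for i in val_ids]

    history = []
    for stage in stages:
        loss_fn = LOSSES[stage.loss]
        physics = PHYSICS_ON[stage.loss]
        collate = collate_stage3 if stage.loss == "stage3" else Batch
        trainable = _trainable_names(model, stage.frozen)
        opt = AdamW(
            {n: model.params[n] for n in trainable},
            lr=stage.lr, weight_decay=_decay_map(model, stage),
        )
        sched = ReduceLROnPlateau(stage.lr, stage.lr_patience, stage.lr_factor)
        val_batch = collate(val, model) if val else None

        for epoch in range(stage.max_epochs):
            order = rng.permutation(len(train))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(train), stage.batch_size):
                chunk = [train[i] for i in order[start:start + stage.batch_size]]
                batch = collate(chunk, model)
                pred = batch.forward(model, physics)
                loss, comps = loss_fn(pred, batch, stage.weights)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss in {stage.name} epoch {epoch}: "
                        + str({k: float(v.data) for k, v in comps.items()})
                    )
                grads = ad.grad(loss, [model.params[n] for n in trainable])
                opt.step({n: g.data for n, g in zip(trainable, grads)})
                epoch_loss += value
                n_batches += 1
            train_loss = epoch_loss / max(n_batches, 1)
            if val_batch is not None:
                vpred = val_batch.forward(model, physics)
                vloss = float(loss_fn(vpred, val_batch, stage.weights)[0].data)
            else:
                vloss = np.nan
            opt.lr = sched.step(train_loss)
            history.append({
                "stage": stage.name, "epoch": epoch, "lr": opt.lr,
                "train_loss": train_loss, "val_loss": vloss,
            })
            if verbose:
                print(f"{stage.name} epoch {epoch:3d} lr {opt.lr:.2e} "
                      f"train {train_loss:.5g} val {vloss:.5g}")
            if opt.lr < stage.lr_stop:
                break
    return history


def energy_rmse(model, records, physics=True) -> float:
    """RMSE of total energies over records (kcal/mol)."""
    batch = Batch(records, model)
    pred = batch.forward(model, physics)
    de = pred["energies"].data - batch.energy_labels
    return float(np.sqrt(np.mean(de**2)))
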