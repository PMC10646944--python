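"""Training engine: losses, regularizer, optimizer policy, scheduling."""

import copy

import numpy as np
import pytest

from eqff import autodiff as ad
from eqff.model import Model
from eqff.presets import reduced_config
from eqff.synth import (
    SURROGATE_REFERENCES,
    SurrogateOracle,
    SynthConfig,
    synthetic_dataset,
)
from eqff.training import (
    AdamW,
    Batch,
    TrainingRecord,
    collate_stage3,
    covariance_regularizer,
    default_stage1,
    default_stage2,
    default_stage3,
    load_records_hdf5,
    load_records_jsonl,
    run_schedule,
    save_records_hdf5,
    save_records_jsonl,
    stage1_loss,
    stage3_loss,
)


@pytest.fixture(scope="module")
def model():
    cfg = reduced_config()
    cfg.reference_energies = dict(SURROGATE_REFERENCES)
    return Model(cfg, seed=3)


@pytest.fixture(scope="module")
def records():
    return synthetic_dataset(SynthConfig(n_records=24), seed=9)


@pytest.fixture(scope="module")
def dimer_records():
    return synthetic_dataset(
        SynthConfig(n_records=10, dimer_fraction=1.0), seed=9
    )


# ------------------------------------------------------------------ generator

def test_synthetic_dataset_is_deterministic(records):
    again = synthetic_dataset(SynthConfig(n_records=24), seed=9)
    for a, b in zip(records, again):
        assert np.array_equal(a.system.positions, b.system.positions)
        assert a.energy == b.energy


def test_synthetic_molecules_are_neutral(records, dimer_records):
    for r in records + dimer_records:
        assert abs(r.charges.sum()) < 1e-12


def test_surrogate_forces_are_consistent_with_its_energy():
    oracle = SurrogateOracle(("O", "H"), ((0, 1, 0.30),))
    pos = np.array([[0.0, 0.0, 0.0], [1.05, 0.3, -0.2]])
    e, f = oracle.energy_forces(pos)
    h = 1e-5
    for i in range(2):
        for k in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, k] += h
            pm[i, k] -= h
            fd = -(oracle.energy_forces(pp)[0] - oracle.energy_forces(pm)[0]) / (2 * h)
            assert abs(fd - f[i, k]) < 1e-6 * max(abs(fd), 1.0)


def test_dimer_records_carry_partitions_and_interaction_energies(dimer_records):
    for r in dimer_records:
        assert r.kind == "interaction"
        ia, ib = r.monomer_partition
        assert len(ia) + len(ib) == r.system.n_atoms
        assert np.isfinite(r.interaction_energy)


def test_unknown_template_is_an_error():
    with pytest.raises(ValueError, match="template"):
        synthetic_dataset(SynthConfig(templates=("XYZ",), n_records=1), seed=0)


# --------------------------------------------------------------------- losses

def test_stage1_loss_is_zero_for_perfect_predictions(model, records):
    batch = Batch(records[:6], model)
    pred = batch.forward(model, physics=False)
    # overwrite labels with the model's own outputs
    batch.energy_labels = pred["energies"].data.copy()
    f = -ad.grad(ad.tsum(pred["energies"]), pred["positions"]).data
    batch.force_labels = f
    batch.charge_labels = pred["charges_nn"].data.copy()
    batch.volume_labels = pred["volumes"].data.copy()
    pred = batch.forward(model, physics=False)
    loss, comps = stage1_loss(
        pred, batch,
        {"lambda_E": 0.001, "lambda_F": 1.0, "lambda_q": 1000.0,
         "lambda_v": 1000.0},
    )
    assert float(loss.data) < 1e-18


def test_stage1_loss_weighted_arithmetic(model, records):
    """Hand-computed oracle: unit energy error with the printed weights."""
    batch = Batch(records[:4], model)
    pred = batch.forward(model, physics=False)
    batch.energy_labels = pred["energies"].data - 1.0  # energy error = 1
    f = -ad.grad(ad.tsum(pred["energies"]), pred["positions"]).data
    batch.force_labels = f
    batch.charge_labels = pred["charges_nn"].data.copy()
    batch.volume_labels = pred["volumes"].data.copy()
    pred = batch.forward(model, physics=False)
    loss, _ = stage1_loss(
        pred, batch,
        {"lambda_E": 0.001, "lambda_F": 1.0, "lambda_q": 1000.0,
         "lambda_v": 1000.0},
    )
    assert np.isclose(float(loss.data), 0.001, rtol=1e-10)

    # mixed residuals: dE = 2 per record, one force component off by 0.5
    batch.energy_labels -= 1.0  # now dE = 2
    batch.force_labels = f.copy()
    batch.force_labels[0, 0] += 0.5
    pred = batch.forward(model, physics=False)
    loss, comps = stage1_loss(
        pred, batch,
        {"lambda_E": 0.001, "lambda_F": 1.0, "lambda_q": 1000.0,
         "lambda_v": 1000.0},
    )
    n0 = batch.records[0].system.n_atoms
    expected = 0.001 * 4.0 + (0.5**2 / (3 * n0)) / batch.n_records
    assert np.isclose(float(loss.data), expected, rtol=1e-10)


def test_stage1_loss_requires_all_labels(model, records):
    recs = [copy.copy(records[0])]
    recs[0].charges = None
    batch = Batch(recs, model)
    pred = batch.forward(model, physics=False)
    with pytest.raises(ValueError, match="charges"):
        stage1_loss(pred, batch, {"lambda_E": 1, "lambda_F": 1,
                                  "lambda_q": 1, "lambda_v": 1})


def test_loss_total_equals_sum_of_logged_components(model, records):
    batch = Batch(records[:4], model)
    pred = batch.forward(model, physics=False)
    loss, comps = stage1_loss(
        pred, batch,
        {"lambda_E": 0.001, "lambda_F": 1.0, "lambda_q": 1000.0,
         "lambda_v": 1000.0, "lambda_cov": 1e-3},
    )
    assert float(loss.data) == sum(float(c.data) for c in comps.values())


def test_covariance_regularizer_properties(rng):
    x = rng.normal(size=(64, 5))
    dup = np.concatenate([x, x[:, :1]], axis=1)  # perfectly correlated pair
    assert float(covariance_regularizer(ad.Tensor(dup)).data) > 0.0
    shifted = x + 13.7
    a = float(covariance_regularizer(ad.Tensor(x)).data)
    b = float(covariance_regularizer(ad.Tensor(shifted)).data)
    assert np.isclose(a, b, rtol=1e-8)
    assert float(covariance_regularizer(ad.Tensor(x[:1])).data) == 0.0


def test_covariance_regularizer_vanishes_for_large_independent_batches(rng):
    values = []
    for n in (50, 500):
        x = rng.normal(size=(n, 8))
        values.append(float(covariance_regularizer(ad.Tensor(x)).data))
    assert values[1] < values[0]


def test_stage3_interaction_arithmetic(model, dimer_records):
    batch = collate_stage3(dimer_records[:3], model)
    pred = batch.forward(model, physics=True)
    e = pred["energies"].data
    # set labels so that every interaction residual is exactly 0.2
    for k, t in enumerate(batch.interaction_triples):
        d, a, b, _ = t
        batch.interaction_triples[k] = (d, a, b, e[d] - e[a] - e[b] - 0.2)
    loss, comps = stage3_loss(pred, batch, {"lambda_E": 0.1, "lambda_DES": 5.0})
    assert np.isclose(float(comps["interaction"].data), 5.0 * 0.2**2)


def test_interaction_term_ignores_constant_energy_shifts(model, dimer_records):
    """Shifting every reference energy shifts total energies but cancels in
    dimer-minus-monomers differences."""
    batch = collate_stage3(dimer_records[:2], model)
    pred = batch.forward(model, physics=True)
    e = pred["energies"].data
    shifted = Model(model.config, params=model.params)
    shifted.config = copy.deepcopy(model.config)
    shifted.config.reference_energies = {
        k: v + 7.0 for k, v in model.config.reference_energies.items()
    }
    batch2 = collate_stage3(dimer_records[:2], shifted)
    pred2 = batch2.forward(shifted, physics=True)
    e2 = pred2["energies"].data
    for (d, a, b, _), (d2, a2, b2, _) in zip(
        batch.interaction_triples, batch2.interaction_triples
    ):
        assert np.isclose(
            e[d] - e[a] - e[b], e2[d2] - e2[a2] - e2[b2], atol=1e-9
        )


# ------------------------------------------------------------------ optimizer

def test_weight_decay_applies_to_output_module_only(model):
    from eqff.training import _decay_map

    stage = default_stage1()
    decay = _decay_map(model, stage)
    groups = model.parameter_groups()
    assert set(decay) == set(groups["output"])
    assert all(v == 0.5 for v in decay.values())
    assert not any(n in decay for n in groups["embedding"])


def test_zero_epochs_leave_the_model_unchanged(model, records):
    before = {k: v.data.copy() for k, v in model.params.items()}
    run_schedule(model, records, [default_stage1(max_epochs=0)], seed=1)
    for k, v in model.params.items():
        assert np.array_equal(before[k], v.data)


def test_frozen_groups_stay_bitwise_identical(records):
    cfg = reduced_config()
    cfg.reference_energies = dict(SURROGATE_REFERENCES)
    m = Model(cfg, seed=4)
    before = {k: v.data.copy() for k, v in m.params.items()}
    stage = default_stage2(max_epochs=1, batch_size=8, lr=1e-3)
    run_schedule(m, records, [stage], seed=1)
    groups = m.parameter_groups()
    frozen = (
        groups["embedding"] + groups["physics"]
        + [n for n in m.params if n.startswith(("head.charge", "head.volume"))]
    )
    for name in frozen:
        assert np.array_equal(before[name], m.params[name].data), name
    changed = [
        n for n in m.params
        if n.startswith("head.energy") and not np.array_equal(
            before[n], m.params[n].data
        )
    ]
    assert changed  # the energy head actually trained


def test_run_schedule_is_deterministic(records):
    losses = []
    for _ in range(2):
        cfg = reduced_config()
        cfg.reference_energies = dict(SURROGATE_REFERENCES)
        m = Model(cfg, seed=4)
        h = run_schedule(
            m, records, [default_stage1(max_epochs=2, batch_size=8)], seed=2
        )
        losses.append([row["train_loss"] for row in h])
    assert losses[0] == losses[1]


def test_empty_dataset_is_an_error(model):
    with pytest.raises(ValueError, match="empty"):
        run_schedule(model, [], [default_stage1(max_epochs=1)], seed=0)


def test_stage_config_validation():
    with pytest.raises(ValueError):
        default_stage1(lr=1e-5, lr_stop=1e-4)
    with pytest.raises(ValueError):
        default_stage3(weights={"lambda_E": -1.0, "lambda_DES": 5.0})


def test_adamw_decay_shrinks_parameters_without_gradients():
    p = {"w": ad.Tensor(np.ones(3))}
    opt = AdamW(p, lr=0.1, weight_decay={"w": 0.5})
    opt.step({"w": np.zeros(3)})
    assert np.allclose(p["w"].data, 1.0 - 0.1 * 0.5)


# ----------------------------------------------------------------- dataset IO

def test_record_files_roundtrip(tmp_path, records, dimer_records):
    sample = records[:3] + dimer_records[:2]
    jl = tmp_path / "data.jsonl"
    save_records_jsonl(sample, jl)
    back = load_records_jsonl(jl)
    h5 = tmp_path / "data.h5"
    save_records_hdf5(sample, h5)
    back_h5 = load_records_hdf5(h5)
    for loaded in (back, back_h5):
        assert len(loaded) == len(sample)
        for a, b in zip(sample, loaded):
            assert np.allclose(a.system.positions, b.system.positions)
            assert np.array_equal(a.system.species, b.system.species)
            assert np.isclose(a.energy, b.energy)
            assert a.kind == b.kind
            if a.kind == "interaction":
                assert np.isclose(a.interaction_energy, b.interaction_energy)
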