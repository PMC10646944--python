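"""Physics module: charge pipeline, damped Coulomb, TS dispersion, Ewald."""

import numpy as np
import pytest

from eqff import autodiff as ad
from eqff.elements import COULOMB_CONSTANT
from eqff.geometry import AtomicSystem, build_pair_graph
from eqff.physics import (
    FFParameters,
    correct_valence,
    coulomb_cp,
    coulomb_point,
    damping,
    dispersion_sigmoid,
    dispersion_switch,
    ewald_coulomb,
    scale_charges,
    ts_combination_rule,
    ts_dispersion_elements,
    vdw_radius,
)
from oracles import direct_lattice_sum


# ---------------------------------------------------------------------- charges

def test_charge_scaling_is_linear_and_neutrality_preserving():
    q = np.array([0.5, -0.5])
    assert np.allclose(scale_charges(q, 1.0), q)
    assert np.allclose(scale_charges(q, 1.2), [0.6, -0.6])
    rng = np.random.default_rng(0)
    q = rng.normal(size=7)
    q -= q.mean()
    assert abs(np.sum(scale_charges(q, 1.7))) < 1e-14


def _two_atom_graph():
    system = AtomicSystem(["H", "O"], [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return build_pair_graph(system, 5.2)


def test_valence_correction_is_inactive_for_moderate_charges():
    graph = _two_atom_graph()
    q = np.array([0.4, -0.4])
    drain = np.array([0.4, -0.4])  # pair (0,1) drained 0.4e from atom 0
    out, hole = correct_valence(ad.Tensor(q), ad.Tensor(drain), graph,
                                np.array([1.0, 6.0]))
    assert np.array_equal(out.data, q)
    assert np.all(hole.data == 0.0)


def test_valence_correction_single_transfer_hand_computed():
    """H (N=1) at q=+0.97 with one neighbor that drained it: the smooth
    hole h = 0.97 - 0.95 + w/4 (quadratic hinge at x=0.02, w=0.05) is
    returned from the neighbor; total charge conserved."""
    graph = _two_atom_graph()
    q = np.array([0.97, -0.97])
    drain = np.array([0.97, -0.97])
    out, _ = correct_valence(ad.Tensor(q), ad.Tensor(drain), graph,
                             np.array([1.0, 6.0]), width=0.05)
    x = 0.97 - 0.95
    h = (x + 0.05) ** 2 / (4 * 0.05)
    assert np.isclose(out.data[0], 0.97 - h)
    assert np.isclose(out.data[1], -0.97 + h)
    assert abs(out.data.sum()) < 1e-14


def test_valence_correction_splits_proportionally_to_drained_amounts():
    system = AtomicSystem(
        ["H", "O", "O"],
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.1, 0.0]],
    )
    graph = build_pair_graph(system, 5.2)
    # directed pairs sorted: (0,1),(0,2),(1,0),(1,2),(2,0),(2,1)
    drain = np.array([0.6, 0.37, -0.6, 0.0, -0.37, 0.0])
    q = np.array([0.97, -0.6, -0.37])
    out, _ = correct_valence(ad.Tensor(q), ad.Tensor(drain), graph,
                             np.array([1.0, 6.0, 6.0]), width=0.05)
    h = (0.97 - 0.95 + 0.05) ** 2 / (4 * 0.05)
    assert np.isclose(out.data[0], 0.97 - h)
    gave = np.array([out.data[1] + 0.6, out.data[2] + 0.37])
    assert np.isclose(gave[0] / gave[1], 0.6 / 0.37)
    assert abs(out.data.sum()) < 1e-14


def test_valence_correction_degenerate_case_warns_and_leaves_charges():
    graph = _two_atom_graph()
    q = np.array([0.97, -0.97])
    drain = np.array([-0.1, 0.1])  # nobody drained atom 0
    with pytest.warns(UserWarning, match="valence hole"):
        out, _ = correct_valence(ad.Tensor(q), ad.Tensor(drain), graph,
                                 np.array([1.0, 6.0]))
    assert np.array_equal(out.data, q)


def test_valence_correction_is_smooth_in_the_inputs():
    graph = _two_atom_graph()
    drain = np.array([0.97, -0.97])
    qs = np.linspace(0.85, 1.05, 400)
    outs = [
        float(correct_valence(ad.Tensor(np.array([qa, -qa])),
                              ad.Tensor(drain * qa / 0.97), graph,
                              np.array([1.0, 6.0]))[0].data[0])
        for qa in qs
    ]
    d1 = np.diff(outs)
    assert np.all(np.abs(np.diff(d1)) < 5e-4)  # no derivative jumps


# ------------------------------------------------------------------- pair terms

def test_damping_limits_and_monotonicity():
    r = np.linspace(0.0, 30.0, 400)
    f = damping(r, 4.0)
    assert f[0] == 0.0
    assert np.all(np.diff(f) >= 0.0)
    assert np.all(np.diff(f)[r[:-1] < 2.0] > 0.0)  # strictly rising early
    assert abs(f[-1] - 1.0) < 1e-12


def test_cp_coulomb_reaches_bare_coulomb_at_long_range():
    e = coulomb_cp(1.0, 1.0, 1.0, 6.0, 50.0, 4.0, 4.0)
    bare = coulomb_point(1.0, 1.0, 50.0)
    assert abs(e - bare) / abs(bare) < 1e-3


def test_cp_coulomb_is_symmetric_under_atom_exchange():
    a = coulomb_cp(0.3, -0.2, 1.0, 6.0, 1.7, 3.0, 5.0)
    b = coulomb_cp(-0.2, 0.3, 6.0, 1.0, 1.7, 3.0, 5.0)
    assert np.isclose(a, b)


def test_cp_coulomb_rejects_nonpositive_distance():
    with pytest.raises(ValueError):
        coulomb_cp(0.1, -0.1, 1.0, 6.0, 0.0, 4.0, 4.0)


def test_vdw_radius_cube_root_scaling():
    assert np.isclose(vdw_radius(1.0, 1.64), 1.64)
    assert np.isclose(vdw_radius(8.0, 1.64), 2 * 1.64)
    radii = [vdw_radius(x, 1.64) for x in (0.9, 1.0, 1.1)]
    assert radii[0] < radii[1] < radii[2]
    with pytest.raises(ValueError):
        vdw_radius(-0.1, 1.64)


def test_ts_combination_rule_homonuclear_identity():
    c6 = ts_combination_rule(80.0, 80.0, 5.0, 5.0)
    assert np.isclose(c6, 80.0)


def test_dispersion_asymptote_and_free_atom_limit():
    params = FFParameters()
    r = 40.0
    e = float(np.squeeze(ts_dispersion_elements(1.0, 1.0, 8, 8, r, params)))
    c6_free = params.free_atoms["O"]["c6_free"]
    assert abs(-e * r**6 - c6_free) / c6_free < 1e-3


def test_dispersion_sigmoid_limits_and_monotonicity():
    r = np.linspace(1e-3, 60.0, 500)
    f = dispersion_sigmoid(r, 3.3, 20.0, 0.94)
    assert f[0] < 1e-6 and abs(f[-1] - 1.0) < 1e-9
    assert np.all(np.diff(f) >= 0.0)
    assert np.all(np.diff(f)[r[:-1] < 8.0] > 0.0)


def test_dispersion_switch_is_one_then_zero():
    assert dispersion_switch(5.0, 10.0, 12.0) == 1.0
    assert dispersion_switch(12.0, 10.0, 12.0) == 0.0
    mid = dispersion_switch(np.linspace(10, 12, 50), 10.0, 12.0)
    assert np.all(np.diff(mid) <= 0.0)


# ------------------------------------------------------------------------ Ewald

def _rocksalt(a=5.64):
    frac = np.array([
        [0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5],
        [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5], [0.5, 0.5, 0.5],
    ])
    cell = np.eye(3) * a
    q = np.array([1.0] * 4 + [-1.0] * 4)
    system = AtomicSystem(["Na"] * 4 + ["Cl"] * 4, frac @ cell, cell, True)
    return system, q


def test_ewald_matches_brute_force_lattice_sum():
    system, q = _rocksalt()
    e = float(ewald_coulomb(system, q, accuracy=1e-6).data)
    ref = direct_lattice_sum(system.positions, q, system.cell, 7)
    assert abs(e - ref) / abs(ref) < 1e-4


def test_ewald_isolated_pair_large_box_limit():
    cell = np.eye(3) * 100.0
    system = AtomicSystem(["Na", "Cl"], [[0, 0, 0], [3.0, 0, 0]], cell, True)
    e = float(ewald_coulomb(system, np.array([1.0, -1.0]), 1e-5).data)
    bare = -COULOMB_CONSTANT / 3.0
    assert abs(e - bare) / abs(bare) < 1e-4


def test_ewald_is_independent_of_the_splitting_parameter():
    system, q = _rocksalt()
    acc = 1e-5
    e1 = float(ewald_coulomb(system, q, acc).data)
    from eqff.physics import ewald_parameters

    eta0, _, _ = ewald_parameters(system.cell, acc)
    e2 = float(ewald_coulomb(system, q, acc, eta=2 * eta0).data)
    assert abs(e2 - e1) / abs(e1) < acc


def test_ewald_rejects_non_neutral_and_non_periodic_inputs():
    system, q = _rocksalt()
    with pytest.raises(ValueError, match="neutral"):
        ewald_coulomb(system, q + 0.1)
    iso = AtomicSystem(["Na"], [[0, 0, 0]])
    with pytest.raises(ValueError, match="periodic"):
        ewald_coulomb(iso, np.array([0.0]))
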