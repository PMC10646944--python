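"""Equivariant embedding: shapes, symmetry, locality, limits."""

import numpy as np
from scipy.spatial.transform import Rotation

from eqff import autodiff as ad
from eqff.allegro import (
    AllegroConfig,
    embed_pairs,
    init_allegro_params,
    interaction_layer,
    two_body_embedding,
)
from eqff.geometry import AtomicSystem, build_pair_graph
from oracles import random_cluster, wigner_block


def _embed(model, species, pos):
    system = AtomicSystem(species, pos)
    graph = build_pair_graph(system, model.config.allegro.r_c)
    return embed_pairs(
        model.params, model.config.allegro, system.species, graph,
        ad.constant(pos),
    )


def test_two_body_is_zero_at_and_beyond_the_cutoff(midsize_model):
    cfg = midsize_model.config.allegro
    n_enc = 2 * cfg.encoding_dim
    enc = np.random.default_rng(0).normal(size=(3, n_enc))
    basis = ad.constant(np.zeros((3, cfg.n_basis)))
    env = ad.constant(np.zeros(3))  # envelope vanishes at the cutoff
    x = two_body_embedding(midsize_model.params, cfg, enc, basis, env)
    assert np.all(x.data == 0.0)


def test_full_size_configuration_dimensions():
    cfg = AllegroConfig()
    assert cfg.n_scalar == 256 and cfg.n_channels == 10
    assert cfg.l_max == 2 and cfg.n_layers == 3 and cfg.n_basis == 10
    assert cfg.r_c == 5.2 and cfg.envelope_p == 3


def test_embedding_shapes_and_layer_count(midsize_model, rng):
    species, pos = random_cluster(rng)
    emb = _embed(midsize_model, species, pos)
    cfg = midsize_model.config.allegro
    n_pairs = emb.graph.n_pairs
    assert emb.scalar.shape == (n_pairs, cfg.n_scalar)
    assert emb.x2b.shape == (n_pairs, cfg.n_scalar)
    assert emb.layer_index == cfg.n_layers
    for (l, p), block in emb.tensor.items():
        assert block.shape == (n_pairs, cfg.n_channels, 2 * l + 1)


def test_directed_pairs_differ_for_unlike_species(midsize_model):
    pos = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0]])
    emb = _embed(midsize_model, ["O", "H"], pos)
    # pair 0 is (0 -> 1) = O->H, pair 1 is H->O
    assert not np.allclose(emb.x2b.data[0], emb.x2b.data[1])


def test_scalar_invariance_and_tensor_equivariance(midsize_model, rng):
    species, pos = random_cluster(rng)
    emb = _embed(midsize_model, species, pos)
    for trial in range(5):
        rot = Rotation.random(random_state=trial).as_matrix()
        if trial % 2:
            rot = -rot  # improper rotation: tests parity handling too
        emb_r = _embed(midsize_model, species, pos @ rot.T)
        scale = np.abs(emb.scalar.data).max()
        assert np.abs(emb_r.scalar.data - emb.scalar.data).max() < 1e-10 * scale
        det = np.linalg.det(rot)
        proper = rot * det  # strip the inversion part
        for (l, p), block in emb.tensor.items():
            d = wigner_block(l, proper)
            parity_factor = 1.0 if det > 0 else p
            expected = np.einsum("kcm,nm->kcn", block.data, d) * parity_factor
            got = emb_r.tensor[(l, p)].data
            ref = max(np.abs(block.data).max(), 1e-12)
            assert np.abs(got - expected).max() < 1e-9 * ref


def test_strict_locality_is_bitwise(midsize_model):
    # d is within r_c of k only; moving d must not touch the (i, j) pair
    base = np.array([
        [0.0, 0.0, 0.0],   # i
        [1.0, 0.0, 0.0],   # j
        [4.5, 0.0, 0.0],   # k (neighbor of i and j)
        [9.0, 0.0, 0.0],   # d (beyond r_c from i and j)
    ])
    moved = base.copy()
    moved[3] = [9.3, 0.2, -0.1]
    species = ["O", "H", "H", "O"]
    e0 = _embed(midsize_model, species, base)
    e1 = _embed(midsize_model, species, moved)
    pair = np.nonzero((e0.graph.src == 0) & (e0.graph.dst == 1))[0][0]
    pair1 = np.nonzero((e1.graph.src == 0) & (e1.graph.dst == 1))[0][0]
    assert np.array_equal(e0.scalar.data[pair], e1.scalar.data[pair1])
    for key in e0.tensor:
        assert np.array_equal(
            e0.tensor[key].data[pair], e1.tensor[key].data[pair1]
        )


def test_environment_sum_is_smooth_as_a_neighbor_crosses_the_cutoff(midsize_model):
    r_c = midsize_model.config.allegro.r_c
    species = ["O", "H", "H"]

    def scalar_at(d):
        pos = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [d, 0.0, 0.0]])
        emb = _embed(midsize_model, species, pos)
        k = np.nonzero((emb.graph.src == 0) & (emb.graph.dst == 1))[0][0]
        return emb.scalar.data[k]

    inside = scalar_at(r_c - 1e-7)
    outside = scalar_at(r_c + 1e-7)
    assert np.abs(inside - outside).max() < 1e-12


def test_zero_mixing_coefficient_removes_the_residual_path(rng):
    """With alpha = 0 and a zeroed latent MLP the new scalars are exactly
    zero: the previous layer's scalars reach the output only through the
    latent path."""
    cfg = AllegroConfig(n_scalar=8, n_channels=2, l_max=1, n_layers=1,
                        two_body_hidden=(8,), latent_hidden=(8,), n_basis=4)
    params = init_allegro_params(cfg, np.random.default_rng(0))
    params["layer0.alpha_raw"] = ad.Tensor(-1e3)  # sigmoid == 0 exactly
    last = len(cfg.latent_hidden)
    params[f"layer0.latent.{last}.w"] = ad.Tensor(
        np.zeros_like(params[f"layer0.latent.{last}.w"].data)
    )
    params[f"layer0.latent.{last}.b"] = ad.Tensor(
        np.zeros_like(params[f"layer0.latent.{last}.b"].data)
    )
    species, pos = random_cluster(rng, symbols=("O", "H", "H"))
    system = AtomicSystem(species, pos)
    graph = build_pair_graph(system, cfg.r_c)
    emb = embed_pairs(params, cfg, system.species, graph, ad.constant(pos))
    assert np.all(emb.scalar.data == 0.0)


def test_isolated_atom_yields_empty_embedding(midsize_model):
    emb = _embed(midsize_model, ["C"], np.zeros((1, 3)))
    assert emb.scalar.shape[0] == 0
    assert emb.graph.n_pairs == 0


def test_permuting_identical_atoms_permutes_pair_embeddings(midsize_model, rng):
    species = ["C", "H", "H", "H"]
    _, pos = random_cluster(rng, symbols=tuple(species))
    e0 = _embed(midsize_model, species, pos)
    perm = np.array([0, 2, 3, 1])  # rotate the hydrogens
    e1 = _embed(midsize_model, [species[k] for k in perm], pos[perm])
    rows0 = {tuple(np.round(r, 10)) for r in e0.scalar.data}
    rows1 = {tuple(np.round(r, 10)) for r in e1.scalar.data}
    assert rows0 == rows1


def test_mixing_coefficients_are_one_parameter_per_layer(midsize_model):
    cfg = midsize_model.config.allegro
    alphas = [
        midsize_model.params[f"layer{L}.alpha_raw"] for L in range(cfg.n_layers)
    ]
    for a in alphas:
        val = float(ad.sigmoid(a).data)
        assert 0.0 <= val < 1.0
        assert a.size == 1
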