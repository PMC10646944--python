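"""Strictly local equivariant pair embedding (Allegro-style).

Each directed pair (i, j) within the cutoff carries a scalar feature vector
x_ij and tensor features V_ij^{nlp} indexed by channel n, rotational order l
and parity p. A two-body block initializes the features from the species
encodings and the radial basis; N_layers interaction layers then (a) build
an equivariant neighborhood summary Gamma_i by summing spherical-harmonic
projections of atom i's neighbors weighted by learned functions of the
scalar features, (b) take a channel-wise tensor product Gamma_i x V_ij over
all symmetry-allowed paths, (c) update the scalar track through a latent
MLP with a normalization-preserving mixing coefficient alpha, and (d)
filter the tensor paths back to N_channels channels with learned linear
weights.

Everything runs on autodiff Tensors so that forces and force-matching
training differentiate through the embedding. Tensor blocks are stored in a
dict keyed by (l, parity); blocks that are identically zero are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .coupling import real_coupling
from .encoding import encoding_matrix
from .geometry import (
    PairGraph,
    bessel_basis,
    polynomial_envelope,
    real_spherical_harmonics,
)

SQRT2_INV = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class AllegroConfig:
    """Hyperparameters of the embedding (defaults: the full-size model)."""

    r_c: float = 5.2  # Angstrom
    n_basis: int = 10
    envelope_p: int = 3
    n_scalar: int = 256
    n_channels: int = 10
    l_max: int = 2
    n_layers: int = 3
    two_body_hidden: tuple = (64, 128)
    latent_hidden: tuple = (256, 256)
    d_row: int = 5
    d_col: int = 10
    gamma_row: float = 100.0
    gamma_col: float = 1000.0
    alpha_init: float = SQRT2_INV
    avg_num_neighbors: float = 20.0  # fixed normalization of the env. sum

    @property
    def encoding_dim(self) -> int:
        return self.d_row + self.d_col

    @property
    def sh_blocks(self):
        """(l, parity) blocks carried by spherical harmonics."""
        return [(l, (-1) ** l) for l in range(self.l_max + 1)]

    @property
    def feature_blocks(self):
        """Full (l, parity) layout of the tensor features."""
        return [
            (l, p) for l in range(self.l_max + 1) for p in (1, -1)
        ]

    def paths(self):
        """Symmetry-allowed (gamma_block, feature_block) -> out_block paths."""
        out = []
        for (l1, p1) in self.sh_blocks:
            for (l2, p2) in self.feature_blocks:
                for l in range(abs(l1 - l2), min(l1 + l2, self.l_max) + 1):
                    out.append(((l1, p1), (l2, p2), (l, p1 * p2)))
        return out

    def path_multiplicity(self):
        mult = {}
        for _, _, out in self.paths():
            mult[out] = mult.get(out, 0) + 1
        return mult


@dataclass
class EquivariantEmbedding:
    """Per-pair features produced by the embedding."""

    x2b: Tensor  # (n_pairs, n_scalar) two-body scalars
    scalar: Tensor  # (n_pairs, n_scalar) current scalar features
    tensor: dict  # (l, p) -> Tensor (n_pairs, n_channels, 2l+1)
    envelope: Tensor  # (n_pairs,)
    harmonics: Tensor  # (n_pairs, (l_max+1)^2)
    graph: PairGraph
    layer_index: int = 0


# ---------------------------------------------------------------------------
# parameter initialization

def _init_linear(rng, fan_in, fan_out, bias=True, prefix="", params=None):
    params[prefix + ".w"] = Tensor(
        rng.normal(size=(fan_in, fan_out)) / np.sqrt(fan_in)
    )
    if bias:
        params[prefix + ".b"] = Tensor(np.zeros(fan_out))


def _init_mlp(rng, dims, prefix, params):
    for k in range(len(dims) - 1):
        _init_linear(rng, dims[k], dims[k + 1], True, f"{prefix}.{k}", params)


def init_allegro_params(config: AllegroConfig, rng) -> dict:
    """Seeded scaled-Gaussian initialization of all embedding weights."""
    p: dict[str, Tensor] = {}
    two_body_in = 2 * config.encoding_dim + config.n_basis
    _init_mlp(
        rng,
        (two_body_in, *config.two_body_hidden, config.n_scalar),
        "two_body",
        p,
    )
    n_lw = config.n_channels * (config.l_max + 1)
    _init_linear(rng, config.n_scalar, n_lw, False, "embed2b", p)
    mult = config.path_multiplicity()
    n_scalar_latent = mult[(0, 1)] * config.n_channels
    for L in range(config.n_layers):
        _init_linear(rng, config.n_scalar, n_lw, False, f"layer{L}.embed", p)
        _init_mlp(
            rng,
            (
                config.n_scalar + n_scalar_latent,
                *config.latent_hidden,
                config.n_scalar,
            ),
            f"layer{L}.latent",
            p,
        )
        a0 = config.alpha_init
        p[f"layer{L}.alpha_raw"] = Tensor(np.log(a0 / (1.0 - a0)))
        for (l, par), m in mult.items():
            fan = m * config.n_channels
            p[f"layer{L}.path.{l}.{par}"] = Tensor(
                rng.normal(size=(config.n_channels, fan)) / np.sqrt(fan)
            )
    return p


# ---------------------------------------------------------------------------
# forward operations

def _mlp(params, prefix, x, n_layers, activation=ad.silu):
    for k in range(n_layers):
        x = ad.einsum("pi,io->po", x, params[f"{prefix}.{k}.w"])
        b = params.get(f"{prefix}.{k}.b")
        if b is not None:
            x = x + ad.reshape(b, (1, b.size))
        if k < n_layers - 1:
            x = activation(x)
    return x


def _sh_block(Y: Tensor, l: int) -> Tensor:
    return ad.narrow(Y, 1, l * l, 2 * l + 1)


def _lweights(params, key, x, config, envelope):
    """Linear no-bias map of scalars to per-(channel, l) weights x envelope."""
    w = ad.einsum("pi,io->po", x, params[key])
    w = w * ad.reshape(envelope, (envelope.shape[0], 1))
    return ad.reshape(
        w, (x.shape[0], config.n_channels, config.l_max + 1)
    )


def two_body_embedding(params, config: AllegroConfig, enc_pair, basis, envelope):
    """Scalar two-body features: MLP over [Z_i || Z_j || B(R)] times f_c."""
    if enc_pair.shape[1] != 2 * config.encoding_dim:
        raise ValueError("species encoding dimension mismatch")
    h = ad.concatenate([ad.constant(enc_pair), basis], axis=1)
    x = _mlp(params, "two_body", h, len(config.two_body_hidden) + 1)
    return x * ad.reshape(envelope, (envelope.shape[0], 1))


def init_equivariant(params, config: AllegroConfig, x2b, harmonics, envelope):
    """Initial tensor features: per-channel linear weights times Y^{lp}."""
    w = _lweights(params, "embed2b.w", x2b, config, envelope)
    V = {}
    n_pairs = x2b.shape[0]
    for l, par in config.sh_blocks:
        wl = ad.narrow(w, 2, l, 1)  # (P, C, 1)
        Yl = ad.reshape(_sh_block(harmonics, l), (n_pairs, 1, 2 * l + 1))
        V[(l, par)] = wl * Yl
    # blocks of the opposite parity start at zero so that every layer sees
    # the same fixed (l, p) feature layout
    for l, par in config.feature_blocks:
        if (l, par) not in V:
            V[(l, par)] = ad.constant(
                np.zeros((n_pairs, config.n_channels, 2 * l + 1))
            )
    return V


def interaction_layer(
    params, config: AllegroConfig, embedding: EquivariantEmbedding, layer: int
):
    """One interaction layer; returns the updated embedding."""
    graph = embedding.graph
    x, V = embedding.scalar, embedding.tensor
    n_pairs, n_atoms = graph.n_pairs, graph.n_atoms
    Y, env = embedding.harmonics, embedding.envelope

    # (a) equivariant neighborhood summary per atom, gathered back to pairs
    w = _lweights(params, f"layer{layer}.embed.w", x, config, env)
    gamma = {}
    scale = 1.0 / np.sqrt(config.avg_num_neighbors)
    for l, par in config.sh_blocks:
        wl = ad.narrow(w, 2, l, 1)
        Yl = ad.reshape(_sh_block(Y, l), (n_pairs, 1, 2 * l + 1))
        per_atom = ad.segment_sum(wl * Yl, graph.src, n_atoms) * scale
        gamma[(l, par)] = ad.take(per_atom, graph.src, axis=0)

    # (b) channel-wise tensor product over all allowed paths
    produced: dict[tuple, list] = {}
    for b1, b2, out in config.paths():
        if b2 not in V:
            continue
        K = real_coupling(b1[0], b2[0], out[0])
        t = ad.einsum("mnp,kcn,kcp->kcm", ad.constant(K), gamma[b1], V[b2])
        produced.setdefault(out, []).append(t)

    # (c) scalar track update with normalization-preserving mixing
    scalars = [
        ad.reshape(t, (n_pairs, config.n_channels))
        for t in produced.get((0, 1), [])
    ]
    latent_in = ad.concatenate([x] + scalars, axis=1)
    x_tilde = _mlp(
        params,
        f"layer{layer}.latent",
        latent_in,
        len(config.latent_hidden) + 1,
    )
    alpha = ad.sigmoid(params[f"layer{layer}.alpha_raw"])
    x_new = alpha * x + (1.0 - alpha * alpha) ** 0.5 * x_tilde

    # (d) filter paths back to n_channels with learned linear weights
    V_new = {}
    for out, tensors in produced.items():
        l, par = out
        stacked = ad.concatenate(
            [ad.reshape(t, (n_pairs, config.n_channels, 2 * l + 1)) for t in tensors],
            axis=1,
        )  # (P, n_paths*C, 2l+1)
        wkey = params[f"layer{layer}.path.{l}.{par}"]
        fan = wkey.shape[1]
        V_new[out] = ad.einsum("dq,kqm->kdm", wkey, stacked) * (1.0 / np.sqrt(fan))

    return EquivariantEmbedding(
        x2b=embedding.x2b,
        scalar=x_new,
        tensor=V_new,
        envelope=env,
        harmonics=Y,
        graph=graph,
        layer_index=layer + 1,
    )


def embed_pairs(
    params,
    config: AllegroConfig,
    species: np.ndarray,
    graph: PairGraph,
    positions: Tensor,
    cell: np.ndarray | None = None,
) -> EquivariantEmbedding:
    """Full embedding: two-body init + n_layers interaction layers.

    `positions` is a Tensor so downstream energies can be differentiated
    for forces. An empty pair graph (isolated atoms) is valid and returns
    an empty embedding.
    """
    disp = ad.take(positions, graph.dst, 0) + (-ad.take(positions, graph.src, 0))
    if graph.shifts is not None:
        disp = disp + ad.constant(graph.shifts @ cell)
    r = ad.norm(disp, axis=-1)
    rcol = ad.reshape(r, (graph.n_pairs, 1))
    unit = disp * ad.power(rcol, -1.0)

    env = polynomial_envelope(r, config.r_c, config.envelope_p)
    basis = bessel_basis(r, config.r_c, config.n_basis, config.envelope_p)
    Y = real_spherical_harmonics(unit, config.l_max)

    enc = encoding_matrix(
        species,
        d_row=config.d_row,
        d_col=config.d_col,
        gamma_row=config.gamma_row,
        gamma_col=config.gamma_col,
    )
    enc_pair = np.concatenate([enc[graph.src], enc[graph.dst]], axis=1)

    x2b = two_body_embedding(params, config, enc_pair, basis, env)
    V = init_equivariant(params, config, x2b, Y, env)
    emb = EquivariantEmbedding(
        x2b=x2b, scalar=x2b, tensor=V, envelope=env, harmonics=Y, graph=graph
    )
    for L in range(config.n_layers):
        emb = interaction_layer(params, config, emb, L)
    return emb
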