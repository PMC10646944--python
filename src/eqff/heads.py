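"""Output heads: pairwise predictions aggregated into atomic properties.

Three independent MLPs read the concatenation of the two-body scalar
embedding and the final scalar embedding and predict, per directed pair, a
local energy contribution e_ij, a charge exchange dq_ij and a volume
contribution u_ij. Aggregation sums pairs on the central atom; charges are
antisymmetrized (q_i = sum_j dq_ij - dq_ji), which makes the total charge
exactly zero by construction, and volume ratios go through a softplus so
they are strictly positive. Isolated atoms (no pairs) get zero energy, zero
charge and the softplus(0) ratio, so the total model energy of a fully
dissociated system is exactly the sum of the isolated-atom reference
energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .elements import symbol
from .geometry import PairGraph

DEFAULT_HEAD_HIDDEN = (256, 128, 64, 32, 16)
OUTPUT_NAMES = ("energy", "charge", "volume")


@dataclass
class AtomicProperties:
    """Per-atom results of head aggregation (autodiff Tensors)."""

    local_energy: Tensor  # (n_atoms,) kcal/mol
    charge: Tensor  # (n_atoms,) e, sums to zero
    volume_ratio: Tensor  # (n_atoms,) dimensionless, > 0
    pair_drain: Tensor  # (n_pairs,) antisymmetrized charge exchange per pair


def init_head_params(rng, n_scalar: int, hidden=DEFAULT_HEAD_HIDDEN, outputs=OUTPUT_NAMES):
    params: dict[str, Tensor] = {}
    dims = (2 * n_scalar, *hidden, 1)
    for name in outputs:
        for k in range(len(dims) - 1):
            params[f"head.{name}.{k}.w"] = Tensor(
                rng.normal(size=(dims[k], dims[k + 1])) / np.sqrt(dims[k])
            )
            params[f"head.{name}.{k}.b"] = Tensor(np.zeros(dims[k + 1]))
    return params


def head_forward(params, x2b: Tensor, x_final: Tensor, hidden=DEFAULT_HEAD_HIDDEN,
                 outputs=OUTPUT_NAMES) -> dict:
    """Raw per-pair outputs of the three heads (no constraints applied)."""
    if x2b is None:
        raise ValueError("two-body embedding is required by the output heads")
    h = ad.concatenate([x2b, x_final], axis=1)
    n_pairs = h.shape[0]
    out = {}
    for name in outputs:
        x = h
        n_layers = len(hidden) + 1
        for k in range(n_layers):
            x = ad.einsum("pi,io->po", x, params[f"head.{name}.{k}.w"])
            b = params[f"head.{name}.{k}.b"]
            x = x + ad.reshape(b, (1, b.size))
            if k < n_layers - 1:
                x = ad.silu(x)
        out[name] = ad.reshape(x, (n_pairs,))
    return out


def aggregate(outputs: dict, graph: PairGraph) -> AtomicProperties:
    """Sum pairwise outputs on the central atom with the head constraints."""
    n = graph.n_atoms
    e = ad.segment_sum(outputs["energy"], graph.src, n)
    rev = graph.reverse_index()
    dq = outputs["charge"]
    drain = dq + (-ad.take(dq, rev, 0))  # dq_ij - dq_ji, exactly antisymmetric
    q = ad.segment_sum(drain, graph.src, n)
    v = ad.softplus(ad.segment_sum(outputs["volume"], graph.src, n))
    return AtomicProperties(local_energy=e, charge=q, volume_ratio=v, pair_drain=drain)


def reference_energy(species, table: dict) -> float:
    """Sum of per-element isolated-atom reference energies (kcal/mol)."""
    total = 0.0
    for z in np.asarray(species, dtype=np.intp):
        sym = symbol(int(z))
        if sym not in table:
            raise ValueError(f"no reference energy for element {sym}")
        total += float(table[sym])
    return total
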