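"""Smooth positional encoding of chemical species.

Each element is mapped to the sine/cosine encoding of its (period, group)
coordinates in the periodic table, in the transformer style: component pairs
are sin and cos of the coordinate divided by gamma**(2i/d). Elements sharing
a period have identical row blocks, elements sharing a group identical
column blocks, and the encoding is a smooth function of (row, col) treated
as real numbers, which allows interpolating between (and perturbing)
chemical species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import PeriodicCoords, Z_MAX, atomic_number, periodic_coords

# defaults used by the full-size model
D_ROW, D_COL = 5, 10
GAMMA_ROW, GAMMA_COL = 100.0, 1000.0


@dataclass(frozen=True)
class SpeciesEncoding:
    """Concatenated [row-block || column-block] encoding of one species."""

    values: np.ndarray
    d_row: int = D_ROW
    d_col: int = D_COL
    gamma_row: float = GAMMA_ROW
    gamma_col: float = GAMMA_COL

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.values.shape != (self.d_row + self.d_col,):
            raise ValueError("encoding length must equal d_row + d_col")

    @property
    def row_block(self) -> np.ndarray:
        return self.values[: self.d_row]

    @property
    def col_block(self) -> np.ndarray:
        return self.values[self.d_row:]


def positional_block(coord: float, d: int, gamma: float) -> np.ndarray:
    """sin/cos encoding of one real coordinate into d components.

    Component 2i is sin(c / gamma**(2i/d)), component 2i+1 is
    cos(c / gamma**(2i/d)); an odd d ends with an unpaired sine.
    """
    if d < 1:
        raise ValueError("encoding dimension must be positive")
    if gamma <= 1.0:
        raise ValueError("frequency parameter gamma must exceed 1")
    k = np.arange(d)
    args = coord / gamma ** (2 * (k // 2) / d)
    out = np.where(k % 2 == 0, np.sin(args), np.cos(args))
    return out


def encode_species(
    coords,
    d_row: int = D_ROW,
    d_col: int = D_COL,
    gamma_row: float = GAMMA_ROW,
    gamma_col: float = GAMMA_COL,
) -> SpeciesEncoding:
    """Encode periodic-table coordinates (a PeriodicCoords or (row, col)).

    Real-valued coordinates are accepted: the encoding is smooth, which is
    what enables the perturbed- and averaged-species experiments.
    """
    if isinstance(coords, PeriodicCoords):
        row, col = float(coords.row), float(coords.col)
    else:
        row, col = (float(c) for c in coords)
    values = np.concatenate(
        [
            positional_block(row, d_row, gamma_row),
            positional_block(col, d_col, gamma_col),
        ]
    )
    return SpeciesEncoding(values, d_row, d_col, gamma_row, gamma_col)


_CACHE: dict[tuple, SpeciesEncoding] = {}


def encode_element(
    element,
    d_row: int = D_ROW,
    d_col: int = D_COL,
    gamma_row: float = GAMMA_ROW,
    gamma_col: float = GAMMA_COL,
) -> SpeciesEncoding:
    """Cached encoding of a chemical element (symbol or atomic number)."""
    z = atomic_number(element)
    key = (z, d_row, d_col, gamma_row, gamma_col)
    if key not in _CACHE:
        _CACHE[key] = encode_species(
            periodic_coords(z), d_row, d_col, gamma_row, gamma_col
        )
    return _CACHE[key]


def encoding_matrix(species, **kwargs) -> np.ndarray:
    """Stack encodings for an array of atomic numbers into (N, d) floats."""
    return np.stack([encode_element(int(z), **kwargs).values for z in species])


def average_encoding(encodings) -> SpeciesEncoding:
    """Componentwise mean of encodings (the 'fictitious element')."""
    encodings = list(encodings)
    if not encodings:
        raise ValueError("cannot average an empty list of encodings")
    first = encodings[0]
    for e in encodings[1:]:
        if e.values.shape != first.values.shape:
            raise ValueError("encodings must share dimensions")
    mean = np.mean([e.values for e in encodings], axis=0)
    return SpeciesEncoding(
        mean, first.d_row, first.d_col, first.gamma_row, first.gamma_col
    )


def average_element_encoding(z_min: int = 1, z_max: int = Z_MAX, **kwargs):
    """Average encoding over a contiguous range of elements (default H-Xe)."""
    return average_encoding(
        [encode_element(z, **kwargs) for z in range(z_min, z_max + 1)]
    )


def encoding_distance_distribution(elements, **kwargs):
    """Euclidean distances in encoding space.

    Returns (pair_distances, distances_to_average): distances over all
    unordered pairs of the given elements, and from each element to the
    average encoding of the set.
    """
    elements = list(elements)
    if len(elements) < 2:
        raise ValueError("need at least 2 elements")
    encs = np.stack([encode_element(e, **kwargs).values for e in elements])
    diff = encs[:, None, :] - encs[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    iu = np.triu_indices(len(elements), k=1)
    pair_distances = dist[iu]
    avg = encs.mean(axis=0)
    to_average = np.sqrt(np.sum((encs - avg) ** 2, axis=-1))
    return pair_distances, to_average
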