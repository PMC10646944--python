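"""Coupling coefficients for real spherical-harmonic tensors.

The equivariant layers combine tensor features with a channel-wise tensor
product; the symmetry-allowed paths (l1, l2) -> l with |l1-l2| <= l <= l1+l2
are contracted with real Clebsch-Gordan coefficients. These are obtained
from the complex Clebsch-Gordan coefficients (sympy) conjugated by the
unitary change of basis between complex and real spherical harmonics
(Condon-Shortley phase). Each path tensor is normalized to unit Frobenius
norm; any fixed per-path scale is absorbed by the learned path weights.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_SQRT2_INV = 1.0 / np.sqrt(2.0)


@lru_cache(maxsize=None)
def complex_to_real_matrix(l: int) -> np.ndarray:
    """U with y_real[m] = sum_mu U[m, mu] y_complex[mu], rows/cols m=-l..l."""
    dim = 2 * l + 1
    U = np.zeros((dim, dim), dtype=np.complex128)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        U[l + m, l + m] = (-1) ** m * _SQRT2_INV
        U[l + m, l - m] = _SQRT2_INV
        U[l - m, l - m] = 1j * _SQRT2_INV
        U[l - m, l + m] = -1j * (-1) ** m * _SQRT2_INV
    return U


@lru_cache(maxsize=None)
def _complex_cg(l1: int, l2: int, l: int) -> np.ndarray:
    """<l m | l1 m1, l2 m2> with shape (2l+1, 2l1+1, 2l2+1)."""
    from sympy import S
    from sympy.physics.quantum.cg import CG

    out = np.zeros((2 * l + 1, 2 * l1 + 1, 2 * l2 + 1))
    for m1 in range(-l1, l1 + 1):
        for m2 in range(-l2, l2 + 1):
            m = m1 + m2
            if abs(m) > l:
                continue
            coeff = CG(S(l1), S(m1), S(l2), S(m2), S(l), S(m)).doit()
            out[l + m, l1 + m1, l2 + m2] = float(coeff)
    return out


@lru_cache(maxsize=None)
def real_coupling(l1: int, l2: int, l: int) -> np.ndarray:
    """Real coupling tensor K with T[m] = sum K[m, m1, m2] A[m1] B[m2].

    If A and B transform as real spherical harmonics of orders l1 and l2,
    T transforms as order l. Normalized to unit Frobenius norm. Raises if
    the path is not allowed by the triangle inequality.
    """
    if not abs(l1 - l2) <= l <= l1 + l2:
        raise ValueError(f"path {l1} x {l2} -> {l} violates triangle rule")
    cg = _complex_cg(l1, l2, l)
    Ul = complex_to_real_matrix(l)
    U1c = complex_to_real_matrix(l1).conj()
    U2c = complex_to_real_matrix(l2).conj()
    K = np.einsum("ma,aij,ni,pj->mnp", Ul, cg, U1c, U2c)
    re_norm, im_norm = np.linalg.norm(K.real), np.linalg.norm(K.imag)
    if re_norm >= im_norm:
        assert im_norm < 1e-10 * max(re_norm, 1.0), "coupling not real"
        K = K.real
    else:
        # odd l1+l2+l paths come out purely imaginary; the overall phase is
        # conventional and i*K is an equally valid real equivariant coupling
        assert re_norm < 1e-10 * im_norm, "coupling not imaginary"
        K = K.imag
    return K / np.linalg.norm(K)


def allowed_paths(l_max_in1, l_max_in2, l_max_out):
    """All (l1, l2, l) with l1 <= l_max_in1, l2 <= l_max_in2, l <= l_max_out."""
    paths = []
    for l1 in range(l_max_in1 + 1):
        for l2 in range(l_max_in2 + 1):
            for l in range(abs(l1 - l2), min(l1 + l2, l_max_out) + 1):
                paths.append((l1, l2, l))
    return paths
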