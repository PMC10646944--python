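"""Trajectory analyses: radial distribution functions and dipole spectra."""

from __future__ import annotations

import numpy as np

from .elements import atomic_number
from .md import Trajectory

# speed of light in cm/fs, for the wavenumber axis of spectra
C_CM_PER_FS = 2.99792458e-5


def radial_distribution(
    traj: Trajectory, species_pair, r_max: float, n_bins: int = 100
):
    """Partial radial distribution function g(r) for one species pair.

    Distances use the minimum-image convention, so r_max must not exceed
    half the smallest cell height. Normalization is by the ideal-gas shell
    count, so g -> 1 at large r for a homogeneous system. Returns
    (bin_centers, g).
    """
    if not traj.periodic:
        raise ValueError("RDF normalization requires a periodic trajectory")
    cell = traj.cell
    vol = abs(np.linalg.det(cell))
    heights = vol / np.linalg.norm(
        np.cross(np.roll(cell, -1, axis=0), np.roll(cell, -2, axis=0)), axis=1
    )
    if r_max > 0.5 * heights.min() + 1e-9:
        raise ValueError("r_max exceeds half the smallest cell height")

    za, zb = (atomic_number(s) for s in species_pair)
    ia = np.nonzero(traj.species == za)[0]
    ib = np.nonzero(traj.species == zb)[0]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("species not present in the trajectory")

    inv = np.linalg.inv(cell)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    frames = traj.wrapped_frames()
    for frame in frames:
        diff = frame[ib][None, :, :] - frame[ia][:, None, :]
        frac = diff @ inv
        frac -= np.round(frac)
        d = np.linalg.norm(frac @ cell, axis=-1)
        if za == zb:
            iu = np.triu_indices(len(ia), 1)
            d = d[iu]
            n_pairs = len(ia) * (len(ia) - 1) / 2
        else:
            d = d.ravel()
            n_pairs = len(ia) * len(ib)
        hist += np.histogram(d, bins=edges)[0]

    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / vol
    g = hist / (len(frames) * ideal)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def coordination_number(centers, g, rho, r_limit):
    """Integral of rho g(r) 4 pi r^2 dr up to r_limit (neighbor count).

    Uses the exact spherical-shell volumes of the histogram bins, so for a
    uniform-bin RDF the identity count = sum(rho g V_shell) holds exactly
    by construction.
    """
    centers = np.asarray(centers)
    dr = centers[1] - centers[0]
    lo, hi = centers - dr / 2.0, centers + dr / 2.0
    mask = centers <= r_limit
    shells = 4.0 / 3.0 * np.pi * (hi[mask] ** 3 - lo[mask] ** 3)
    return float(np.sum(rho * g[mask] * shells))


def total_dipole(traj: Trajectory) -> np.ndarray:
    """M(t) = sum_i q_i(t) r_i(t) per frame (e*Angstrom).

    Uses unwrapped coordinates; for neutral systems the result is
    origin-independent.
    """
    if traj.charges is None:
        raise ValueError("trajectory carries no per-frame charges")
    return np.einsum("fn,fnd->fd", traj.charges, traj.frames)


def dipole_spectrum(traj: Trajectory, window: str = "hann"):
    """Power spectrum of the total-dipole autocorrelation.

    Returns (wavenumbers_cm1, intensity). The autocorrelation of M(t) is
    computed per Cartesian component, summed, apodized with a Hann window
    and Fourier transformed; the frequency axis is in 1/cm.
    """
    m = total_dipole(traj)
    m = m - m.mean(axis=0)
    n = len(m)
    # FFT-based autocorrelation, averaged over time origins
    nfft = 2 * n
    acf = np.zeros(n)
    for k in range(3):
        f = np.fft.rfft(m[:, k], nfft)
        c = np.fft.irfft(f * np.conj(f), nfft)[:n]
        acf += c.real
    acf /= np.arange(n, 0, -1)
    if window == "hann":
        acf = acf * np.hanning(2 * n)[n:]
    spec = np.abs(np.fft.rfft(acf))
    freq_per_fs = np.fft.rfftfreq(n, d=traj.dt)
    wavenumber = freq_per_fs / C_CM_PER_FS
    return wavenumber, spec
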