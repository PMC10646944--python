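"""Readers and writers for XYZ / extended-XYZ, and a PDB coordinate reader.

Extended XYZ follows the common 'Lattice="ax ay az bx by bz cx cy cz"'
comment-line dialect; only species and positions are read (a Properties
entry, if present, is assumed to start with species:S:1:pos:R:3). PDB
parsing delegates to biotite and keeps only species and coordinates.
"""

from __future__ import annotations

import re

import numpy as np

from .elements import symbol
from .geometry import AtomicSystem
from .md import Trajectory

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"', re.IGNORECASE)


def read_xyz(path) -> list:
    """Read all frames of an (extended) XYZ file into AtomicSystems."""
    systems = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        comment = lines[k + 1]
        cell, periodic = None, False
        m = _LATTICE_RE.search(comment)
        if m:
            cell = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            periodic = True
        species, pos = [], []
        for line in lines[k + 2:k + 2 + n]:
            parts = line.split()
            species.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        systems.append(AtomicSystem(species, np.asarray(pos), cell, periodic))
        k += 2 + n
    return systems


def write_xyz(path, systems, comments=None):
    """Write AtomicSystem(s) as (extended) XYZ."""
    if isinstance(systems, AtomicSystem):
        systems = [systems]
    with open(path, "w") as fh:
        for idx, system in enumerate(systems):
            fh.write(f"{system.n_atoms}\n")
            comment = comments[idx] if comments else ""
            if system.periodic:
                flat = " ".join(f"{x:.10g}" for x in system.cell.ravel())
                comment = f'Lattice="{flat}" ' + comment
            fh.write(comment.strip() + "\n")
            for z, p in zip(system.species, system.positions):
                fh.write(
                    f"{symbol(int(z)):2s} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}\n"
                )


def write_trajectory_xyz(path, traj: Trajectory):
    systems = [
        AtomicSystem(traj.species, frame, traj.cell, traj.periodic)
        for frame in traj.frames
    ]
    comments = None
    if traj.energies is not None:
        comments = [f"energy={e:.8f}" for e in traj.energies]
    write_xyz(path, systems, comments)


def read_pdb(path) -> AtomicSystem:
    """Species and coordinates from a PDB file (no connectivity is used)."""
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    species = [e.capitalize() for e in structure.element]
    return AtomicSystem(species, np.asarray(structure.coord, dtype=float))
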