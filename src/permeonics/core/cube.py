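"""Gaussian cube file I/O.

The cube standard stores the grid origin and voxel vectors in Bohr when
the voxel counts are positive (the usual case) and in Å when they are
negative. Values are a scalar field with z as the fastest index, six per
line. Internally everything is converted to Å and e/Å³.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..constants import BOHR_TO_ANGSTROM
from .elements import SYMBOL_TO_Z, Z_TO_SYMBOL
from .roles import infer_water_topology
from .types import AtomRecord, DensityGrid


class CubeParseError(ValueError):
    pass


class UnsupportedGridError(ValueError):
    pass


def read_cube(path, infer_molecules: bool = True) -> DensityGrid:
    """Read a Gaussian cube file into a DensityGrid (Å, e/Å³).

    Only axis-aligned voxel vectors are supported. When ``infer_molecules``
    is set, water molecules and ions in the atom block are grouped
    geometrically (the cube format carries no residue topology).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise CubeParseError(f"{path}: file too short for a cube header")
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
    except (IndexError, ValueError):
        raise CubeParseError(f"{path}:3: malformed atom-count/origin line")
    if natoms < 0:
        raise UnsupportedGridError(
            f"{path}: orbital cube files (negative atom count) are not supported")

    counts = np.empty(3, dtype=int)
    vox = np.zeros((3, 3))
    for i in range(3):
        parts = lines[3 + i].split()
        try:
            counts[i] = int(parts[0])
            vox[i] = [float(x) for x in parts[1:4]]
        except (IndexError, ValueError):
            raise CubeParseError(f"{path}:{4 + i}: malformed voxel-vector line")
    # positive counts signal Bohr units per the cube convention
    bohr = np.all(counts > 0)
    shape = np.abs(counts)
    scale = BOHR_TO_ANGSTROM if bohr else 1.0
    origin = origin * scale
    vox = vox * scale
    off_diag = vox - np.diag(np.diag(vox))
    if np.any(np.abs(off_diag) > 1e-10):
        raise UnsupportedGridError(f"{path}: non-axis-aligned voxel vectors")

    atoms = []
    for j in range(natoms):
        parts = lines[6 + j].split()
        try:
            z = int(float(parts[0]))
            pos = np.array([float(x) for x in parts[2:5]]) * scale
        except (IndexError, ValueError):
            raise CubeParseError(f"{path}:{7 + j}: malformed atom line")
        sym = Z_TO_SYMBOL.get(z)
        if sym is None:
            raise CubeParseError(f"{path}:{7 + j}: unknown atomic number {z}")
        atoms.append(AtomRecord(sym, pos, "other", j, j))
    if infer_molecules and atoms:
        infer_water_topology(atoms)

    data = []
    for ln in lines[6 + natoms:]:
        data.extend(float(x) for x in ln.split())
    npts = int(shape[0] * shape[1] * shape[2])
    if len(data) != npts:
        raise CubeParseError(
            f"{path}: expected {npts} grid values, found {len(data)}")
    values = np.array(data).reshape(shape)
    if bohr:
        values = values / BOHR_TO_ANGSTROM**3  # e/Bohr³ -> e/Å³
    return DensityGrid(origin=origin, voxel_vectors=vox, values=values, atoms=atoms)


def write_cube(grid: DensityGrid, path, comment: str = "permeonics density") -> None:
    """Write a DensityGrid as a standard cube file (Bohr units, e/Bohr³)."""
    b = BOHR_TO_ANGSTROM
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by permeonics (Bohr units)\n")
        o = grid.origin / b
        fh.write(f"{len(grid.atoms):5d} {o[0]:15.9f} {o[1]:15.9f} {o[2]:15.9f}\n")
        for i in range(3):
            v = grid.voxel_vectors[i] / b
            fh.write(f"{grid.shape[i]:5d} {v[0]:15.9f} {v[1]:15.9f} {v[2]:15.9f}\n")
        for a in grid.atoms:
            z = SYMBOL_TO_Z[a.element]
            p = a.position / b
            fh.write(f"{z:5d} {float(z):12.6f} {p[0]:15.9f} {p[1]:15.9f} {p[2]:15.9f}\n")
        vals = (grid.values * b**3).reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        for row in vals:
            for k in range(0, len(row), 6):
                fh.write("".join(f"{v:17.9E}" for v in row[k:k + 6]) + "\n")
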