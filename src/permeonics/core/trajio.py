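"""Trajectory readers and writers.

XYZ is parsed in-package (the standard format carries no box, so we read
and write a ``box=Lx,Ly,Lz`` token on the comment line, plus an optional
``time=`` token in ns). PDB and GRO go through MDAnalysis, which handles
multi-model PDB trajectories and residue topology.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .elements import normalize_symbol
from .roles import RoleMap
from .types import AtomRecord, Frame, Trajectory


class TrajectoryParseError(ValueError):
    """Raised for malformed trajectory files; carries a line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.line = line


def read_trajectory(path, fmt: str = "auto", role_map: RoleMap | None = None,
                    box=None, dt: float = 1.0) -> Trajectory:
    """Read a trajectory from an XYZ, PDB or GRO file.

    Parameters
    ----------
    path : path-like
    fmt : {"auto", "xyz", "pdb", "gro"}
        "auto" dispatches on the file extension.
    role_map : RoleMap, optional
        Element/residue rules used to tag atoms.
    box : 3-sequence of float, optional
        Box edge lengths in Å; overrides (and is required in the absence
        of) box metadata in the file.
    dt : float
        Frame spacing in ns used when the file carries no time stamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path, role_map or RoleMap(), box, dt)
    if fmt in ("pdb", "gro"):
        return _read_mdanalysis(path, role_map or RoleMap(), box, dt)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _parse_comment_tokens(comment: str) -> dict:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key.strip().lower()] = val
    return out


def _read_xyz(path: Path, role_map: RoleMap, box, dt: float) -> Trajectory:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nline = len(lines)
    k = 0
    while i < nline:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError:
            raise TrajectoryParseError("expected atom count", path, i + 1)
        tokens = _parse_comment_tokens(lines[i + 1] if i + 1 < nline else "")
        fbox = box
        if "box" in tokens:
            try:
                fbox = [float(x) for x in tokens["box"].split(",")]
            except ValueError:
                raise TrajectoryParseError("malformed box= token", path, i + 2)
        if fbox is None:
            raise TrajectoryParseError(
                "no box in file; pass box=(Lx, Ly, Lz)", path, i + 2)
        time = float(tokens["time"]) if "time" in tokens else k * dt
        atoms = []
        for j in range(natoms):
            ln = i + 2 + j
            if ln >= nline:
                raise TrajectoryParseError(
                    f"truncated frame: {natoms} atoms declared, file ends", path, nline)
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryParseError("expected 'element x y z'", path, ln + 1)
            try:
                el = normalize_symbol(parts[0])
            except ValueError as exc:
                raise TrajectoryParseError(str(exc), path, ln + 1)
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryParseError("malformed coordinate", path, ln + 1)
            atoms.append(AtomRecord(el, np.array(xyz), "other", 0, j))
        _assign_xyz_topology(atoms, role_map)
        frames.append(Frame(time=time, atoms=atoms, box=np.asarray(fbox, float)))
        i += 2 + natoms
        k += 1
    if not frames:
        raise TrajectoryParseError("no frames found", path, 1)
    return Trajectory(frames=frames)


def _assign_xyz_topology(atoms: list[AtomRecord], role_map: RoleMap) -> None:
    """Assign roles by element and group O,H,H runs into water molecules."""
    mol = 0
    i = 0
    n = len(atoms)
    while i < n:
        a = atoms[i]
        a.role = role_map.assign(a.element)
        if (a.role == "water_O" and i + 2 < n
                and atoms[i + 1].element == "H" and atoms[i + 2].element == "H"):
            for b in (a, atoms[i + 1], atoms[i + 2]):
                b.molecule_id = mol
            atoms[i + 1].role = "water_H"
            atoms[i + 2].role = "water_H"
            mol += 1
            i += 3
            continue
        a.molecule_id = mol
        mol += 1
        i += 1


def _read_mdanalysis(path: Path, role_map: RoleMap, box, dt: float) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - wrap parser diversity
            raise TrajectoryParseError(f"MDAnalysis failed to parse: {exc}", path)
        try:
            elements = [normalize_symbol(e) for e in u.atoms.elements]
        except (mda.exceptions.NoDataError, ValueError):
            from MDAnalysis.topology.guessers import guess_types

            elements = [normalize_symbol(e) for e in guess_types(u.atoms.names)]
        # name-based guessing cannot tell a Ca²⁺ ion from a Cα carbon;
        # single-atom ion residues resolve the ambiguity
        from .roles import ION_RESNAME_TO_ELEMENT

        for i, (rn, name) in enumerate(zip(u.atoms.resnames, u.atoms.names)):
            key = rn.strip().upper()
            if key in ION_RESNAME_TO_ELEMENT and name.strip().upper() == key:
                elements[i] = ION_RESNAME_TO_ELEMENT[key]
        resnames = list(u.atoms.resnames)
        resids = list(u.atoms.resids)
        frames = []
        for k, ts in enumerate(u.trajectory):
            fbox = box
            if fbox is None and ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                    raise ValueError(
                        f"{path}: only orthorhombic boxes are supported "
                        f"(angles {ts.dimensions[3:]})")
                fbox = ts.dimensions[:3]
            if fbox is None:
                raise TrajectoryParseError(
                    "no box in file; pass box=(Lx, Ly, Lz)", path)
            atoms = [
                AtomRecord(
                    element=elements[i],
                    position=ts.positions[i].astype(float).copy(),
                    role=role_map.assign(elements[i], resnames[i]),
                    molecule_id=int(resids[i]),
                    atom_id=i,
                )
                for i in range(len(u.atoms))
            ]
            time = float(ts.time) / 1000.0 if ts.time is not None and ts.time > 0 else k * dt
            frames.append(Frame(time=time, atoms=atoms, box=np.asarray(fbox, float)))
    return Trajectory(frames=frames)


def write_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame XYZ with box=/time= comment tokens."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{len(frame.atoms)}\n")
            bx = ",".join(f"{v:.6f}" for v in frame.box)
            fh.write(f"box={bx} time={frame.time:.9g}\n")
            for a in frame.atoms:
                x, y, z = a.position
                fh.write(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_points_xyz(path) -> np.ndarray:
    """Read an XYZ-style point list (e.g. localized-orbital centers).

    Element symbols are ignored ('X' is common); returns an (n, 3) array in Å.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise TrajectoryParseError("empty file", path, 1)
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise TrajectoryParseError("expected point count", path, 1)
    pts = []
    for j in range(n):
        if 2 + j >= len(lines):
            raise TrajectoryParseError("truncated point list", path, len(lines))
        parts = lines[2 + j].split()
        if len(parts) < 4:
            raise TrajectoryParseError("expected 'label x y z'", path, 3 + j)
        pts.append([float(parts[1]), float(parts[2]), float(parts[3])])
    return np.array(pts)


def write_points_xyz(points: np.ndarray, path, label: str = "X", comment: str = "") -> None:
    points = np.asarray(points, float)
    with open(path, "w") as fh:
        fh.write(f"{len(points)}\n{comment}\n")
        for p in points:
            fh.write(f"{label:<2s} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}\n")
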