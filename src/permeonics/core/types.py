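"""Domain containers: atoms, frames, trajectories and volumetric densities.

All coordinates are stored in Å, times in ns, electron densities in e/Å³.
The pore axis is z by convention, with +z pointing outward (extracellular).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

#: Recognised atom roles.
ROLES = ("ion", "water_O", "water_H", "protein", "other")

Selector = Callable[["AtomRecord"], bool]


@dataclass
class AtomRecord:
    """A single atom in a frame.

    ``molecule_id`` groups atoms into molecules (a water molecule is one
    water_O plus two water_H sharing a molecule_id; a protein residue is one
    molecule_id). ``atom_id`` is unique within a frame and stable across
    frames of a trajectory.
    """

    element: str
    position: np.ndarray
    role: str = "other"
    molecule_id: int = 0
    atom_id: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass
class Frame:
    """One trajectory frame: a time stamp, atoms and an orthorhombic box."""

    time: float
    atoms: list[AtomRecord]
    box: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,):
            raise ValueError("box must be a 3-vector of edge lengths")
        if not np.all(self.box > 0):
            raise ValueError("box edge lengths must be positive")
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite position for atom {a.atom_id}")

    def select(self, selection) -> list[AtomRecord]:
        sel = make_selector(selection)
        return [a for a in self.atoms if sel(a)]

    def positions(self, selection=None) -> np.ndarray:
        atoms = self.atoms if selection is None else self.select(selection)
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])


@dataclass
class Trajectory:
    """An ordered list of frames with consistent atom identities.

    The pore axis convention is fixed: the channel axis is z and +z points
    outward. Readers and generators are expected to orient data accordingly.
    """

    frames: list[Frame]
    axis_convention: str = "pore axis = z, outward = +z"

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def sim_time(self) -> float:
        """Total simulated time span in ns (0 for a single frame)."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].time - self.frames[0].time

    def atom_ids(self, selection=None) -> list[int]:
        if not self.frames:
            return []
        atoms = self.frames[0].atoms if selection is None else self.frames[0].select(selection)
        return [a.atom_id for a in atoms]

    def positions_by_atom(self, selection=None) -> dict[int, np.ndarray]:
        """Per-atom (n_frames, 3) position arrays for the selected atoms.

        Raises if a selected atom is missing from any frame (inconsistent
        atom identities).
        """
        ids = self.atom_ids(selection)
        out = {i: np.empty((self.n_frames, 3)) for i in ids}
        wanted = set(ids)
        for k, frame in enumerate(self.frames):
            seen = set()
            for a in frame.atoms:
                if a.atom_id in wanted:
                    out[a.atom_id][k] = a.position
                    seen.add(a.atom_id)
            if seen != wanted:
                missing = sorted(wanted - seen)
                raise ValueError(f"atoms {missing} missing from frame {k}")
        return out

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])


def make_selector(selection) -> Selector:
    """Normalize a selection spec to a predicate over AtomRecord.

    Accepts a role name ("ion"), an iterable of role names, or a callable.
    """
    if selection is None:
        return lambda a: True
    if callable(selection):
        return selection
    if isinstance(selection, str):
        roles = {selection}
    else:
        roles = set(selection)
    unknown = roles - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles in selection: {sorted(unknown)}")
    return lambda a: a.role in roles


@dataclass
class DensityGrid:
    """Axis-aligned volumetric scalar field with an associated atom list.

    ``values`` holds the field in e/Å³ on a regular grid; ``voxel_vectors``
    are the three grid step vectors (required axis-aligned). Voxel (i, j, k)
    is centred at origin + i·v0 + j·v1 + k·v2 (cube-file convention: the
    origin is the first grid point).
    """

    origin: np.ndarray
    voxel_vectors: np.ndarray
    values: np.ndarray
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_vectors = np.asarray(self.voxel_vectors, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if self.voxel_vectors.shape != (3, 3):
            raise ValueError("voxel_vectors must be a 3x3 matrix")
        off_diag = self.voxel_vectors - np.diag(np.diag(self.voxel_vectors))
        if np.any(np.abs(off_diag) > 1e-10):
            raise ValueError("only axis-aligned (diagonal) voxel vectors are supported")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.diag(self.voxel_vectors).copy()

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.voxel_vectors)))

    def integral(self) -> float:
        """Total integral of the field, values × voxel volume."""
        return float(self.values.sum() * self.voxel_volume)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Grid-point coordinates along each axis."""
        d = self.spacing
        return tuple(
            self.origin[i] + d[i] * np.arange(self.shape[i]) for i in range(3)
        )  # type: ignore[return-value]

    def same_grid_as(self, other: "DensityGrid", tol: float = 1e-6) -> str | None:
        """Return None if grids are congruent, else the differing field name."""
        if self.shape != other.shape:
            return "shape"
        if np.any(np.abs(self.origin - other.origin) > tol):
            return "origin"
        if np.any(np.abs(self.voxel_vectors - other.voxel_vectors) > tol):
            return "voxel_vectors"
        return None
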