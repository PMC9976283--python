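"""Electron-density-difference charge transfer and localized-center analysis.

The charge-transfer pipeline takes three congruent volumetric densities —
the ion-ligand complex, the bare ion, and the ligand shell alone — forms
Δϱ = ϱ_complex − ϱ_ion − ϱ_rest, and integrates Δϱ over the Voronoi cell
of every atom (each voxel assigned to its nearest atom, ties broken by
lowest atom id). The per-atom electron gains/losses aggregate per element
and per molecule; the ion's gain converts its nominal charge to an
effective charge.

Localized-orbital ("Wannier") centers of water are classified as O-H bond
or oxygen lone-pair centers, their field-induced displacements projected
on chemically meaningful axes, and molecular dipoles computed from the
valence point-charge model (O +6, H +1, centers −2 each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEBYE_PER_E_ANGSTROM
from .core.types import AtomRecord, DensityGrid, Frame


# --------------------------------------------------------- Δϱ and Voronoi


def density_difference(complex_grid: DensityGrid, ligand_grid: DensityGrid,
                       rest_grid: DensityGrid, tol: float = 1e-6) -> DensityGrid:
    """Δϱ = ϱ_complex − ϱ_ligand − ϱ_rest on congruent grids.

    The three grids must share origin, voxel vectors and shape to ``tol``
    (no resampling is attempted). The atom list is taken from the complex.
    """
    for name, other in (("ligand", ligand_grid), ("rest", rest_grid)):
        bad = complex_grid.same_grid_as(other, tol)
        if bad is not None:
            raise ValueError(f"{name} grid differs from complex grid in: {bad}")
    values = complex_grid.values - ligand_grid.values - rest_grid.values
    return DensityGrid(origin=complex_grid.origin.copy(),
                       voxel_vectors=complex_grid.voxel_vectors.copy(),
                       values=values, atoms=list(complex_grid.atoms))


def voronoi_integrate(grid: DensityGrid, sites: np.ndarray,
                      chunk: int = 200_000) -> np.ndarray:
    """Integrate the grid field over the Voronoi cell of each site.

    Voxel centers are assigned to the nearest site (Euclidean); exact ties
    go to the lowest site index, making the partition exhaustive and
    exclusive: the per-site integrals sum to the total grid integral.
    """
    sites = np.asarray(sites, float).reshape(-1, 3)
    if len(sites) == 0:
        raise ValueError("empty site list")
    ax, ay, az = grid.axes()
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    vals = grid.values.ravel()
    out = np.zeros(len(sites))
    for lo in range(0, len(pts), chunk):
        hi = min(lo + chunk, len(pts))
        d2 = ((pts[lo:hi, None, :] - sites[None, :, :]) ** 2).sum(axis=-1)
        owner = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
        out += np.bincount(owner, weights=vals[lo:hi], minlength=len(sites))
    return out * grid.voxel_volume


# --------------------------------------------------------- charge transfer


@dataclass
class ChargeTransferTable:
    """Per-atom/element/molecule electron redistribution from Δϱ."""

    per_atom: dict[int, float]                  # atom_id -> Δn_e (gain > 0)
    per_element: dict[str, float]
    per_molecule: dict[int, float]
    effective_ion_charge: float                 # e
    nominal_charge: float
    ion_atom_id: int
    element_stats: pd.DataFrame | None = None   # multi-snapshot mean ± sd
    per_water_mean_loss: float | None = None    # mean electrons lost per water

    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def _single_snapshot_table(delta: DensityGrid, ion_id: int,
                           nominal_charge: float) -> ChargeTransferTable:
    atoms = delta.atoms
    ids = [a.atom_id for a in atoms]
    if ion_id not in ids:
        raise ValueError(f"ion atom_id {ion_id} not present in grid atoms")
    sites = np.array([a.position for a in atoms])
    integrals = voronoi_integrate(delta, sites)
    per_atom = {a.atom_id: float(v) for a, v in zip(atoms, integrals)}
    per_element: dict[str, float] = {}
    per_molecule: dict[int, float] = {}
    for a, v in zip(atoms, integrals):
        per_element[a.element] = per_element.get(a.element, 0.0) + float(v)
        per_molecule[a.molecule_id] = per_molecule.get(a.molecule_id, 0.0) + float(v)
    eff = nominal_charge - per_atom[ion_id]
    ion_mol = next(a.molecule_id for a in atoms if a.atom_id == ion_id)
    water_mols = sorted(set(a.molecule_id for a in atoms
                            if a.role in ("water_O", "water_H")) - {ion_mol})
    loss = None
    if water_mols:
        loss = float(np.mean([-per_molecule[m] for m in water_mols]))
    return ChargeTransferTable(per_atom=per_atom, per_element=per_element,
                               per_molecule=per_molecule,
                               effective_ion_charge=float(eff),
                               nominal_charge=nominal_charge, ion_atom_id=ion_id,
                               per_water_mean_loss=loss)


def charge_transfer(delta: DensityGrid, ion_id: int, nominal_charge: float = 2.0,
                    snapshots: list[DensityGrid] | None = None) -> ChargeTransferTable:
    """Voronoi charge-transfer table from Δϱ.

    With ``snapshots`` (additional Δϱ grids of the same system), per-element
    values are averaged and reported with their standard deviation in
    ``element_stats``; scalar fields then hold snapshot means.
    """
    tables = [_single_snapshot_table(delta, ion_id, nominal_charge)]
    for g in snapshots or []:
        tables.append(_single_snapshot_table(g, ion_id, nominal_charge))
    if len(tables) == 1:
        t = tables[0]
        t.element_stats = pd.DataFrame(
            {"mean": pd.Series(t.per_element), "sd": np.nan})
        return t
    elements = sorted({e for t in tables for e in t.per_element})
    data = np.array([[t.per_element.get(e, 0.0) for e in elements] for t in tables])
    stats = pd.DataFrame({"mean": data.mean(axis=0), "sd": data.std(axis=0, ddof=1)},
                         index=elements)
    base = tables[0]
    base.element_stats = stats
    base.effective_ion_charge = float(np.mean([t.effective_ion_charge for t in tables]))
    base.per_water_mean_loss = float(np.mean([t.per_water_mean_loss for t in tables
                                              if t.per_water_mean_loss is not None]))
    return base


# --------------------------------------------------------- Wannier centers


@dataclass
class WannierCenter:
    position: np.ndarray
    molecule_id: int
    kind: str                   # lone_pair | OH_bond | unassigned
    charge: float = -2.0
    bonded_h: int | None = None  # atom_id of the H for OH_bond centers


@dataclass
class WannierCenterSet:
    centers: list[WannierCenter]
    frame: Frame

    def by_molecule(self, molecule_id: int) -> list[WannierCenter]:
        return [c for c in self.centers if c.molecule_id == molecule_id]

    def kinds(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.centers:
            out[c.kind] = out.get(c.kind, 0) + 1
        return out


def assign_and_classify_centers(centers: np.ndarray, frame: Frame, *,
                                assign_radius: float = 1.2,
                                bond_cone_deg: float = 35.0) -> WannierCenterSet:
    """Attach localized-orbital centers to water molecules and classify them.

    A center belongs to the molecule of its nearest oxygen (within
    ``assign_radius`` Å; farther centers become 'unassigned' with a
    warning). It is an O-H bond center when the angle between O→center and
    O→H is below ``bond_cone_deg`` for either hydrogen, else a lone pair.
    """
    import warnings

    centers = np.asarray(centers, float).reshape(-1, 3)
    oxygens = [a for a in frame.atoms if a.element == "O"]
    if not oxygens:
        raise ValueError("frame contains no oxygen atoms")
    opos = np.array([a.position for a in oxygens])
    hydro = {a.molecule_id: [] for a in oxygens}
    for a in frame.atoms:
        if a.element == "H" and a.molecule_id in hydro:
            hydro[a.molecule_id].append(a)
    out = []
    cos_cone = np.cos(np.deg2rad(bond_cone_deg))
    for c in centers:
        d = np.linalg.norm(opos - c, axis=1)
        j = int(np.argmin(d))
        if d[j] > assign_radius:
            warnings.warn(f"center {c.round(3)} is {d[j]:.2f} Å from the nearest "
                          "oxygen; left unassigned", stacklevel=2)
            out.append(WannierCenter(c, molecule_id=-1, kind="unassigned"))
            continue
        o = oxygens[j]
        v = c - o.position
        nv = np.linalg.norm(v)
        kind = "lone_pair"
        bonded = None
        for h in hydro[o.molecule_id]:
            u = h.position - o.position
            cosang = float(v @ u / (nv * np.linalg.norm(u))) if nv > 1e-12 else 0.0
            if cosang > cos_cone:
                kind = "OH_bond"
                bonded = h.atom_id
                break
        out.append(WannierCenter(c, molecule_id=o.molecule_id, kind=kind,
                                 bonded_h=bonded))
    return WannierCenterSet(centers=out, frame=frame)


def center_shift(set_a: WannierCenterSet, set_b: WannierCenterSet,
                 direction_ref: np.ndarray) -> dict[str, float]:
    """Mean projected displacement of matched centers between two sets.

    ``set_a`` is the perturbed state (e.g. ion present), ``set_b`` the
    reference at identical water geometry. Lone-pair displacements are
    projected on the O→ion unit vector (positive toward the ion at
    ``direction_ref``); bond-center displacements on the H→O unit vector
    (positive toward the oxygen). Bond centers are matched through their
    hydrogen; lone pairs by closest-distance pairing within the molecule.
    """
    direction_ref = np.asarray(direction_ref, float)
    o_by_mol = {a.molecule_id: a for a in set_a.frame.atoms if a.element == "O"}
    h_by_id = {a.atom_id: a for a in set_a.frame.atoms if a.element == "H"}
    lp_shifts, bond_shifts = [], []
    mols = sorted(o_by_mol)
    for m in mols:
        ca = set_a.by_molecule(m)
        cb = set_b.by_molecule(m)
        if not ca and not cb:
            continue
        if len(ca) != len(cb):
            raise ValueError(f"unmatched centers for molecule {m}: "
                             f"{len(ca)} vs {len(cb)}")
        o = o_by_mol[m]
        # bonds matched via their hydrogen
        bonds_a = {c.bonded_h: c for c in ca if c.kind == "OH_bond"}
        bonds_b = {c.bonded_h: c for c in cb if c.kind == "OH_bond"}
        if set(bonds_a) != set(bonds_b):
            raise ValueError(f"bond centers of molecule {m} do not match")
        for hid, c1 in bonds_a.items():
            c2 = bonds_b[hid]
            h = h_by_id[hid]
            u = o.position - h.position
            u = u / np.linalg.norm(u)
            bond_shifts.append(float((c1.position - c2.position) @ u))
        lp_a = [c for c in ca if c.kind == "lone_pair"]
        lp_b = [c for c in cb if c.kind == "lone_pair"]
        if len(lp_a) != len(lp_b):
            raise ValueError(f"lone-pair centers of molecule {m} do not match")
        u_ion = direction_ref - o.position
        u_ion = u_ion / np.linalg.norm(u_ion)
        # nearest-pairing of lone pairs (2 per water: trivial assignment)
        used = set()
        for c1 in lp_a:
            dists = [(np.linalg.norm(c1.position - c2.position), k)
                     for k, c2 in enumerate(lp_b) if k not in used]
            _, k = min(dists)
            used.add(k)
            lp_shifts.append(float((c1.position - lp_b[k].position) @ u_ion))
    return {
        "lone_pair": float(np.mean(lp_shifts)) if lp_shifts else float("nan"),
        "OH_bond": float(np.mean(bond_shifts)) if bond_shifts else float("nan"),
        "lone_pair_sd": float(np.std(lp_shifts, ddof=1)) if len(lp_shifts) > 1 else float("nan"),
        "OH_bond_sd": float(np.std(bond_shifts, ddof=1)) if len(bond_shifts) > 1 else float("nan"),
    }


@dataclass
class DipoleResult:
    molecule_id: int
    dipole_vector: np.ndarray   # e·Å
    magnitude: float            # Debye


#: Valence nuclear charges in the pseudopotential convention.
VALENCE_CHARGE = {"O": 6.0, "H": 1.0}


def molecular_dipole(center_set: WannierCenterSet, molecule_id: int) -> DipoleResult:
    """Water dipole from valence nuclei (O +6, H +1) and 4 centers of −2e.

    The molecule is net neutral (6 + 1 + 1 − 4·2 = 0), so the dipole is
    origin-independent.
    """
    frame = center_set.frame
    atoms = [a for a in frame.atoms if a.molecule_id == molecule_id
             and a.element in VALENCE_CHARGE]
    elements = sorted(a.element for a in atoms)
    if elements != ["H", "H", "O"]:
        raise ValueError(f"molecule {molecule_id} is not a water (atoms {elements})")
    centers = center_set.by_molecule(molecule_id)
    if len(centers) != 4:
        raise ValueError(f"molecule {molecule_id} has {len(centers)} centers, expected 4")
    mu = np.zeros(3)
    for a in atoms:
        mu += VALENCE_CHARGE[a.element] * a.position
    for c in centers:
        mu += c.charge * c.position
    return DipoleResult(molecule_id=molecule_id, dipole_vector=mu,
                        magnitude=float(np.linalg.norm(mu)) * DEBYE_PER_E_ANGSTROM)
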