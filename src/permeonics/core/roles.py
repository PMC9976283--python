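"""Rule-based assignment of atom roles and molecule grouping.

Roles are assigned from element symbols plus (when available) residue
names. The defaults follow common force-field conventions: water residues
{SOL, HOH, TIP3, WAT, TIP4, SPC}, ion residues {CA, CAL, NA, SOD, K, POT,
CL, CLA, MG, RB, CS, BA}. Everything belonging to a standard amino-acid
residue is tagged protein; the rest is "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import ION_ELEMENTS, normalize_symbol
from .types import AtomRecord

WATER_RESNAMES = {"SOL", "HOH", "TIP3", "WAT", "TIP4", "SPC", "T3P"}
ION_RESNAMES = {"CA", "CAL", "CA2", "NA", "SOD", "K", "POT", "CL", "CLA",
                "MG", "RB", "CS", "BA", "LI"}
#: Residue-name -> element for monoatomic ions (resolves the "CA" ambiguity:
#: a CA *residue* is calcium, while a CA *atom name* in a protein is Cα).
ION_RESNAME_TO_ELEMENT = {
    "CA": "Ca", "CAL": "Ca", "CA2": "Ca", "NA": "Na", "SOD": "Na",
    "K": "K", "POT": "K", "CL": "Cl", "CLA": "Cl", "MG": "Mg",
    "RB": "Rb", "CS": "Cs", "BA": "Ba", "LI": "Li",
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}


@dataclass
class RoleMap:
    """Configurable element/residue-name rules for role assignment."""

    water_resnames: set[str] = field(default_factory=lambda: set(WATER_RESNAMES))
    ion_resnames: set[str] = field(default_factory=lambda: set(ION_RESNAMES))
    ion_elements: set[str] = field(default_factory=lambda: set(ION_ELEMENTS))
    protein_resnames: set[str] = field(default_factory=lambda: set(AMINO_ACIDS))

    def assign(self, element: str, resname: str | None = None) -> str:
        element = normalize_symbol(element)
        if resname is not None:
            rn = resname.strip().upper()
            if rn in self.water_resnames:
                return "water_O" if element == "O" else "water_H" if element == "H" else "other"
            if rn in self.ion_resnames and element in self.ion_elements:
                return "ion"
            if rn in self.protein_resnames:
                return "protein"
        # element-only fallback (XYZ files carry no residue information)
        if element in self.ion_elements:
            return "ion"
        if element == "O":
            return "water_O"
        if element == "H":
            return "water_H"
        return "other"


def infer_water_topology(atoms: list[AtomRecord], oh_cutoff: float = 1.25) -> None:
    """Assign roles and molecule_ids geometrically, in place.

    Intended for atom lists without residue information (XYZ files, cube
    atom blocks): each H is attached to its nearest O within ``oh_cutoff``
    Å; every O founds a molecule; ion elements become single-atom
    molecules. Hydrogens without a nearby O keep role other.
    """
    pos = np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3))
    oxygens = [i for i, a in enumerate(atoms) if a.element == "O"]
    mol = 0
    for i, a in enumerate(atoms):
        if a.element in ION_ELEMENTS:
            a.role = "ion"
            a.molecule_id = mol
            mol += 1
    o_mol: dict[int, int] = {}
    for i in oxygens:
        atoms[i].role = "water_O"
        atoms[i].molecule_id = mol
        o_mol[i] = mol
        mol += 1
    for i, a in enumerate(atoms):
        if a.element != "H":
            continue
        if not oxygens:
            a.role = "other"
            continue
        d = np.linalg.norm(pos[oxygens] - pos[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= oh_cutoff:
            a.role = "water_H"
            a.molecule_id = o_mol[oxygens[j]]
        else:
            a.role = "other"
            a.molecule_id = mol
            mol += 1
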