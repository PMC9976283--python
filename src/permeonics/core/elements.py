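"""Minimal element table: symbols, atomic numbers, and role heuristics."""

from __future__ import annotations

SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Mn": 25, "Fe": 26,
    "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35, "Rb": 37, "Sr": 38,
    "I": 53, "Cs": 55, "Ba": 56,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: Elements treated as permeant/bound ions by default.
ION_ELEMENTS = {"Ca", "Na", "K", "Mg", "Cl", "Rb", "Cs", "Ba", "Sr", "Li"}


def normalize_symbol(sym: str) -> str:
    """Normalize an element symbol ('CA' -> 'Ca', 'o' -> 'O')."""
    s = sym.strip()
    if not s:
        raise ValueError("empty element symbol")
    s = s[0].upper() + s[1:].lower()
    if s not in SYMBOL_TO_Z:
        raise ValueError(f"unknown element symbol {sym!r}")
    return s
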