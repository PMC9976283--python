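"""Gaussian basis sets: shells, normalization, packing for the integral kernels.

Basis functions are contracted Cartesian Gaussians
x^i y^j z^k exp(-a r²) with components in canonical order (for l=2:
xx, xy, xz, yy, yz, zz). All exponents are in Bohr⁻² and centers in Bohr;
the quantum-chemistry layer works in atomic units throughout and converts
at its boundary.

The package ships its own atom-optimized double-zeta-plus-polarization
set (see scripts/build_basis.py) as JSON data; any basis in the same JSON
layout can be loaded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import pi, sqrt

import numpy as np


def double_factorial(n: int) -> int:
    """(2k-1)!! style double factorial; (-1)!! = 1 by convention."""
    if n <= 0:
        return 1
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Canonical Cartesian component exponents for angular momentum l."""
    return [(lx, ly, l - lx - ly) for lx in range(l, -1, -1) for ly in range(l - lx, -1, -1)]


N_CART = {l: (l + 1) * (l + 2) // 2 for l in range(7)}


def primitive_norm(l: int, a: float) -> float:
    """Norm of the (l,0,0) Cartesian primitive with exponent a."""
    return (2 * a / pi) ** 0.75 * (4 * a) ** (l / 2) / sqrt(double_factorial(2 * l - 1))


def component_scale(lx: int, ly: int, lz: int) -> float:
    """Relative normalization of a Cartesian component vs (l,0,0)."""
    l = lx + ly + lz
    return sqrt(
        double_factorial(2 * l - 1)
        / (double_factorial(2 * lx - 1) * double_factorial(2 * ly - 1) * double_factorial(2 * lz - 1))
    )


@dataclass
class Shell:
    """One contracted shell on a center."""

    l: int
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients (raw, un-normalized)
    center: np.ndarray  # Bohr

    def __post_init__(self) -> None:
        self.exps = np.asarray(self.exps, float)
        self.coefs = np.asarray(self.coefs, float)
        self.center = np.asarray(self.center, float)
        if self.exps.shape != self.coefs.shape:
            raise ValueError("exponent/coefficient length mismatch")

    @property
    def nbf(self) -> int:
        return N_CART[self.l]

    def normalized_coefs(self) -> np.ndarray:
        """Coefficients × primitive norms, rescaled to unit self-overlap of (l,0,0)."""
        c = self.coefs * np.array([primitive_norm(self.l, a) for a in self.exps])
        # self-overlap of the contracted (l,0,0) function; s is the overlap
        # of *normalized* primitives, so it contracts with the raw coefficients
        a = self.exps[:, None]
        b = self.exps[None, :]
        s = (2 * np.sqrt(a * b) / (a + b)) ** (self.l + 1.5)
        norm = float(self.coefs @ s @ self.coefs)
        return c / sqrt(norm)


@dataclass
class BasisSet:
    """Element → list of shell templates (centers unset)."""

    name: str
    elements: dict[str, list[dict]]
    provenance: str = ""

    @classmethod
    def from_json(cls, path_or_dict) -> "BasisSet":
        if isinstance(path_or_dict, dict):
            d = path_or_dict
        else:
            with open(path_or_dict) as fh:
                d = json.load(fh)
        return cls(name=d.get("name", "unnamed"), elements=d["elements"],
                   provenance=d.get("provenance", ""))

    @classmethod
    def builtin(cls, name: str = "pdzp") -> "BasisSet":
        """Load a basis shipped as package data."""
        ref = resources.files("permeonics.qm").joinpath(f"data/{name}.json")
        with ref.open() as fh:
            return cls.from_json(json.load(fh))

    def shells_for(self, element: str, center_bohr) -> list[Shell]:
        if element not in self.elements:
            raise KeyError(f"element {element} not in basis {self.name}")
        return [
            Shell(l=sh["l"], exps=np.array(sh["exp"]), coefs=np.array(sh["coef"]),
                  center=np.asarray(center_bohr, float))
            for sh in self.elements[element]
        ]

    def to_json_dict(self) -> dict:
        return {"name": self.name, "provenance": self.provenance, "elements": self.elements}


@dataclass
class PackedBasis:
    """Flat-array view of a molecular basis for the numba kernels."""

    shell_l: np.ndarray          # (nshell,) int32
    shell_nprim: np.ndarray      # (nshell,) int32
    shell_pstart: np.ndarray     # (nshell,) int32 index into prim arrays
    shell_center: np.ndarray     # (nshell, 3) float64, Bohr
    shell_ao_start: np.ndarray   # (nshell,) int32 first AO index
    prim_exp: np.ndarray         # (nprim_total,)
    prim_coef: np.ndarray        # (nprim_total,) normalized coefficients
    comp_scale: np.ndarray       # (nbf,) per-AO component scale
    nbf: int
    shells: list[Shell] = field(default_factory=list)

    @property
    def nshell(self) -> int:
        return len(self.shell_l)


def pack_shells(shells: list[Shell]) -> PackedBasis:
    ls, nprims, pstarts, centers, ao_starts = [], [], [], [], []
    exps, coefs, scales = [], [], []
    ao = 0
    p = 0
    for sh in shells:
        ls.append(sh.l)
        nprims.append(len(sh.exps))
        pstarts.append(p)
        centers.append(sh.center)
        ao_starts.append(ao)
        exps.extend(sh.exps.tolist())
        coefs.extend(sh.normalized_coefs().tolist())
        for lx, ly, lz in cartesian_components(sh.l):
            scales.append(component_scale(lx, ly, lz))
        p += len(sh.exps)
        ao += sh.nbf
    return PackedBasis(
        shell_l=np.array(ls, np.int32),
        shell_nprim=np.array(nprims, np.int32),
        shell_pstart=np.array(pstarts, np.int32),
        shell_center=np.array(centers, float).reshape(-1, 3),
        shell_ao_start=np.array(ao_starts, np.int32),
        prim_exp=np.array(exps, float),
        prim_coef=np.array(coefs, float),
        comp_scale=np.array(scales, float),
        nbf=ao,
        shells=list(shells),
    )


# component exponent tables packed for numba: comp_lx[l][k] etc.
_MAXL = 4
COMP_LX = np.zeros((_MAXL + 1, N_CART[_MAXL]), np.int32)
COMP_LY = np.zeros_like(COMP_LX)
COMP_LZ = np.zeros_like(COMP_LX)
for _l in range(_MAXL + 1):
    for _k, (_lx, _ly, _lz) in enumerate(cartesian_components(_l)):
        COMP_LX[_l, _k] = _lx
        COMP_LY[_l, _k] = _ly
        COMP_LZ[_l, _k] = _lz
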