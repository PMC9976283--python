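"""Electron density of an SCF state on volumetric grids.

Evaluates contracted Cartesian Gaussian basis functions on arbitrary
points and accumulates ρ = Σ_i n_i |ψ_i|², returning a DensityGrid in the
package units (Å, e/Å³) ready for the charge-transfer analysis or cube
export.
"""

from __future__ import annotations

import numpy as np

from ..constants import BOHR_TO_ANGSTROM
from ..core.roles import infer_water_topology
from ..core.types import AtomRecord, DensityGrid
from .basis import PackedBasis, cartesian_components, component_scale
from .scf import SCFResult


def ao_values(basis: PackedBasis, points_bohr: np.ndarray) -> np.ndarray:
    """Basis-function values at points (npts, 3) in Bohr -> (npts, nbf)."""
    pts = np.asarray(points_bohr, float).reshape(-1, 3)
    out = np.empty((len(pts), basis.nbf))
    ao = 0
    for sh in basis.shells:
        d = pts - sh.center
        r2 = np.einsum("ij,ij->i", d, d)
        coefs = sh.normalized_coefs()
        radial = np.zeros(len(pts))
        for a, c in zip(sh.exps, coefs):
            radial += c * np.exp(-a * r2)
        for lx, ly, lz in cartesian_components(sh.l):
            mono = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz if sh.l else 1.0
            out[:, ao] = mono * radial * component_scale(lx, ly, lz)
            ao += 1
    return out


def density_values(res: SCFResult, points_ang: np.ndarray,
                   chunk: int = 50000) -> np.ndarray:
    """Electron density in e/Å³ at points given in Å."""
    pts = np.asarray(points_ang, float).reshape(-1, 3) / BOHR_TO_ANGSTROM
    occ_idx = np.where(res.occupations > 1e-8)[0]
    Cocc = res.mo_coeff[:, occ_idx]
    nocc_w = res.occupations[occ_idx]
    rho = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        hi = min(lo + chunk, len(pts))
        phi = ao_values(res.basis, pts[lo:hi])
        psi = phi @ Cocc
        rho[lo:hi] = (psi * psi) @ nocc_w
    return rho / BOHR_TO_ANGSTROM**3


def density_grid(res: SCFResult, origin: np.ndarray, spacing: float,
                 shape: tuple[int, int, int], role_inference: bool = True) -> DensityGrid:
    """Sample the SCF electron density on a regular grid (Å, e/Å³)."""
    origin = np.asarray(origin, float)
    nx, ny, nz = shape
    ax = origin[0] + spacing * np.arange(nx)
    ay = origin[1] + spacing * np.arange(ny)
    az = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    rho = density_values(res, pts).reshape(shape)
    atoms = [AtomRecord(s, p, "other", i, i)
             for i, (s, p) in enumerate(zip(res.mol.symbols, res.mol.coords))]
    if role_inference:
        infer_water_topology(atoms)
    return DensityGrid(origin=origin, voxel_vectors=np.eye(3) * spacing,
                       values=rho, atoms=atoms)
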