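"""Restricted Hartree-Fock with DIIS, plus spherically averaged atomic SCF.

This is a deliberately small self-consistent-field engine: closed-shell
RHF in a Cartesian Gaussian basis, core-Hamiltonian guess, Pulay DIIS on
the orthonormalized error matrix F·D·S - S·D·F, optional level shift and
density damping for difficult starts. Atomic ground states with open
shells are handled by fractional (spherically averaged) occupations,
which is what the basis-construction pipeline needs.

Atomic units internally; the molecular geometry interface is in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import BOHR_TO_ANGSTROM
from ..core.elements import SYMBOL_TO_Z
from .basis import BasisSet, PackedBasis, Shell, pack_shells
from .integrals import coulomb_exchange, eri_supermatrix, one_electron_matrices


@dataclass
class Molecule:
    """Nuclei for the quantum-chemistry layer. Coordinates in Å."""

    symbols: list[str]
    coords: np.ndarray  # (n, 3) Å
    charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbol/coordinate count mismatch")

    @property
    def Zs(self) -> np.ndarray:
        return np.array([SYMBOL_TO_Z[s] for s in self.symbols], float)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords / BOHR_TO_ANGSTROM

    @property
    def n_electrons(self) -> int:
        return int(self.Zs.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        e = 0.0
        xyz = self.coords_bohr
        Z = self.Zs
        for i in range(len(Z)):
            for j in range(i):
                e += Z[i] * Z[j] / np.linalg.norm(xyz[i] - xyz[j])
        return e


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFResult:
    mol: Molecule
    basis: PackedBasis
    energy: float
    mo_coeff: np.ndarray      # (nbf, nmo)
    mo_energy: np.ndarray
    occupations: np.ndarray   # per-MO occupation numbers
    converged: bool
    n_iter: int
    S: np.ndarray = field(repr=False, default=None)
    dipole_ints: np.ndarray = field(repr=False, default=None)

    @property
    def density(self) -> np.ndarray:
        C = self.mo_coeff
        return (C * self.occupations) @ C.T

    @property
    def n_occ(self) -> int:
        return int(np.sum(self.occupations > 1e-8))

    def dipole_moment(self) -> np.ndarray:
        """Total dipole (nuclear + electronic) in e·Å, about the origin."""
        P = self.density
        mu_e = -np.einsum("dij,ij->d", self.dipole_ints, P)
        mu_n = (self.mol.Zs[:, None] * self.mol.coords_bohr).sum(axis=0)
        return (mu_e + mu_n) * BOHR_TO_ANGSTROM


def build_packed_basis(mol: Molecule, basis: BasisSet | str = "pdzp") -> PackedBasis:
    if isinstance(basis, str):
        basis = BasisSet.builtin(basis)
    shells: list[Shell] = []
    for sym, xyz in zip(mol.symbols, mol.coords_bohr):
        shells.extend(basis.shells_for(sym, xyz))
    return pack_shells(shells)


def _occupations(mo_energy: np.ndarray, n_electrons: int, degeneracy_tol: float = 1e-6):
    """Aufbau occupations; electrons in a partially filled degenerate set
    are spread equally (spherical averaging for atoms)."""
    n = len(mo_energy)
    occ = np.zeros(n)
    remaining = float(n_electrons)
    i = 0
    while remaining > 1e-12 and i < n:
        j = i
        while j + 1 < n and abs(mo_energy[j + 1] - mo_energy[i]) < degeneracy_tol:
            j += 1
        nset = j - i + 1
        put = min(remaining, 2.0 * nset)
        occ[i:j + 1] = put / nset
        remaining -= put
        i = j + 1
    if remaining > 1e-12:
        raise ValueError("more electrons than spin orbitals")
    return occ


def rhf(mol: Molecule, basis: BasisSet | str = "pdzp", *,
        max_iter: int = 120, conv_tol: float = 1e-8, diis_size: int = 8,
        level_shift: float = 0.0, damping: float = 0.0,
        fractional: bool = False, eri_screen: float = 1e-12,
        verbose: bool = False) -> SCFResult:
    """Converge a closed-shell (or spherically averaged) SCF.

    ``fractional`` enables spherically averaged fractional occupations for
    open-shell atoms; otherwise the electron count must be even.
    """
    pb = build_packed_basis(mol, basis)
    nelec = mol.n_electrons
    if not fractional and nelec % 2:
        raise ValueError("odd electron count requires fractional=True")
    S, T, V, M = one_electron_matrices(pb, mol.Zs, mol.coords_bohr)
    H = T + V
    G2 = eri_supermatrix(pb, eri_screen)
    Enuc = mol.nuclear_repulsion()

    # symmetric orthogonalization with near-linear-dependence removal
    sval, svec = np.linalg.eigh(S)
    keep = sval > 1e-9
    X = svec[:, keep] / np.sqrt(sval[keep])

    # core guess
    Fp = X.T @ H @ X
    eps, Cp = np.linalg.eigh(Fp)
    C = X @ Cp
    occ = _occupations(eps, nelec) if fractional else _fixed_occ(len(eps), nelec)
    P = (C * occ) @ C.T

    diis_F: list[np.ndarray] = []
    diis_E: list[np.ndarray] = []
    energy = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J, K = coulomb_exchange(G2, P)
        F = H + J - 0.5 * K
        energy_new = 0.5 * np.sum(P * (H + F)) + Enuc
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        err_norm = np.max(np.abs(err))
        if verbose:
            print(f"iter {it:3d}  E = {energy_new:.10f}  |FPS-SPF| = {err_norm:.2e}")
        if err_norm < conv_tol and it > 1:
            energy = energy_new
            converged = True
            break
        energy = energy_new

        diis_F.append(F.copy())
        diis_E.append(err.copy())
        if len(diis_F) > diis_size:
            diis_F.pop(0)
            diis_E.pop(0)
        if len(diis_F) >= 2:
            F = _diis_extrapolate(diis_F, diis_E)

        Fp = X.T @ F @ X
        if level_shift > 0.0:
            # shift virtual levels up: F' += s(1 - P'/2), P'/2 = occupied projector
            Pp = X.T @ S @ P @ S @ X
            Fp = Fp + level_shift * (np.eye(Fp.shape[0]) - 0.5 * Pp)
        eps, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        occ = _occupations(eps, nelec) if fractional else _fixed_occ(len(eps), nelec)
        P_new = (C * occ) @ C.T
        if damping > 0.0:
            P = damping * P + (1.0 - damping) * P_new
        else:
            P = P_new

    if not converged:
        raise SCFConvergenceError(
            f"SCF not converged in {max_iter} iterations (residual {err_norm:.2e})")
    return SCFResult(mol=mol, basis=pb, energy=float(energy), mo_coeff=C,
                     mo_energy=eps, occupations=occ, converged=converged,
                     n_iter=it, S=S, dipole_ints=M)


def _fixed_occ(nmo: int, nelec: int) -> np.ndarray:
    occ = np.zeros(nmo)
    occ[: nelec // 2] = 2.0
    return occ


def _diis_extrapolate(Fs: list[np.ndarray], Es: list[np.ndarray]) -> np.ndarray:
    m = len(Fs)
    B = -np.ones((m + 1, m + 1))
    B[m, m] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = np.sum(Es[i] * Es[j])
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        w = np.linalg.solve(B, rhs)
    except np.linalg.LinAlgError:
        return Fs[-1]
    F = np.zeros_like(Fs[0])
    for i in range(m):
        F += w[i] * Fs[i]
    return F
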