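"""Validation of the Hartree-Fock backend against independent oracles.

The s-type integrals and the full SCF are anchored to the classic
published H2 minimal-basis values; p- and d-type integrals are checked by
numerical quadrature with analytic orbital gradients; electron repulsion
is cross-validated against nuclear attraction through the point-charge
limit; invariance under rigid rotation exercises every angular-momentum
code path at once.
"""

import numpy as np
import pytest

from permeonics.constants import BOHR_TO_ANGSTROM as BOHR
from permeonics.qm import Molecule, rhf
from permeonics.qm.basis import (
    Shell,
    cartesian_components,
    component_scale,
    pack_shells,
)
from permeonics.qm.density import density_grid, density_values
from permeonics.qm.integrals import boys, eri_supermatrix, one_electron_matrices
from permeonics.qm.localize import localized_centers


def pair(p, q):
    a, b = max(p, q), min(p, q)
    return a * (a + 1) // 2 + b


class TestBoysFunction:
    def test_against_incomplete_gamma(self):
        from scipy.special import gammainc, gamma

        for T in (1e-14, 0.01, 0.5, 3.0, 20.0, 34.9, 35.1, 80.0):
            F = np.zeros(9)
            boys(8, T, F)
            for m in range(9):
                if T < 1e-12:
                    ref = 1.0 / (2 * m + 1)
                else:
                    ref = 0.5 * gamma(m + 0.5) * gammainc(m + 0.5, T) / T**(m + 0.5)
                assert F[m] == pytest.approx(ref, rel=1e-12, abs=1e-15)


class TestTextbookH2:
    """Minimal-basis H2 at R = 1.4 a0: the standard worked example."""

    def test_integrals_match_published_table(self, sto3g_h):
        mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4 * BOHR]])
        from permeonics.qm.scf import build_packed_basis

        pb = build_packed_basis(mol, sto3g_h)
        S, T, V, _ = one_electron_matrices(pb, mol.Zs, mol.coords_bohr)
        G = eri_supermatrix(pb)
        assert S[0, 1] == pytest.approx(0.6593, abs=5e-5)
        assert T[0, 0] == pytest.approx(0.7600, abs=5e-5)
        assert T[0, 1] == pytest.approx(0.2365, abs=5e-5)
        assert G[pair(0, 0), pair(0, 0)] == pytest.approx(0.7746, abs=5e-5)
        assert G[pair(0, 0), pair(1, 1)] == pytest.approx(0.5697, abs=5e-5)
        assert G[pair(0, 0), pair(0, 1)] == pytest.approx(0.4441, abs=5e-5)
        assert G[pair(0, 1), pair(0, 1)] == pytest.approx(0.2970, abs=5e-5)

    def test_total_energy(self, sto3g_h):
        mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4 * BOHR]])
        res = rhf(mol, sto3g_h)
        assert res.energy == pytest.approx(-1.1167, abs=1e-4)


def _quadrature_aos(shells, X, Y, Z):
    """Reference AO values evaluated independently of the integral code."""
    aos, grads = [], []
    for sh in shells:
        c = sh.normalized_coefs()
        dx, dy, dz = X - sh.center[0], Y - sh.center[1], Z - sh.center[2]
        r2 = dx**2 + dy**2 + dz**2
        rad = sum(ci * np.exp(-ai * r2) for ci, ai in zip(c, sh.exps))
        drad = sum(-2 * ai * ci * np.exp(-ai * r2) for ci, ai in zip(c, sh.exps))
        for lx, ly, lz in cartesian_components(sh.l):
            cs = component_scale(lx, ly, lz)
            mono = dx**lx * dy**ly * dz**lz
            aos.append(mono * rad * cs)
            gx = ((lx * dx**(lx - 1) if lx else 0) * dy**ly * dz**lz * rad
                  + mono * drad * dx) * cs
            gy = (dx**lx * (ly * dy**(ly - 1) if ly else 0) * dz**lz * rad
                  + mono * drad * dy) * cs
            gz = (dx**lx * dy**ly * (lz * dz**(lz - 1) if lz else 0) * rad
                  + mono * drad * dz) * cs
            grads.append((gx, gy, gz))
    return aos, grads


@pytest.fixture(scope="module")
def quad_setup():
        rng = np.random.default_rng(3)
        shells = [
            Shell(l=2, exps=[1.3, 0.4], coefs=[0.6, 0.5], center=rng.normal(size=3) * 0.7),
            Shell(l=1, exps=[0.9, 0.25], coefs=[0.4, 0.7], center=rng.normal(size=3) * 0.7),
        ]
        pb = pack_shells(shells)
        Zs = np.array([1.7])
        Zc = np.array([[0.3, -0.2, 0.5]])
        S, T, V, M = one_electron_matrices(pb, Zs, Zc)
        n = 120
        L = 11.0
        x = (np.arange(n) + 0.5) / n * 2 * L - L
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        dV = (2 * L / n) ** 3
        aos, grads = _quadrature_aos(shells, X, Y, Z)
        return dict(S=S, T=T, V=V, M=M, Zs=Zs, Zc=Zc, X=X, Y=Y, Z=Z, dV=dV,
                    aos=aos, grads=grads, pb=pb)


class TestQuadratureOracles:
    """One-electron integrals over p and d shells vs numerical integration."""

    def test_overlap(self, quad_setup):
        aos, dV = quad_setup["aos"], quad_setup["dV"]
        num = np.array([[np.sum(a * b) * dV for b in aos] for a in aos])
        assert np.abs(quad_setup["S"] - num).max() < 1e-10

    def test_dipole(self, quad_setup):
        aos, dV = quad_setup["aos"], quad_setup["dV"]
        for d, C in enumerate((quad_setup["X"], quad_setup["Y"], quad_setup["Z"])):
            num = np.array([[np.sum(a * C * b) * dV for b in aos] for a in aos])
            assert np.abs(quad_setup["M"][d] - num).max() < 1e-9

    def test_nuclear_attraction(self, quad_setup):
        aos, dV = quad_setup["aos"], quad_setup["dV"]
        r = np.sqrt((quad_setup["X"] - quad_setup["Zc"][0, 0])**2
                    + (quad_setup["Y"] - quad_setup["Zc"][0, 1])**2
                    + (quad_setup["Z"] - quad_setup["Zc"][0, 2])**2)
        num = np.array([[-quad_setup["Zs"][0] * np.sum(a * b / r) * dV for b in aos]
                        for a in aos])
        # the 1/r singularity limits midpoint-rule accuracy
        assert np.abs(quad_setup["V"] - num).max() < 5e-3

    def test_kinetic_via_analytic_gradients(self, quad_setup):
        grads, dV = quad_setup["grads"], quad_setup["dV"]
        num = np.array([[0.5 * sum(np.sum(ga * gb) for ga, gb in zip(g1, g2)) * dV
                         for g2 in grads] for g1 in grads])
        assert np.abs(quad_setup["T"] - num).max() < 1e-10

    def test_eri_point_charge_limit(self, quad_setup):
        """(ab|δδ)/q ≈ nuclear attraction of a point charge at the δ center."""
        alpha = 5e5
        delta = Shell(l=0, exps=[alpha], coefs=[1.0], center=quad_setup["Zc"][0])
        pb2 = pack_shells(quad_setup["pb"].shells + [delta])
        G = eri_supermatrix(pb2)
        nd = (2 * alpha / np.pi) ** 0.75
        q_eff = nd**2 * (np.pi / (2 * alpha)) ** 1.5
        di = quad_setup["pb"].nbf
        errs = []
        for i in range(di):
            for j in range(i + 1):
                val = G[pair(i, j), pair(di, di)] / q_eff
                ref = -quad_setup["V"][i, j] / quad_setup["Zs"][0]
                errs.append(abs(val - ref))
        assert max(errs) < 5e-6


class TestSCFProperties:
    def test_orbitals_are_orthonormal(self, water_scf):
        C, S = water_scf.mo_coeff, water_scf.S
        eye = C.T @ S @ C
        assert np.abs(eye - np.eye(len(eye))).max() < 1e-8

    def test_energy_rotation_invariant(self, water_molecule):
        from scipy.spatial.transform import Rotation

        e0 = rhf(water_molecule, "pdzp").energy
        R = Rotation.from_euler("zyx", [71, -23, 48], degrees=True).as_matrix()
        rot = Molecule(water_molecule.symbols, water_molecule.coords @ R.T)
        e1 = rhf(rot, "pdzp").energy
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_water_energy_in_double_zeta_band(self, water_scf):
        # Hartree-Fock water: basis-set limit -76.067 Ha, minimal basis ~ -75.7
        assert -76.07 < water_scf.energy < -75.9

    def test_water_dipole_hartree_fock_range(self, water_scf):
        mu = np.linalg.norm(water_scf.dipole_moment()) * 4.80320
        assert 2.0 < mu < 2.35   # HF overpolarizes water (exp. 1.85 D)

    def test_h2_density_integrates_to_electron_count(self, sto3g_h):
        mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
        res = rhf(mol, sto3g_h)
        g = density_grid(res, origin=[-5, -5, -5], spacing=0.1, shape=(101, 101, 109))
        assert g.integral() == pytest.approx(2.0, abs=1e-3)

    def test_density_positive(self, water_scf):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-3, 3, size=(500, 3))
        assert np.all(density_values(water_scf, pts) >= 0)


class TestBoysLocalization:
    def test_water_valence_centers_geometry(self, water_scf, water_molecule):
        centers = localized_centers(water_scf)
        assert len(centers) == 4
        d_o = np.sort(np.linalg.norm(centers, axis=1))
        # two lone pairs near 0.3 Å, two bond centers near 0.5 Å from O
        assert np.all(np.abs(d_o[:2] - 0.30) < 0.06)
        assert np.all(np.abs(d_o[2:] - 0.52) < 0.06)

    def test_center_model_reproduces_scf_dipole(self, water_scf, water_molecule):
        centers = localized_centers(water_scf)
        mu_model = (6 * water_molecule.coords[0] + water_molecule.coords[1]
                    + water_molecule.coords[2] - 2 * centers.sum(axis=0))
        mu_scf = water_scf.dipole_moment()
        assert np.linalg.norm(mu_model - mu_scf) * 4.80320 < 0.02  # Debye
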