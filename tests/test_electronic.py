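"""Density-difference, Voronoi partitioning and localized-center analyses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from permeonics.core.types import AtomRecord, DensityGrid, Frame
from permeonics.electronic import (
    assign_and_classify_centers,
    center_shift,
    charge_transfer,
    density_difference,
    molecular_dipole,
    voronoi_integrate,
)
from permeonics.synthetic import gen_cluster_geometry, gen_gaussian_density, \
    gen_wannier_fixture

GRID = dict(origin=[-6.0, -6.0, -6.0], spacing=0.15, shape=(81, 81, 81))


def cluster_atoms():
    return gen_cluster_geometry(7, 2.4).atoms


class TestDensityDifference:
    def test_exact_cancellation(self):
        atoms = cluster_atoms()
        lig = gen_gaussian_density([([0, 0, 0], 18, 0.5)], **GRID)
        rest = gen_gaussian_density([([2.4, 0, 0], 10, 0.7)], **GRID)
        comp = DensityGrid(origin=lig.origin, voxel_vectors=lig.voxel_vectors,
                           values=lig.values + rest.values, atoms=atoms)
        delta = density_difference(comp, lig, rest)
        # cancellation to machine precision of the summands
        assert np.abs(delta.values).max() <= 4e-16 * comp.values.max()
        assert [a.atom_id for a in delta.atoms] == [a.atom_id for a in atoms]

    def test_electron_count_conservation(self):
        comp = gen_gaussian_density([([0, 0, 1], 28, 0.8)], **GRID)
        lig = gen_gaussian_density([([0, 0, 1], 18, 0.6)], **GRID)
        rest = gen_gaussian_density([([0, 0, 1], 10, 0.9)], **GRID)
        delta = density_difference(comp, lig, rest)
        assert delta.integral() == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_shape_names_field(self):
        a = gen_gaussian_density([([0, 0, 0], 1, 0.5)], **GRID)
        b = gen_gaussian_density([([0, 0, 0], 1, 0.5)],
                                 origin=[-6, -6, -6], spacing=0.15, shape=(80, 81, 81))
        with pytest.raises(ValueError, match="shape"):
            density_difference(a, b, a)

    def test_mismatched_origin_names_field(self):
        a = gen_gaussian_density([([0, 0, 0], 1, 0.5)], **GRID)
        b = gen_gaussian_density([([0, 0, 0], 1, 0.5)],
                                 origin=[-6.001, -6, -6], spacing=0.15,
                                 shape=(81, 81, 81))
        with pytest.raises(ValueError, match="origin"):
            density_difference(a, a, b)


class TestVoronoi:
    def test_single_site_gets_everything(self):
        g = gen_gaussian_density([([1, 0, 0], 5, 0.8)], **GRID)
        out = voronoi_integrate(g, np.array([[0.3, 0.2, -0.1]]))
        assert out[0] == pytest.approx(g.integral(), rel=1e-12)

    def test_reflection_symmetric_density_splits_in_half(self):
        # the z axis is symmetric about 0 with no grid point on the tie plane
        g = gen_gaussian_density([([0, 0, 2], 4, 0.9), ([0, 0, -2], 4, 0.9)],
                                 origin=[-6, -6, -6.075], spacing=0.15,
                                 shape=(81, 81, 82))
        out = voronoi_integrate(g, np.array([[0, 0, 2.0], [0, 0, -2.0]]))
        assert abs(out[0] - out[1]) < 1e-9

    def test_tie_plane_goes_to_lowest_site_index(self):
        g = gen_gaussian_density([([0, 0, 0], 1.0, 0.9)], **GRID)
        hi = voronoi_integrate(g, np.array([[0, 0, 2.0], [0, 0, -2.0]]))
        lo = voronoi_integrate(g, np.array([[0, 0, -2.0], [0, 0, 2.0]]))
        # whichever site is listed first receives the z = 0 plane
        assert hi[0] > hi[1]
        assert lo[0] > lo[1]

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(8)
        sites = rng.uniform(-3, 3, size=(5, 3))
        g = gen_gaussian_density([(s, k + 1.0, 0.9) for k, s in enumerate(sites)],
                                 **GRID)
        out = voronoi_integrate(g, sites)
        assert out.sum() == pytest.approx(g.integral(), rel=1e-12)

    def test_against_monte_carlo_quadrature(self):
        rng = np.random.default_rng(12)
        sites = rng.uniform(-2.5, 2.5, size=(5, 3))
        comps = [(s, 2.0 + k, 0.8) for k, s in enumerate(sites)]
        g = gen_gaussian_density(comps, **GRID)
        grid_result = voronoi_integrate(g, sites)

        # Monte-Carlo nearest-site quadrature of the analytic density
        n_mc = 1_000_000
        pts = rng.uniform(-6, 6, size=(n_mc, 3))
        vol = 12.0**3
        rho = np.zeros(n_mc)
        for c, ne, sig in comps:
            r2 = ((pts - np.asarray(c))**2).sum(axis=1)
            rho += ne * np.exp(-r2 / (2 * sig**2)) / ((2 * np.pi)**1.5 * sig**3)
        owner = np.argmin(((pts[:, None, :] - sites[None])**2).sum(-1), axis=1)
        for k in range(len(sites)):
            sel = owner == k
            est = rho[sel].sum() * vol / n_mc
            sigma = rho[sel].std() * vol * np.sqrt(sel.sum()) / n_mc
            assert abs(grid_result[k] - est) < 3 * sigma + 1e-3

    def test_empty_sites_rejected(self):
        g = gen_gaussian_density([([0, 0, 0], 1, 0.5)], **GRID)
        with pytest.raises(ValueError, match="empty"):
            voronoi_integrate(g, np.zeros((0, 3)))


class TestChargeTransfer:
    def test_zero_delta_keeps_nominal_charge(self):
        atoms = cluster_atoms()
        delta = gen_gaussian_density([], atoms=atoms, **GRID)
        t = charge_transfer(delta, ion_id=0, nominal_charge=2.0)
        assert t.effective_ion_charge == pytest.approx(2.0)
        assert t.per_water_mean_loss == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_donation_pattern(self):
        # +0.21 e on the ion, −0.03 e on each of the 7 water oxygens
        atoms = cluster_atoms()
        comps = [([0.0, 0.0, 0.0], 0.21, 0.35)]
        for a in atoms:
            if a.role == "water_O":
                comps.append((a.position, -0.03, 0.35))
        delta = gen_gaussian_density(comps, atoms=atoms, **GRID)
        t = charge_transfer(delta, ion_id=0, nominal_charge=2.0)
        assert t.effective_ion_charge == pytest.approx(1.79, abs=0.005)
        assert t.per_water_mean_loss == pytest.approx(0.03, abs=0.002)
        assert t.per_element["Ca"] == pytest.approx(0.21, abs=0.005)

    def test_electron_conservation_invariant(self):
        atoms = cluster_atoms()
        rng = np.random.default_rng(3)
        comps = [(rng.uniform(-3, 3, 3), rng.uniform(-1, 1), 0.6) for _ in range(6)]
        delta = gen_gaussian_density(comps, atoms=atoms, **GRID)
        t = charge_transfer(delta, ion_id=0)
        assert t.total() == pytest.approx(delta.integral(), rel=1e-10)

    def test_snapshot_averaging_reports_sd(self):
        atoms = cluster_atoms()
        d1 = gen_gaussian_density([([0, 0, 0], 0.2, 0.4)], atoms=atoms, **GRID)
        d2 = gen_gaussian_density([([0, 0, 0], 0.3, 0.4)], atoms=atoms, **GRID)
        t = charge_transfer(d1, ion_id=0, snapshots=[d2])
        assert t.element_stats.loc["Ca", "mean"] == pytest.approx(0.25, abs=0.01)
        assert t.element_stats.loc["Ca", "sd"] > 0

    def test_missing_ion_rejected(self):
        delta = gen_gaussian_density([], atoms=cluster_atoms(), **GRID)
        with pytest.raises(ValueError, match="ion"):
            charge_transfer(delta, ion_id=999)


def water_frame_and_centers(target=1.85):
    return gen_wannier_fixture(target)


class TestClassification:
    def test_center_on_oh_axis_is_bond(self):
        frame, _ = water_frame_and_centers()
        o = frame.atoms[0].position
        h = frame.atoms[1].position
        c = o + 0.5 * (h - o) / np.linalg.norm(h - o)
        cs = assign_and_classify_centers(np.array([c]), frame)
        assert cs.centers[0].kind == "OH_bond"

    def test_center_perpendicular_to_plane_is_lone_pair(self):
        frame, _ = water_frame_and_centers()
        c = frame.atoms[0].position + np.array([0.0, 0.3, 0.0])
        cs = assign_and_classify_centers(np.array([c]), frame)
        assert cs.centers[0].kind == "lone_pair"

    def test_fixture_has_two_bonds_two_lone_pairs(self):
        frame, centers = water_frame_and_centers()
        cs = assign_and_classify_centers(centers, frame)
        assert cs.kinds() == {"OH_bond": 2, "lone_pair": 2}

    def test_far_center_unassigned_with_warning(self):
        frame, _ = water_frame_and_centers()
        with pytest.warns(UserWarning, match="unassigned"):
            cs = assign_and_classify_centers(np.array([[5.0, 5.0, 5.0]]), frame)
        assert cs.centers[0].kind == "unassigned"

    def test_classification_rotation_invariant(self):
        frame, centers = water_frame_and_centers()
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [33, -57, 121], degrees=True).as_matrix()
        atoms = [AtomRecord(a.element, R @ a.position, a.role, a.molecule_id,
                            a.atom_id) for a in frame.atoms]
        rframe = Frame(0.0, atoms, frame.box)
        c1 = assign_and_classify_centers(centers, frame)
        c2 = assign_and_classify_centers(centers @ R.T, rframe)
        assert [c.kind for c in c1.centers] == [c.kind for c in c2.centers]


class TestCenterShift:
    def test_identical_sets_shift_zero(self):
        frame, centers = water_frame_and_centers()
        cs = assign_and_classify_centers(centers, frame)
        out = center_shift(cs, cs, np.array([0.0, 0.0, 5.0]))
        assert out["lone_pair"] == pytest.approx(0.0, abs=1e-12)
        assert out["OH_bond"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_lone_pair_displacement(self):
        frame, centers = water_frame_and_centers()
        ion = np.array([0.0, 0.0, -4.0])   # on the lone-pair side
        o = frame.atoms[0].position
        u = (ion - o) / np.linalg.norm(ion - o)
        moved = centers.copy()
        moved[2] += 0.03 * u
        moved[3] += 0.03 * u
        a = assign_and_classify_centers(moved, frame)
        b = assign_and_classify_centers(centers, frame)
        out = center_shift(a, b, ion)
        assert out["lone_pair"] == pytest.approx(0.03, abs=1e-9)
        assert out["OH_bond"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_bond_displacement_toward_oxygen(self):
        frame, centers = water_frame_and_centers()
        o = frame.atoms[0].position
        moved = centers.copy()
        for k, hid in ((0, 1), (1, 2)):
            h = frame.atoms[hid].position
            u = (o - h) / np.linalg.norm(o - h)
            moved[k] += 0.06 * u
        a = assign_and_classify_centers(moved, frame)
        b = assign_and_classify_centers(centers, frame)
        out = center_shift(a, b, np.array([0.0, 0.0, -4.0]))
        assert out["OH_bond"] == pytest.approx(0.06, abs=1e-9)

    def test_unmatched_centers_rejected(self):
        frame, centers = water_frame_and_centers()
        a = assign_and_classify_centers(centers, frame)
        b = assign_and_classify_centers(centers[:3], frame)
        with pytest.raises(ValueError, match="unmatched|match"):
            center_shift(a, b, np.zeros(3))


class TestMolecularDipole:
    def test_fixture_round_trips_target(self):
        frame, centers = gen_wannier_fixture(1.85)
        cs = assign_and_classify_centers(centers, frame)
        assert molecular_dipole(cs, 0).magnitude == pytest.approx(1.85, abs=0.01)

    def test_cancelling_placement_gives_zero(self):
        frame, centers = gen_wannier_fixture(0.0)
        cs = assign_and_classify_centers(centers, frame)
        assert molecular_dipole(cs, 0).magnitude == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    def test_translation_invariance(self, tx, ty, tz):
        t = np.array([tx, ty, tz])
        frame, centers = gen_wannier_fixture(2.3)
        cs = assign_and_classify_centers(centers, frame)
        mag0 = molecular_dipole(cs, 0).magnitude
        atoms = [AtomRecord(a.element, a.position + t, a.role, a.molecule_id,
                            a.atom_id) for a in frame.atoms]
        cs_t = assign_and_classify_centers(centers + t, Frame(0.0, atoms, frame.box))
        assert molecular_dipole(cs_t, 0).magnitude == pytest.approx(mag0, abs=1e-9)

    def test_wrong_center_count_rejected(self):
        frame, centers = gen_wannier_fixture(1.85)
        cs = assign_and_classify_centers(centers[:3], frame)
        with pytest.raises(ValueError, match="centers"):
            molecular_dipole(cs, 0)
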