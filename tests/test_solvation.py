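"""Occupancy, Boltzmann inversion, RDF and coordination statistics."""

import numpy as np
import pytest

from permeonics.constants import Constants
from permeonics.core.types import AtomRecord, Frame, Trajectory
from permeonics.solvation import (
    OccupancyProfile,
    boltzmann_invert,
    coordination_count,
    hydration_profile,
    occupancy,
    rdf,
)
from permeonics.synthetic import gen_cluster_geometry, gen_ideal_gas


def fixed_ion_traj(pos, n_frames=10, box=(10.0, 10.0, 10.0)):
    frames = [Frame(float(k),
                    [AtomRecord("Ca", np.asarray(pos, float), "ion", 0, 0)],
                    np.asarray(box)) for k in range(n_frames)]
    return Trajectory(frames=frames)


class TestOccupancy:
    def test_fixed_ion_single_bin(self):
        traj = fixed_ion_traj([5.0, 5.0, 5.0])
        prof = occupancy(traj, bins=np.array([0.0, 10.0]))
        assert prof.counts[0] == 10
        assert prof.relative[0] == 1.0

    def test_concentration_of_one_ion_per_1000_A3(self):
        traj = fixed_ion_traj([5.0, 5.0, 5.0])
        prof = occupancy(traj, bins=np.array([0.0, 10.0]))
        assert prof.concentration[0] == pytest.approx(1.6605, abs=2e-4)

    def test_uniform_positions_give_flat_profile(self):
        gas = gen_ideal_gas(200, [10, 10, 50], 100, seed=2, role="ion", element="Ca")
        edges = np.linspace(0, 50, 11)
        prof = occupancy(gas, bins=edges)
        # binomial Monte-Carlo bound: p = 1/10 per ion-frame sample
        n = 200 * 100
        p = 0.1
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(prof.counts - n * p) < 3 * sigma)

    def test_counts_conserved_over_covering_bins(self):
        gas = gen_ideal_gas(50, [10, 10, 50], 20, seed=3, role="ion", element="Ca")
        prof = occupancy(gas, bins=np.linspace(0, 50, 26))
        assert prof.counts.sum() == 50 * 20

    def test_2d_mode_bins_axial_radial(self):
        traj = fixed_ion_traj([5.0, 5.0, 25.0], box=(10, 10, 50))
        prof = occupancy(traj, bins_2d=(np.linspace(0, 50, 6), np.linspace(0, 8, 5)),
                         axis_xy=(5.0, 5.0))
        assert prof.counts.sum() == 10
        assert prof.counts[2, 0] == 10  # z bin containing 25, r = 0

    def test_zero_volume_bin_rejected(self):
        traj = fixed_ion_traj([5, 5, 5])
        with pytest.raises(ValueError, match="volume"):
            occupancy(traj, bins=np.array([0.0, 5.0, 5.0, 10.0]))


class TestBoltzmannInversion:
    def _profile_from_density(self, density, volumes=1.0):
        density = np.asarray(density, float)
        counts = density * 1000.0
        return OccupancyProfile(
            bin_edges=(np.arange(len(density) + 1, dtype=float),),
            counts=counts, n_frames=1000,
            bin_volumes=np.full_like(density, volumes),
            density=density, concentration=density * 1660.54)

    def test_uniform_density_gives_zero_free_energy(self):
        prof = boltzmann_invert(self._profile_from_density(np.ones(20)))
        assert np.allclose(prof.free_energy.compressed(), 0.0)

    def test_gaussian_density_gives_harmonic_free_energy(self):
        z = np.linspace(-3, 3, 61)
        sigma = 1.2
        prof = self._profile_from_density(np.exp(-z**2 / (2 * sigma**2)))
        prof = boltzmann_invert(prof)
        expected = z**2 / (2 * sigma**2)
        assert np.max(np.abs(prof.free_energy - expected)) < 0.02

    def test_ratio_e_inverse_is_one_kbt(self):
        prof = boltzmann_invert(self._profile_from_density([1.0, np.exp(-1.0)]))
        assert float(prof.free_energy[1]) == pytest.approx(1.0, abs=1e-12)
        kT = Constants(303.0).kT_kj_per_mol
        assert float(prof.free_energy_kj_mol[1]) == pytest.approx(kT, rel=1e-6)

    def test_empty_bins_masked_not_infinite(self):
        prof = boltzmann_invert(self._profile_from_density([1.0, 0.0, 0.5]))
        assert np.ma.is_masked(prof.free_energy[1])
        assert np.isfinite(prof.free_energy.compressed()).all()

    def test_all_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_invert(self._profile_from_density([0.0, 0.0]))

    def test_inversion_roundtrip_up_to_additive_constant(self):
        rng = np.random.default_rng(5)
        F_true = rng.random(30) * 4.0
        density = np.exp(-F_true)
        prof = boltzmann_invert(self._profile_from_density(density))
        diff = prof.free_energy.compressed() - F_true
        assert np.ptp(diff) < 1e-12


def water_shell_frame(n=7, r=2.4):
    return gen_cluster_geometry(n_waters=n, ca_o_distance=r)


class TestRdf:
    def test_delta_pair_occupies_single_bin(self):
        atoms = [AtomRecord("Ca", np.array([10.0, 10, 10]), "ion", 0, 0),
                 AtomRecord("O", np.array([12.4, 10, 10]), "water_O", 1, 1)]
        traj = Trajectory(frames=[Frame(0.0, atoms, np.array([20.0, 20, 20]))])
        res = rdf(traj, "ion", "water_O", r_max=5.0, dr=0.1)
        nz = np.nonzero(res.g)[0]
        assert len(nz) == 1
        assert abs(res.r_centers[nz[0]] - 2.4) <= 0.05 + 1e-9

    def test_ideal_gas_is_uniform(self):
        gas = gen_ideal_gas(1000, [20, 20, 20], 50, seed=4, role="water_O",
                            element="O")
        # one fixed probe center in every frame
        frames = []
        for f in gas.frames:
            center = AtomRecord("Ca", np.array([10.0, 10, 10]), "ion", 9999, 9999)
            frames.append(Frame(f.time, [center] + f.atoms, f.box))
        traj = Trajectory(frames=frames)
        res = rdf(traj, "ion", "water_O", r_max=8.0, dr=0.25)
        sel = res.r_centers > 2.0
        assert np.mean(np.abs(res.g[sel] - 1.0)) < 0.05

    def test_running_coordination_matches_direct_count(self):
        frame = water_shell_frame()
        traj = Trajectory(frames=[frame])
        res = rdf(traj, "ion", "water_O", r_max=4.0, dr=0.05)
        ca = frame.atoms[0]
        direct = coordination_count(frame, ca, "water_O", 4.0)
        assert res.n_running[-1] == pytest.approx(direct)
        assert np.all(np.diff(res.n_running) >= 0)

    def test_rmax_beyond_half_box_rejected(self):
        traj = Trajectory(frames=[water_shell_frame()])
        with pytest.raises(ValueError, match="half"):
            rdf(traj, "ion", "water_O", r_max=16.0)

    def test_empty_conditioned_window_rejected(self):
        traj = Trajectory(frames=[water_shell_frame()])
        with pytest.raises(ValueError, match="empty|samples"):
            rdf(traj, "ion", "water_O", r_max=4.0, condition_window=(100.0, 110.0))

    def test_conditioning_restricts_samples(self):
        f1 = water_shell_frame()
        atoms2 = [AtomRecord(a.element, a.position + np.array([0, 0, 8.0]),
                             a.role, a.molecule_id, a.atom_id) for a in f1.atoms]
        f2 = Frame(1.0, atoms2, f1.box)
        traj = Trajectory(frames=[f1, f2])
        res = rdf(traj, "ion", "water_O", r_max=4.0, dr=0.1,
                  condition_window=(7.0, 9.0))
        assert res.n_running[-1] == pytest.approx(7.0)  # only the shifted frame


class TestCoordination:
    def test_seven_fold_shell(self):
        frame = water_shell_frame(7, 2.4)
        assert coordination_count(frame, frame.atoms[0], "water_O", 3.2) == 7

    def test_no_partner_in_cutoff(self):
        frame = water_shell_frame(7, 2.4)
        assert coordination_count(frame, frame.atoms[0], "water_O", 1.0) == 0

    def test_partner_exactly_at_cutoff_counts(self):
        # closed boundary, cross-checked against the brute-force distance list
        atoms = [AtomRecord("Ca", np.zeros(3), "ion", 0, 0),
                 AtomRecord("O", np.array([3.2, 0, 0]), "water_O", 1, 1),
                 AtomRecord("O", np.array([0, 3.2001, 0]), "water_O", 2, 2)]
        frame = Frame(0.0, atoms, np.array([50.0, 50, 50]))
        dists = sorted(np.linalg.norm(a.position) for a in atoms[1:])
        brute = sum(1 for d in dists if d <= 3.2)
        assert coordination_count(frame, atoms[0], "water_O", 3.2) == brute == 1

    def test_infinite_cutoff_counts_everything(self):
        frame = water_shell_frame(6, 2.4)
        assert coordination_count(frame, frame.atoms[0], "water_O", 14.9) == 6


class TestHydrationProfile:
    def _shell_traj(self, z_positions, n_waters=6):
        frames = []
        base = gen_cluster_geometry(n_waters=n_waters)
        for k, z in enumerate(z_positions):
            shift = np.array([15.0, 15.0, z])
            atoms = [AtomRecord(a.element, a.position + shift, a.role,
                                a.molecule_id, a.atom_id) for a in base.atoms]
            frames.append(Frame(float(k), atoms, np.array([30.0, 30.0, 60.0])))
        return Trajectory(frames=frames)

    def test_fixed_shell_is_flat_with_zero_sd(self):
        traj = self._shell_traj(np.linspace(5, 55, 12))
        prof = hydration_profile(traj, z_bins=np.linspace(0, 60, 7))
        filled = prof.n_samples > 0
        assert np.allclose(prof.water_mean[filled], 6.0)
        assert np.allclose(prof.water_sd[filled], 0.0)

    def test_step_profile_when_shell_changes(self):
        lo = self._shell_traj([10.0, 12.0], n_waters=7)
        hi = self._shell_traj([40.0, 42.0], n_waters=6)
        frames = lo.frames + [Frame(f.time + 2.0, f.atoms, f.box) for f in hi.frames]
        traj = Trajectory(frames=frames)
        prof = hydration_profile(traj, z_bins=np.array([0.0, 30.0, 60.0]))
        assert prof.water_mean[0] == pytest.approx(7.0)
        assert prof.water_mean[1] == pytest.approx(6.0)

    def test_residue_with_two_oxygens_counts_once(self):
        atoms = [AtomRecord("Ca", np.array([5.0, 5, 5]), "ion", 0, 0),
                 AtomRecord("O", np.array([7.0, 5, 5]), "protein", 42, 1),
                 AtomRecord("O", np.array([5.0, 7, 5]), "protein", 42, 2),
                 AtomRecord("O", np.array([5.0, 5, 7.5]), "protein", 43, 3)]
        traj = Trajectory(frames=[Frame(0.0, atoms, np.array([20.0, 20, 20]))])
        prof = hydration_profile(traj, z_bins=np.array([0.0, 10.0]),
                                 protein_cutoff=3.2)
        assert prof.protein_mean[0] == pytest.approx(2.0)  # residues 42 and 43

    def test_empty_bins_are_nan(self):
        traj = self._shell_traj([10.0])
        prof = hydration_profile(traj, z_bins=np.array([0.0, 20.0, 40.0]))
        assert np.isnan(prof.water_mean[1])
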