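"""Ion occupancy, free-energy maps and hydration statistics.

Occupancy profiles bin ion positions along the pore axis (1-D in z, or
2-D in z and the distance r from the pore axis), convert counts to number
density, molar concentration, and — by Boltzmann inversion
F = -k_BT·ln(ρ/ρ_max) — to a free-energy profile whose most occupied bin
defines F = 0.

Radial distribution functions use minimum-image distances in the
orthorhombic box; the running coordination number is obtained by direct
counting (not by integrating g), so it is exact independent of binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import Constants, DEFAULT_TEMPERATURE, density_to_mol_per_liter
from .core.types import AtomRecord, Frame, Trajectory, make_selector


@dataclass
class OccupancyProfile:
    """Binned ion density along z (1-D) or (z, r) (2-D)."""

    bin_edges: tuple[np.ndarray, ...]   # 1 or 2 edge arrays
    counts: np.ndarray
    n_frames: int
    bin_volumes: np.ndarray             # Å³ per bin
    density: np.ndarray                 # Å⁻³
    concentration: np.ndarray           # mol/L
    free_energy: np.ndarray | None = None        # masked array, k_BT
    free_energy_kj_mol: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)

    @property
    def relative(self) -> np.ndarray:
        """Occupancy normalized to its maximum (dimensionless)."""
        m = self.density.max()
        if m <= 0:
            raise ValueError("empty occupancy profile")
        return self.density / m

    def bin_centers(self, axis: int = 0) -> np.ndarray:
        e = self.bin_edges[axis]
        return 0.5 * (e[1:] + e[:-1])


@dataclass
class RdfResult:
    r_edges: np.ndarray
    g: np.ndarray
    n_running: np.ndarray       # mean partner count within r (at bin upper edges)
    reference_density: float    # Å⁻³
    condition_window: tuple[float, float] | None = None

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])


@dataclass
class HydrationProfile:
    z_edges: np.ndarray
    water_mean: np.ndarray
    water_sd: np.ndarray
    protein_mean: np.ndarray
    protein_sd: np.ndarray
    n_samples: np.ndarray

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[1:] + self.z_edges[:-1])


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - np.round(d / box) * box


def occupancy(traj: Trajectory, ion_selection="ion", bins=None, bins_2d=None,
              axis_xy: tuple[float, float] = (0.0, 0.0),
              temperature: float = DEFAULT_TEMPERATURE) -> OccupancyProfile:
    """Accumulate an ion occupancy histogram over all frames.

    ``bins``: 1-D bin edges along z (Å). ``bins_2d``: (z_edges, r_edges) for
    an axial-radial map, with r the distance from the pore axis at
    ``axis_xy``. Bin volumes: Lx·Ly·Δz for 1-D, π(r₂²−r₁²)·Δz for 2-D
    (azimuthally averaged).
    """
    if (bins is None) == (bins_2d is None):
        raise ValueError("pass exactly one of bins (1-D) or bins_2d")
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    per_ion = traj.positions_by_atom(ion_selection)
    if not per_ion:
        raise ValueError("ion selection matched no atoms")
    pos = np.concatenate([p for p in per_ion.values()], axis=0)  # (nf*nion, 3)
    box = traj.boxes().mean(axis=0)

    if bins is not None:
        z_edges = np.asarray(bins, float)
        counts, _ = np.histogram(pos[:, 2], bins=z_edges)
        counts = counts.astype(float)
        vols = box[0] * box[1] * np.diff(z_edges)
        edges = (z_edges,)
    else:
        z_edges = np.asarray(bins_2d[0], float)
        r_edges = np.asarray(bins_2d[1], float)
        r = np.hypot(pos[:, 0] - axis_xy[0], pos[:, 1] - axis_xy[1])
        counts, _, _ = np.histogram2d(pos[:, 2], r, bins=(z_edges, r_edges))
        vols = (np.pi * np.diff(r_edges**2)[None, :] * np.diff(z_edges)[:, None])
        edges = (z_edges, r_edges)
    if np.any(vols <= 0):
        raise ValueError("zero-volume bin")
    density = counts / (traj.n_frames * vols)
    conc = density_to_mol_per_liter(1.0) * density
    return OccupancyProfile(bin_edges=edges, counts=counts, n_frames=traj.n_frames,
                            bin_volumes=vols, density=density, concentration=conc,
                            temperature=temperature)


def boltzmann_invert(profile: OccupancyProfile) -> OccupancyProfile:
    """Fill the free-energy fields: F = -k_BT ln(ρ/ρ_max), empty bins masked."""
    if profile.density.max() <= 0:
        raise ValueError("cannot invert an all-empty profile")
    occ_mask = profile.counts > 0
    F = np.ma.masked_array(np.zeros_like(profile.density), mask=~occ_mask)
    F[occ_mask] = -np.log(profile.density[occ_mask] / profile.density.max())
    kT_kj = Constants(profile.temperature).kT_kj_per_mol
    profile.free_energy = F
    profile.free_energy_kj_mol = F * kT_kj
    return profile


def rdf(traj: Trajectory, center_selection="ion", partner_selection="water_O",
        r_max: float = 8.0, dr: float = 0.05,
        condition_window: tuple[float, float] | None = None,
        reference_density: float | None = None) -> RdfResult:
    """Radial distribution function and running coordination number.

    g(r) is normalized by ``reference_density`` (default: mean partner
    count / box volume — note that in a confined pore this is not a bulk
    density). ``condition_window`` restricts the (frame, center) samples to
    those where the center's z lies inside the window. n_running(r) is the
    mean number of partners within r by direct counting.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    box0 = traj.boxes().min(axis=0)
    if r_max >= box0.min() / 2:
        raise ValueError("r_max must be below half the smallest box edge")
    cen_sel = make_selector(center_selection)
    par_sel = make_selector(partner_selection)
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    hist = np.zeros(len(edges) - 1)
    n_samples = 0
    n_partners_total = 0
    vol_total = 0.0
    for frame in traj.frames:
        centers = frame.positions(cen_sel)
        partners = frame.positions(par_sel)
        if len(centers) == 0:
            continue
        if condition_window is not None:
            lo, hi = condition_window
            centers = centers[(centers[:, 2] >= lo) & (centers[:, 2] <= hi)]
            if len(centers) == 0:
                continue
        d = _minimum_image(partners[None, :, :] - centers[:, None, :], frame.box)
        dist = np.linalg.norm(d, axis=-1).ravel()
        dist = dist[dist > 1e-12]  # drop self-pairs if selections overlap
        hist += np.histogram(dist, bins=edges)[0]
        n_samples += len(centers)
        n_partners_total += len(centers) * len(partners)
        vol_total += len(centers) * np.prod(frame.box)
    if n_samples == 0:
        raise ValueError("no center samples (empty conditioned frame set?)")
    rho_ref = reference_density
    if rho_ref is None:
        rho_ref = n_partners_total / vol_total
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    g = hist / (n_samples * rho_ref * shell_vol)
    n_running = np.cumsum(hist) / n_samples
    return RdfResult(r_edges=edges, g=g, n_running=n_running,
                     reference_density=float(rho_ref),
                     condition_window=condition_window)


def coordination_count(frame: Frame, center: AtomRecord, partner_selection,
                       cutoff: float) -> int:
    """Partners within ``cutoff`` Å of the center (minimum image, closed
    boundary: a partner exactly at the cutoff counts)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    partners = frame.positions(partner_selection)
    if len(partners) == 0:
        return 0
    d = _minimum_image(partners - center.position, frame.box)
    dist = np.linalg.norm(d, axis=-1)
    dist = dist[dist > 1e-12] if _same_atom_possible(frame, center, partner_selection) else dist
    return int(np.sum(dist <= cutoff))


def _same_atom_possible(frame: Frame, center: AtomRecord, partner_selection) -> bool:
    sel = make_selector(partner_selection)
    return sel(center)


def hydration_profile(traj: Trajectory, ion_selection="ion", z_bins=None,
                      water_cutoff: float = 3.2, protein_cutoff: float = 3.2) -> HydrationProfile:
    """Water-oxygen and protein-residue coordination along the pore axis.

    For every (frame, ion) sample the ion's z selects a bin; the water
    count is the number of water_O within ``water_cutoff``, the protein
    count the number of distinct protein molecule_ids (residues) with at
    least one oxygen within ``protein_cutoff``. Reported as mean ± sd per
    bin; empty bins are NaN.
    """
    z_edges = np.asarray(z_bins, float)
    nb = len(z_edges) - 1
    sums_w = np.zeros(nb)
    sums_w2 = np.zeros(nb)
    sums_p = np.zeros(nb)
    sums_p2 = np.zeros(nb)
    n = np.zeros(nb, dtype=int)
    ion_sel = make_selector(ion_selection)
    for frame in traj.frames:
        waters = frame.positions("water_O")
        prot = [(a.molecule_id, a.position) for a in frame.atoms
                if a.role == "protein" and a.element == "O"]
        prot_pos = np.array([p for _, p in prot]) if prot else np.zeros((0, 3))
        prot_mol = np.array([m for m, _ in prot], dtype=int)
        for ion in frame.atoms:
            if not ion_sel(ion):
                continue
            k = np.searchsorted(z_edges, ion.position[2], side="right") - 1
            if k < 0 or k >= nb:
                continue
            if len(waters):
                dw = _minimum_image(waters - ion.position, frame.box)
                cw = int(np.sum(np.linalg.norm(dw, axis=-1) <= water_cutoff))
            else:
                cw = 0
            if len(prot_pos):
                dp = _minimum_image(prot_pos - ion.position, frame.box)
                near = np.linalg.norm(dp, axis=-1) <= protein_cutoff
                cp = len(set(prot_mol[near].tolist()))
            else:
                cp = 0
            sums_w[k] += cw
            sums_w2[k] += cw * cw
            sums_p[k] += cp
            sums_p2[k] += cp * cp
            n[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        wm = np.where(n > 0, sums_w / np.maximum(n, 1), np.nan)
        pm = np.where(n > 0, sums_p / np.maximum(n, 1), np.nan)
        wv = np.where(n > 0, sums_w2 / np.maximum(n, 1) - wm**2, np.nan)
        pv = np.where(n > 0, sums_p2 / np.maximum(n, 1) - pm**2, np.nan)
    return HydrationProfile(z_edges=z_edges,
                            water_mean=wm, water_sd=np.sqrt(np.maximum(wv, 0)),
                            protein_mean=pm, protein_sd=np.sqrt(np.maximum(pv, 0)),
                            n_samples=n)
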