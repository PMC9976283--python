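"""Synthetic generators with the statistical structure the analyses assume.

The pore simulator is an overdamped (Brownian) Langevin model of ions on
the channel axis: Gaussian binding-site wells, a constant transmembrane
field E = V/L_z, screened ion-ion repulsion (the minimal ingredient that
reproduces a loosely coupled knock-on signature), a reflecting lateral
cylinder, and periodic recycling along z that emulates the reservoirs of
a computational-electrophysiology setup.

Default parameters emulate the published study conditions: a divalent ion
(q = 2 e) at 600 mV across a ~70 Å box at 303 K, four binding sites along
the filter and cavity. Well depths of a few k_BT and a confined diffusion
coefficient of 30 Å²/ns are the package's own choices of realistic
magnitudes (the study reports free-energy maps, not well parameters).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import Constants, DEFAULT_TEMPERATURE
from .core.types import AtomRecord, DensityGrid, Frame, Trajectory
from .permeation import ChannelSpan

R_OH = 0.9572           # Å, gas-phase water
HOH_ANGLE = 104.52      # degrees


@dataclass
class PoreModel:
    """Parameters of the Brownian pore simulator."""

    span: ChannelSpan = field(default_factory=lambda: ChannelSpan(-10.0, 10.0))
    well_positions: tuple[float, ...] = (-7.0, -2.0, 3.0, 8.0)
    well_depths: tuple[float, ...] = (3.0, 4.0, 3.0, 2.0)   # k_BT
    well_width: float = 1.5          # Å (Gaussian sigma)
    voltage: float = 0.6             # V
    diffusion_coeff: float = 30.0    # Å²/ns
    ion_charge: float = 2.0          # e
    n_ions: int = 3
    coupling_strength: float = 25.0  # k_BT·Å (screened repulsion prefactor)
    screening_length: float = 3.0    # Å
    cylinder_radius: float = 2.0     # Å (selectivity-filter-like: quasi-single-file)
    box: tuple[float, float, float] = (30.0, 30.0, 70.0)
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.well_positions) != len(self.well_depths):
            raise ValueError("well positions/depths length mismatch")
        if any(d < 0 for d in self.well_depths):
            raise ValueError("well depths must be >= 0 (depth of attraction)")
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion coefficient must be positive")

    def field_force(self) -> float:
        """q·E in k_BT/Å for the configured voltage and box."""
        kT_ev = Constants(self.temperature).kT_ev
        return self.ion_charge * self.voltage / (self.box[2] * kT_ev)


def max_stable_dt(model: PoreModel) -> float:
    """Largest dt with step sd below a quarter of the well width."""
    return (model.well_width / 4.0) ** 2 / (2.0 * model.diffusion_coeff)


def gen_pore_trajectory(model: PoreModel, n_frames: int, dt: float,
                        substeps: int = 1) -> Trajectory:
    """Simulate ions in the pore; one frame is recorded every ``substeps``.

    Euler-Maruyama integration of dz = βD·F dt + √(2D dt)·η with F the sum
    of well, field and ion-ion forces (k_BT/Å); x, y diffuse freely inside
    a reflecting cylinder. z is wrapped into (-L_z/2, L_z/2], which
    recycles permeated ions back into the opposite reservoir.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_max = max_stable_dt(model)
    if model.well_depths and max(model.well_depths) > 0 and dt > dt_max:
        raise ValueError(
            f"dt = {dt} ns too large for well width {model.well_width} Å; "
            f"use dt <= {dt_max:.2e} ns")
    rng = np.random.default_rng(model.seed)
    n = model.n_ions
    if n < 1:
        raise ValueError("need at least one ion")
    D = model.diffusion_coeff
    lz = model.box[2]
    qE = model.field_force()
    wells_z = np.asarray(model.well_positions, float)
    wells_d = np.asarray(model.well_depths, float)
    w2 = model.well_width**2
    A = model.coupling_strength
    lam = model.screening_length

    z = (rng.random(n) - 0.5) * lz
    xy = np.zeros((n, 2))
    sigma = np.sqrt(2.0 * D * dt)
    frames = []
    box = np.asarray(model.box, float)

    def record(k: int) -> None:
        atoms = [AtomRecord("Ca", np.array([xy[i, 0], xy[i, 1], z[i]]),
                            "ion", i, i) for i in range(n)]
        frames.append(Frame(time=k * substeps * dt, atoms=atoms, box=box.copy()))

    record(0)
    chunk = 4096
    noise = None
    ptr = chunk
    total_steps = (n_frames - 1) * substeps
    for step in range(total_steps):
        if ptr >= chunk:
            noise = rng.standard_normal((chunk, n, 3))
            ptr = 0
        eta = noise[ptr]
        ptr += 1
        # force from the binding-site wells: F = -dU/dz, U = -Σ d_k exp(...)
        if len(wells_z):
            dzw = z[:, None] - wells_z[None, :]
            F = -(wells_d[None, :] * dzw / w2 * np.exp(-dzw**2 / (2 * w2))).sum(axis=1)
        else:
            F = np.zeros(n)
        F += qE
        if n > 1 and A > 0:
            dz_ij = z[:, None] - z[None, :]
            dz_ij -= np.round(dz_ij / lz) * lz
            dxy = xy[:, None, :] - xy[None, :, :]
            d = np.sqrt(dz_ij**2 + (dxy**2).sum(axis=-1))
            np.fill_diagonal(d, np.inf)
            mag = A * np.exp(-d / lam) * (1.0 / d**2 + 1.0 / (lam * d))
            F += (mag * dz_ij / d).sum(axis=1)
        z = z + D * F * dt + sigma * eta[:, 2]
        z -= np.round(z / lz) * lz
        xy = xy + sigma * eta[:, :2]
        r = np.linalg.norm(xy, axis=1)
        over = r > model.cylinder_radius
        if np.any(over):
            # reflect at the cylinder wall
            scale = (2 * model.cylinder_radius - r[over]) / r[over]
            xy[over] *= scale[:, None]
        if (step + 1) % substeps == 0:
            record((step + 1) // substeps)
    return Trajectory(frames=frames)


def gen_ideal_gas(n_atoms: int, box, n_frames: int, seed: int = 0,
                  element: str = "Ar", role: str = "other") -> Trajectory:
    """Uniform i.i.d. positions per frame (ideal-gas reference)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    frames = []
    for k in range(n_frames):
        pos = rng.random((n_atoms, 3)) * box
        atoms = [AtomRecord(element, pos[i], role, i, i) for i in range(n_atoms)]
        frames.append(Frame(time=float(k), atoms=atoms, box=box.copy()))
    return Trajectory(frames=frames)


def _sphere_code(n: int, seed: int = 0) -> np.ndarray:
    """n unit vectors minimizing pairwise Coulomb energy (Thomson problem)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=(n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)

    def energy(flat):
        p = flat.reshape(n, 3)
        p = p / np.linalg.norm(p, axis=1, keepdims=True)
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        iu = np.triu_indices(n, 1)
        return np.sum(1.0 / d[iu])

    res = minimize(energy, x0.ravel(), method="L-BFGS-B")
    p = res.x.reshape(n, 3)
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def gen_cluster_geometry(n_waters: int = 7, ca_o_distance: float = 2.4,
                         jitter: float = 0.0, seed: int = 0,
                         box: float = 30.0) -> Frame:
    """Ca²⁺ at the origin with n_waters first-shell waters.

    Water oxygens sit on a spherical code at the given radius; each water
    is oriented with its dipole toward the ion (hydrogens pointing away).
    Optional Gaussian positional jitter (Å) perturbs all atoms.
    """
    if n_waters < 1:
        raise ValueError("need at least one water")
    rng = np.random.default_rng(seed)
    units = _sphere_code(n_waters, seed=seed)
    ang = np.deg2rad(HOH_ANGLE)
    atoms = [AtomRecord("Ca", np.zeros(3), "ion", 0, 0)]
    aid = 1
    for m, u in enumerate(units, start=1):
        o = ca_o_distance * u
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        h1 = o + R_OH * (np.cos(ang / 2) * u + np.sin(ang / 2) * e1)
        h2 = o + R_OH * (np.cos(ang / 2) * u - np.sin(ang / 2) * e1)
        atoms.append(AtomRecord("O", o, "water_O", m, aid))
        atoms.append(AtomRecord("H", h1, "water_H", m, aid + 1))
        atoms.append(AtomRecord("H", h2, "water_H", m, aid + 2))
        aid += 3
    if jitter > 0:
        for a in atoms:
            a.position = a.position + rng.normal(scale=jitter, size=3)
    return Frame(time=0.0, atoms=atoms, box=np.array([box, box, box]))


def gen_gaussian_density(components, origin, spacing: float, shape,
                         atoms: list[AtomRecord] | None = None) -> DensityGrid:
    """Sum of isotropic normalized Gaussians with known electron counts.

    ``components``: iterable of (center, electron_count, sigma). The total
    integral is analytically Σ electron_count. Warns when a sigma is not
    resolved by the grid spacing.
    """
    import warnings

    origin = np.asarray(origin, float)
    nx, ny, nz = shape
    ax = origin[0] + spacing * np.arange(nx)
    ay = origin[1] + spacing * np.arange(ny)
    az = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    vals = np.zeros(shape, float)
    for center, ne, sigma in components:
        if sigma < spacing:
            warnings.warn(f"sigma {sigma} below grid spacing {spacing}: "
                          "density under-resolved", stacklevel=2)
        c = np.asarray(center, float)
        r2 = (X - c[0])**2 + (Y - c[1])**2 + (Z - c[2])**2
        vals += ne * np.exp(-r2 / (2 * sigma**2)) / ((2 * np.pi)**1.5 * sigma**3)
    return DensityGrid(origin=origin, voxel_vectors=np.eye(3) * spacing,
                       values=vals, atoms=atoms or [])


def gen_wannier_fixture(target_dipole: float, *, r_oh: float = R_OH,
                        angle_deg: float = HOH_ANGLE, lp_spread: float = 0.25,
                        bond_fraction: float = 0.5,
                        box: float = 20.0) -> tuple[Frame, np.ndarray]:
    """A single water plus 4 localized centers with a prescribed dipole.

    Bond centers sit at ``bond_fraction`` along each O-H bond, which makes
    them cancel the valence-nuclear term exactly at 0.5; the lone pairs sit
    symmetrically off the bisector, displaced by g = μ/(4·4.80320 D/eÅ)
    against the bisector so the dipole formula returns ``target_dipole``
    (in Debye) exactly.
    """
    if target_dipole < 0:
        raise ValueError("target dipole must be >= 0")
    ang = np.deg2rad(angle_deg)
    u = np.array([0.0, 0.0, 1.0])        # bisector, O -> midpoint(H,H)
    e1 = np.array([1.0, 0.0, 0.0])       # molecular plane
    n_hat = np.array([0.0, 1.0, 0.0])    # out of plane
    o = np.zeros(3)
    h1 = o + r_oh * (np.cos(ang / 2) * u + np.sin(ang / 2) * e1)
    h2 = o + r_oh * (np.cos(ang / 2) * u - np.sin(ang / 2) * e1)
    mu_nuc = 6 * o + h1 + h2
    # electrons: bonds at f·(O->H); lone pairs at -g·u ± s·n
    mu_bonds = -2 * bond_fraction * (h1 + h2 - 2 * o)
    residual = mu_nuc + mu_bonds         # along u by symmetry
    target_ea = target_dipole / 4.80320
    g = (target_ea - residual @ u) / 4.0
    if abs(g) > 0.6:
        raise ValueError(f"target {target_dipole} D infeasible for this geometry "
                         f"(lone-pair offset {g:.2f} Å)")
    c_b1 = o + bond_fraction * (h1 - o)
    c_b2 = o + bond_fraction * (h2 - o)
    c_l1 = o - g * u + lp_spread * n_hat
    c_l2 = o - g * u - lp_spread * n_hat
    atoms = [AtomRecord("O", o, "water_O", 0, 0),
             AtomRecord("H", h1, "water_H", 0, 1),
             AtomRecord("H", h2, "water_H", 0, 2)]
    frame = Frame(time=0.0, atoms=atoms, box=np.array([box, box, box]))
    return frame, np.array([c_b1, c_b2, c_l1, c_l2])
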