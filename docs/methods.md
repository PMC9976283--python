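# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Units and conventions

Lengths are in Å, times in ns, voltages in V, charges in units of the
elementary charge, energies in k_BT at the configured temperature
(default 303 K), electron densities in e/Å³, dipoles in Debye
(1 e·Å = 4.80320 D). The pore axis is z with +z pointing outward
(extracellular). Boxes are orthorhombic; triclinic input is rejected
explicitly. Cube files follow the Gaussian convention (positive voxel
counts signal Bohr units) and are converted on read.

## Permeation events and conductance

An ion is classified per frame as below, inside, or above the channel
span. An event is emitted only for a full traversal
(below → inside → above = outward; the mirror sequence = inward),
attributed to the frame of first exit on the far side. Re-entries that
retreat to the same side emit nothing, so thermal jitter at a boundary is
never double-counted; the counting rule is therefore a hysteresis
(two-plane) detector rather than a single-plane crossing counter.
Trajectories are unwrapped per ion by minimum image on the frame-to-frame
displacement (assumes physical steps < box_z/2; violations warn), and the
unwrapped coordinate is compared against the periodic image of the span
nearest each frame, which correctly counts repeated crossings in
reservoir-recycling (computational-electrophysiology-style) setups while
ignoring the recycling jumps themselves.

Counts convert to current I = n·q·e/t and conductance g = I/V in pS. Both
net (outward − inward, the default) and outward-only counting are exposed,
since published event counts rarely state the rule. Replica statistics use
the sample standard deviation (n−1); a single replica reports sd as
not available rather than 0.

## Occupancy, concentration, free energy

Occupancy histograms accumulate (frame, ion) samples on 1-D z bins
(volume Lx·Ly·Δz) or 2-D axial–radial (z, r) bins (volume π(r₂²−r₁²)Δz).
The 2-D map is the azimuthal average; a planar cross-section is a display
choice that the axial–radial symmetrization replaces for statistics.
Number density is counts/(frames × bin volume); concentration uses
1 Å⁻³ = 10²⁷/N_A mol/L ≈ 1660.54 mol/L. Boltzmann inversion sets
F = −k_BT ln(ρ/ρ_max) with the most occupied bin as the zero of free
energy (the reference is a convention; any other choice shifts F by a
constant). Empty bins are masked, never ±inf sentinels. F is reported in
k_BT and kJ/mol (k_BT at 303 K = 2.5190 kJ/mol).

## RDF, coordination, hydration profiles

g(r) uses minimum-image distances on spherical shells; r_max must stay
below half the smallest box edge. The reference density defaults to
(mean partner count)/(box volume). In a confined pore this is **not** a
bulk density, so peak heights are comparable only within one analysis;
pass `reference_density` to normalize against a bulk value. The running
coordination number is computed by direct counting (mean partners within
r), not by integrating g(r), so it is independent of binning and of the
reference density. An optional conditioning window restricts samples to
frames where the central ion sits in a z interval (default width when
studying a single site: ±1 Å around the site, configurable) — this is how
site-resolved hydration is obtained from a permeation trajectory.

Coordination counts use a closed boundary (a partner exactly at the
cutoff counts). The default first-shell cutoff is 3.2 Å, chosen in the
first-minimum region beyond the ~2.4 Å Ca–O peak. Hydration profiles
report mean ± sd of water-oxygen counts and of distinct protein residues
(distinct molecule_ids with ≥1 oxygen within the cutoff) per z bin.

## Density-difference charge transfer

Δϱ = ϱ_complex − ϱ_ion − ϱ_shell is formed voxel-wise on three congruent
grids (origin, voxel vectors and shape must agree to 10⁻⁶ Å; no
resampling is attempted, which avoids silent quadrature bias). Each voxel
center is assigned to its nearest atom (Euclidean; exact ties to the
lowest atom id), making the Voronoi partition exhaustive and exclusive:
per-atom integrals sum to the total grid integral by construction.
Electron gains are positive; the ion's effective charge is
nominal − Δn_e(ion); per-water loss is the negative of the water
molecule's summed Δn_e. Multi-snapshot input averages per-element values
and reports the standard deviation across snapshots.

## Localized-orbital centers and dipoles

Centers within 1.2 Å of an oxygen belong to that water; a center is an
O–H bond center when the O→center direction lies within 35° of an O→H
bond, otherwise a lone pair. Both thresholds are configurable; the
defaults come from typical water localized-orbital geometry (bond centers
~0.5 Å from O along the bond, lone pairs ~0.3 Å off the back of the
oxygen) and are validated against the backend's own localized orbitals.
Shifts between two states at identical water geometry are projected
displacements: lone pairs on the O→ion unit vector (positive toward the
ion), bond centers on the H→O unit vector (positive toward the oxygen);
bond centers are matched through their hydrogen, lone pairs by
closest-distance pairing within the molecule. Molecular dipoles use the
pseudopotential-style valence model (O +6, H +1, four centers of −2 e),
which is net neutral, hence origin-independent.

## The Hartree–Fock backend

No quantum-chemistry engine is part of the runtime environment, so the
package carries a minimal restricted Hartree–Fock implementation used by
the charge-transfer pipeline: Cartesian Gaussian integrals by the
McMurchie–Davidson scheme (Hermite expansion + Boys-function Coulomb
recursion, numba-compiled, Schwarz screening at shell-pair and
primitive-pair level), in-core electron repulsion stored as a dense
(pq|rs) pair supermatrix, DIIS-accelerated SCF with a core guess,
spherically averaged fractional occupations for open-shell atoms, Boys
localization by Jacobi 2×2 sweeps, and density evaluation on arbitrary
grids.

The basis (`pdzp`, shipped as package data and regenerable by
`scripts/build_basis.py`) is a double-zeta-plus-polarization set built by
the package itself: even-tempered primitives optimized variationally
(H against the exact one-electron atom, O against closed-shell water,
Ca against closed-shell Ca²⁺), generally contracted with the atomic
orbital vectors (ANO style) plus one free diffuse function per angular
momentum, and fixed polarization exponents (O d 0.85, H p 0.80,
Ca d 1.0 and 0.25 as acceptor functions). Resulting quality markers:
H atom −0.4988 Ha (exact −0.5), water −76.036 Ha (HF basis-set limit
−76.067) with a dipole of 2.18 D (typical HF double-zeta value), water
valence localization into two bond centers at 0.52 Å and two lone pairs
at 0.30 Å whose point-charge dipole reproduces the SCF dipole to
0.003 D.

Correctness anchors: s-type integrals and the total energy match the
classic published minimal-basis H₂ values; p- and d-type overlap, dipole
and kinetic integrals match numerical quadrature with analytic orbital
gradients to ~10⁻¹⁰; nuclear attraction matches quadrature to the
midpoint-rule limit of the 1/r cusp; electron repulsion is
cross-validated against nuclear attraction through a point-charge
(tight-Gaussian) limit; the total energy is invariant under rigid
rotations, which exercises every angular-momentum path at once.

### Scaled-down electronic-structure conditions

The charge-transfer/center-shift reference computation is a gas-phase
Ca²⁺(H₂O)₇ cluster (22 atoms, 200 basis functions): oxygens on a
Thomson-problem spherical code at the 2.4 Å first-shell distance, water
dipoles oriented toward the ion, standard internal geometry
(r_OH 0.9572 Å, 104.52°). The three SCF states (complex, bare ion,
shell) are sampled on a 95³ grid of 0.15 Å spacing with a 7 Å half-width;
this spacing was fixed by internal convergence of the Voronoi integrals
(per-water transfer changes by <5·10⁻⁴ e between 0.20 and 0.15 Å, and
∫Δϱ ≈ 10⁻³ e). Note that the *individual* density integrals carry large
midpoint-rule error at the sharp O/Ca cores; these core contributions are
identical between the congruent grids and cancel in Δϱ, which is the
quantity integrated.

Production studies of this system use hybrid-DFT (B3LYP-level) QM regions
embedded in the full membrane-protein electrostatics and average over
many thermal snapshots. Relative to that, this backend (i) is
Hartree–Fock, which systematically *underestimates* intermolecular charge
transfer, and (ii) has no second hydration shell, H-bond acceptors or
protein field acting on the O–H bonds. Consequently, quantities dominated
by first-shell electrostatics and induction transfer well (effective ion
charge ≈ 1.9 e; coordinated-water dipole 2.8–2.9 D vs 1.8–1.9 D without
the ion; lone-pair centers shifting ~0.024 Å toward the ion; per-atom O
gain ~+0.1 e and H loss ~−0.06 e), while charge-transfer magnitude
(per-water donation ~0.012 e at HF vs ~0.03 e at hybrid-DFT-in-protein)
and O–H bond-center displacement (~0.029 Å vs ~0.06 Å with H-bonded
neighbors) come out roughly a factor of two small. Passing tests
demonstrate the pipeline's correctness on these conditions, not
quantitative transferability of HF gas-phase cluster values to embedded
hybrid-DFT ensembles.

## The Brownian pore simulator

Overdamped Langevin dynamics of point ions on the channel axis:
dz = βD·F·dt + √(2D·dt)·η with F the sum of Gaussian binding-site well
forces (−dU/dz with U = −Σ d_k·exp(−(z−z_k)²/2w²)), the constant field
force qV/L_z, and screened ion–ion repulsion U = (A/d)·exp(−d/λ) acting
along z with the full 3-D separation; x, y diffuse freely inside a
reflecting cylinder and z wraps periodically (reservoir recycling).
Euler–Maruyama is stable here when the per-step displacement sd stays
below a quarter of the well width; larger dt raises an error with the
admissible value.

Defaults emulate the published study conditions where stated — divalent
ions, 600 mV, 303 K, a ~70 Å box, four binding sites along the filter
and cavity — while the remaining magnitudes are the package's own
realistic choices: well depths 2–4 k_BT (permeation-compatible barriers),
well width 1.5 Å, confined diffusion coefficient 30 Å²/ns (about 40% of
the bulk Ca²⁺ value), screened repulsion A = 25 k_BT·Å with λ = 3 Å
(≈3 k_BT at contact, Debye-like screening at ~molar ionic strength), and
a 2 Å lateral cylinder making transport quasi-single-file as in a
selectivity filter. Single-file confinement matters: with a wide pore,
ions pass each other and the knock-on correlation disappears. The
knock-on signature is asserted as a correlation property — binned counts
of filter entries (full traversals of the lower half-span) and exits
(upper half-span) correlate positively under coupling (r ≈ 0.05–0.18)
and not without it (r ≈ 0) — never as a quantitative match.

What the generator does **not** emulate: explicit water and protein
(hydration/contact analyses use the cluster and ideal-gas generators
instead), the double-membrane charge-imbalance machinery (a constant
field stands in for it), ion-specific binding chemistry, and conductance
magnitudes of any real channel — the demo pore conducts ~10× more than
a real Ca²⁺-permeable receptor because its barriers are deliberately
shallow. Analyses validated on these trajectories are validated as
*algorithms*; conclusions about a real channel require real MD input.

## Problem sizes and determinism

Test-suite and acceptance runs use: detector suites on hand-built traces;
10⁶-step single-ion Langevin runs for flux/drift statistics (bounds set
at 3σ of the exact sampling distributions); 1000-partner/50-frame
ideal-gas RDFs; 81³–95³ density grids; the 22-atom cluster with 200 basis
functions for the electronic pipeline. Every random number flows from an
explicit seed (numpy Generator); the pipeline driver derives all stage
seeds from the single top-level seed, and rerunning a config reproduces
summary.json byte for byte. Voronoi ties, lone-pair matching and DIIS
give deterministic results at fixed input ordering.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* The RDF reference density in a pore is not bulk-normalized (documented
  above); peak *positions* are robust, peak *heights* are relative.
* The detector assumes ions move less than half a box per frame; heavily
  strided trajectories warn.
* The SCF is closed-shell (or spherically averaged) Hartree–Fock without
  electron correlation; see the scaled-down-conditions section for the
  systematic consequences. SCF convergence on strongly stretched or
  open-shell molecular systems is out of scope.
* `regrid`/resampling of non-congruent cube triplets is intentionally not
  provided; inputs must share one grid.
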