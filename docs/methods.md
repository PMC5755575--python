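# Methods

## Model

The thermally smeared electron density of the crystal is written as a sum of
atom-centred aspherical densities convolved with harmonic probability
densities for nuclear motion. A molecular electron density ρ(r) for a
chemically complete fragment (grown from the asymmetric unit) is partitioned
into stockholder atoms with weights w_A(r) = ρ⁰_A / Σ_B ρ⁰_B built from
spherical free-atom reference densities. Each Hirshfeld atom is Fourier
transformed, referenced to its nucleus,

    f_A(h) = ∫ w_A(r) ρ(r) exp(2πi h*·(r − R_A)) dV,

so that the refinable lattice phases stay in the structure-factor sum

    F(h) = k Σ_s Σ_A (occ_A / m_A) f_A(R_sᵀ h) T_A(R_sᵀ h)
           exp[2πi h·(R_s x_A + t_s)],

where s runs over the space-group operations, m_A is the order of the site
stabilizer (so special positions are not double counted), and
T(h) = exp(−2π² Σ_ij h_i h_j a*_i a*_j U^ij) is the Debye–Waller factor in
the CIF U convention. Because Hirshfeld atoms are aspherical, a symmetry
copy scatters with the rotated index R_sᵀh; form factors are evaluated once
on the closure of the unique reflection list under {R_sᵀ} and looked up
afterwards (one Friedel mate of each ±h pair is computed, the other is its
conjugate while no anomalous dispersion is applied).

Refinement minimises Σ_h w_h (|F_o| − k|F_c|)² with statistical weights
w = 1/σ²(F) — refinement is against |F|, not F². Parameters are fractional
coordinates, U^ij (six per anisotropic atom, one per isotropic atom) and a
single scale k. Derivatives of F with respect to all parameters are
analytic; |F| derivatives follow via Re(F̄/|F| · ∂F/∂p). Hydrogen ADPs are
refined freely and anisotropically by default; isotropic and fixed modes
are available.

The outer (HAR) iteration alternates: regrow the fragment from the current
coordinates, recompute the density and hence the form factors, then run the
inner least squares to convergence at frozen form factors. It stops when
max |shift/s.u.| < 0.01 (configurable) or the absolute shifts fall below
1e-6 Å / 1e-7 Å², with a 15-cycle cap and an oscillation guard.

## Free-atom reference densities

The spherical reference atoms (promolecule ingredients and IAM form
factors) are reconstructed analytically from the International Tables
four-Gaussian form-factor fits: a reciprocal-space Gaussian a·exp(−b s²)
inverts to the real-space Gaussian a (p/π)^{3/2} exp(−p r²) with
p = 4π²/b. The constant term of the fit is folded into a tight Gaussian
(b = 0.01 Å²) and the sum is renormalised to exactly Z electrons. Densities
are tabulated on a 600-point log mesh to 10 Å and evaluated through a cubic
spline of log ρ (relative interpolation error < 1e-6); the Gaussian
expansion itself remains available for closed-form Fourier transforms.
Coverage is H–Kr; heavier elements are refused because neglecting
relativistic effects would distort the reference density. The promolecule
reference is neutral by default (the conventional stockholder choice); a
charge-state switch exists for ionic crystals.

## Numerical integration

Hirshfeld form factors are integrated on atom-centred product grids:
Gauss–Chebyshev (second kind) radial nodes under Becke's r = R(1+x)/(1−x)
map (R from the covalent radius, 0.35 Å for H, truncated at 12 Å where the
truncation error is < 1e-8 even for a hydrogenic tail), crossed with a
Gauss–Legendre × uniform-φ spherical product grid, and combined with
Becke's smooth Voronoi partition (three smoothing iterations, no size
adjustment). Presets (radial × polar-angle counts): `test` 40×10,
`standard` 75×21, `fine` 120×29. The angular order is what limits the
accuracy of the oscillatory Fourier integrand; at `standard` the
form-factor error is ≲ 1e-5 e up to 1.4 Å⁻¹ on Gaussian test atoms, and at
150×29 the quadrature reproduces closed-form Gaussian form factors to
better than 1e-6 e (the analytic-oracle test). Plane-wave phases are
assembled from per-axis integer-power tables (exp(2πi u_j)^{h_j}) so the
per-atom sums reduce to one BLAS matrix product per reflection block.

A density provider may advertise closed-form factors
(`analytic_form_factors` + `form_factor_for_site`); the engine then uses
them directly, which makes the synthetic models exact and fast. The
quadrature path can always be forced (`force_quadrature=True`) and is what
a numerical SCF backend would exercise.

## Constraints and degeneracies

* Special positions: the stabilizer of a site defines projectors on the
  coordinate shifts (mean of the rotation matrices) and on the U six-vector
  (mean of the congruence action in the scaled crystal basis); refinement
  proceeds in the null space of the violated directions, so constrained
  components receive exactly zero shift.
* Floating origins: directions fixed by every rotation part of the space
  group are polar; along each the occupancy-weighted centre of the
  heaviest-element atoms is held fixed. With |F|-only data the absolute
  origin along a polar axis is unobservable, so refined coordinates in
  polar groups are compared through distances, not absolute positions.
* Non-positive-definite U during refinement is eigenvalue-clamped at
  1e-5 Å² in the Cartesian frame with a warning; a final clamped ADP is a
  quality flag.
* Step control: Gauss–Newton shifts are capped at 0.1 Å / 0.02 Å² per
  cycle and a step is halved (up to five times) whenever it would increase
  wR2, keeping the inner iteration monotone. A shift/s.u.-proportional
  damping was rejected because s.u.s are vanishingly small on noise-free
  synthetic data and would stall the iteration.
* Standard uncertainties come from the inverse reduced normal matrix scaled
  by the goodness of fit.

## Crystal-field environment

With a positive cluster radius, whole molecules (symmetry images of the
connected components of the asymmetric unit) having any atom within the
radius of the fragment are enumerated; `charges_dipoles` places each
neighbour atom's Hirshfeld charge and (rotation-transformed) dipole at its
site, `explicit_cluster` returns the atoms themselves for the density
calculation. Charges and dipoles are iterated with the density to
self-consistency (max |Δq| and |Δμ| < 1e-3, at most 10 cycles). Radius
zero disables the environment. The bundled analytic providers do not
respond to the field (they have no SCF), so their self-consistency loop
terminates after one refresh; the machinery is in place for backends that
do.

## Synthetic study conditions

The synthetic module is the package's experimental bench: Gaussian-atom
crystals whose shells default to the element's free-atom Gaussian
expansion, so the spherical limit of a toy atom is exactly its IAM atom and
every structure factor has a closed form (evaluated independently of the
engine as a direct Cartesian sum over symmetry copies and shells — the
oracle chain).

* `diatomic_P1` — a C/O pair (bond 1.22 Å) in a triclinic P-1 cell;
  the recovery and calibration workhorse.
* `polar_XH_P1` — an O–H pair (0.97 Å) in P-1 with the entire hydrogen
  density displaced 0.10 Å towards O, a minimal surrogate for the bond
  density that makes spherical refinements foreshorten X—H bonds by about
  0.1 Å. Because the displacement is a pure translation of the H density,
  the spherical fit relocates the hydrogen to the density centroid and the
  foreshortening equals 0.100 Å exactly, inside the 0.08–0.12 Å band
  expected of the effect.
* `mirror_site_Pm` — a water-like molecule across a mirror (Z′ = ½):
  exercises fragment completion through a special position, site-symmetry
  constraints (Δy = 0, U12 = U23 = 0 on the mirror atom) and the
  floating-origin fix of a polar group.
* `one_atom_P1`, `ionic_P1` — minimal cells for oracle and environment
  tests (the ionic pair carries 18/10 electrons on K/F-shaped shells, so
  Hirshfeld charges of ±1 and a neutral 8 Å cluster emerge).

Simulated data carry |F_obs| = |F_true|(1 + ε), ε ~ N(0, noise²),
σ = noise·|F_true| with an absolute floor of 1e-4 × rms|F|. The floor (and
not a per-reflection relative one) matters: relative floors give
near-extinct reflections unbounded weights and create spurious least-squares
minima. Refinement itself contains no randomness; seeds live only in the
synthetic module. Default problem sizes (resolution 0.8 Å⁻¹, ~1.5–3.6×10³
unique reflections for ~19 parameters) keep each refinement under a second
with analytic providers, and the full acceptance run under a minute.

What the synthetic conditions do *not* emulate: SCF densities responding to
geometry and environment, absorption/extinction/TDS errors, disorder, twin
laws. Passing tests therefore demonstrate the correctness of the
partitioning, Fourier, symmetry, least-squares and statistics machinery —
not the physics of a particular quantum-chemical level of theory. No SCF
backend is bundled; real-data HAR requires plugging one into the provider
contract.

## Validation statistics

R1, wR2 and GOF follow the standard definitions on |F|. Residual maps are
difference Fourier syntheses with model phases on an FFT grid (≤ 0.3 Å
step, no (000) term, hence zero mean). The fractal-dimension curve df(ρ0)
box-counts the iso-surface of the residual map — the voxels whose periodic
2×2×2 corner cube brackets the level — at decimations 1, 2, 4, 8 over 101
uniform levels; a thin value-shell membership was tried first and saturates
well below the surface dimension on desk-scale maps, whereas the
iso-surface construction yields the expected df(0) ≈ 3 parabola on white
noise. The ADP comparison reports ⟨U^ii_X/U^ii_N⟩, ⟨|ΔU^ii|⟩, ⟨|ΔU^ij|⟩
(i≠j) with sample standard deviations, pooled over components by default
(per-atom averaging first is available; the two orders differ only in the
weighting of atoms with anisotropic spreads), computed on the deposited
crystal-basis U^ij by default with a Cartesian option. wRMSD divides each
difference by the combined standard uncertainty sqrt(σ²_X + σ²_N); 1 means
statistical agreement. The rigid-bond test projects both Cartesian U
tensors on the unit bond vector and reports Δ = z²_A − z²_B per bond class;
rigid-body (TLS) displacement fields satisfy it to numerical precision, and
values below 0.001 Å² are the conventional pass for bonds between non-H
atoms.

## Known limitations

* No extinction correction, no refinement against F², no anharmonic
  motion, no twinning, no restraints.
* Occupancies are carried but never refined.
* H–Kr only; no relativistic reference densities, no effective core
  potentials (they lack the core density HAR needs).
* The hkl F vs F² dialect cannot be auto-detected (SHELX HKLF 3 and 4
  records are byte-identical); only fixed- vs free-format layout is
  detected, the dialect is an explicit argument.
* The CLI's `har` command falls back to the promolecule provider, which by
  construction reproduces the IAM result; aspherical refinement of real
  data needs an external density backend.
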