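# Methods

This note documents the physical model, the numerical choices, and what the
validation systems do and do not demonstrate.

## Units and constants

Lengths are nm, times ns, energies kJ/mol; hence forces kJ/(mol·nm),
pressures kJ/(mol·nm³), diffusion coefficients nm²/ns and viscosities
kJ·ns/(mol·nm³). The Boltzmann constant is the molar
k_B = 0.008314462 kJ/(mol·K); the default temperature is 293.15 K
(kT ≈ 2.437 kJ/mol). The default solvent viscosity is water at 20 °C,
1.0 mPa·s. Converting 1 Pa·s = 1 J·s/m³ into molar simulation units
multiplies by 6.02214076 × 10²⁰ (J → kJ/mol), 10⁹ (s → ns) and divides by
10²⁷ (m³ → nm³), giving 1 mPa·s ≡ 0.60221 kJ·ns/(mol·nm³). Sanity check: a
1 nm-radius sphere then has D = kT/(6πηr) ≈ 0.215 nm²/ns, the physical
value.

## Rigid-bead hydrodynamics

A molecule type is a rigid set of beads (radii aᵢ, positions rᵢ) plus
optional zero-size interaction patches. Its diffusion tensors are computed
once at definition time:

1. The 3N×3N translational mobility supermatrix has Stokes self-blocks
   I/(6πηaᵢ) and pairwise Rotne–Prager–Yamakawa blocks for unequal radii;
   overlapping beads (|rᵢⱼ| < aᵢ+aⱼ) use the regularized overlap form of Zuk
   et al., which reduces to the classical equal-radii RPY overlap expression.
   A bead fully contained in another is rejected as degenerate.
2. The supermatrix is inverted to the friction supermatrix and contracted
   with the rigid-body kinematic map (uᵢ = v + ω×rᵢ) to the 6×6 friction
   tensor at the working origin. The rotational block receives the volume
   correction Σᵢ 8πηaᵢ³·I — each bead's own rotational resistance, which the
   translational supermatrix cannot see; this makes the single-bead rotational
   diffusion exactly kT/(8πηa³).
3. D₆ = kT·Ξ₆⁻¹. The origin is then shifted to the **center of diffusion**,
   the unique point at which the translation–rotation coupling block of the
   diffusion tensor is symmetric, obtained from
   (Tr(D_rr)·I − D_rr)·r_CD = axial(D_tr − D_trᵀ), and the tensors are
   recomputed there. For symmetric bodies this point coincides with the
   geometric center. Bead coordinates are stored re-centered on it, because
   it is both the correct point to propagate and the correct reference for
   the rigid-body virial.

Translation–rotation coupling (D_tr) is computed and stored but not used by
the propagator: for the nearly axisymmetric bead models this package targets
its effect on trajectories is far below sampling noise, and dropping it keeps
the propagator a pair of independent 3×3 Cholesky draws. Species may instead
be declared with a direct scalar diffusion coefficient (`diffusion_constant`),
in which case the rotational tensor follows from the implied hydrodynamic
radius.

## Propagation

First-order Euler–Maruyama in the body frame, per step of length Δt:

- translation: Δx_b = (D_tt F_b / kT)Δt + L_t ξ, with L_t L_tᵀ = 2 D_tt Δt,
  rotated to the world frame;
- rotation: a body-frame rotation vector Δφ_b = (D_rr T_b / kT)Δt + L_r ξ,
  applied as q ← q ⊗ δq(Δφ_b) and renormalized (norm preserved to 1e−9 per
  step). Rotation noise is sampled in the body frame; for anisotropic D_rr
  this is the frame in which the covariance is stationary.

Randomness comes from one counter-based Philox stream per run; per-step noise
is drawn in ascending external-molecule-id order, so a fixed seed reproduces
trajectories bit-for-bit. Molecule ids are monotonically issued and never
reused within a run.

One simulation step is ordered as: (1) propagate all molecules and apply
boundary handling; (2) a single sweep over the neighbor-list particle pairs
accumulates forces, torques, the pair virial, and the Doi bimolecular event
list; (3) due Gillespie timers append unimolecular events; (4) events execute
in uniformly random order. Forces are **not** recomputed after reactions —
products first feel forces on the next sweep — except binding bonds, whose
force is evaluated at execution. An event whose educt was consumed (or has
already reacted) in the same step is invalidated; this is the conflict policy
that enforces at most one reaction per molecule per step.

## Interactions and pressure

Potentials act between particle types through the two-function contract
(U(r), dU/dr); built-ins are harmonic repulsion (C¹ at σ), the weak piecewise
harmonic well, a cut-shifted continuous square well, and the Mie-50/49 pseudo
hard sphere. Bead forces map to molecule force and torque about the center of
diffusion. The virial pressure is

P = (N kT + W/3)/V,  W = Σ_pairs r_ij·F_ij,

with r_ij the **molecule-center** (center-of-diffusion) separation — the
molecular virial convention required for rigid bodies in Brownian dynamics.
External-potential virial terms are not included (only pair terms plus the
ideal part); none of the validation systems use external potentials.

## Neighbor search

The hierarchical grid keeps one linked-cell level per distinct cutoff
diameter (capped at 8 levels, geometric binning beyond), with cells at least
as large as the level's largest cutoff. Particles pair if
r < (cᵢ + cⱼ)/2 — the arithmetic-mean mixing rule, which for excluded volume
(cᵢ = 2rᵢ) is the contact distance rᵢ + rⱼ. Same-level sweeps scan
nearest-neighbor cells; cross-level sweeps scan only smaller-cell levels from
each coarser particle, so each unordered pair is produced exactly once. Cells
are rebuilt every step (no Verlet skin). Per-particle cutoffs are the maximum
of the interaction cutoffs and bimolecular reaction radii involving that
particle type, so one sweep serves both forces and reactions.

## Mesh compartments

Compartments are closed triangulated manifolds (every edge shared by exactly
two triangles, consistent counterclockwise winding) kept in a shared-vertex
structure with per-triangle edge and neighbor arrays, plus a voxel grid over
the bounding box for ray queries. Geometric kernels: barycentric
point-in-triangle (closed convention, tolerance 1e−9), Eberly's region-based
point–triangle distance, Möller–Trumbore ray–triangle intersection, and
Amanatides–Woo voxel traversal with early exit once the entry parameter
passes the best hit.

Volume molecules of small isotropic species resolve mesh collisions by ray
tracing with mirror reflection — pure geometry, independent of Δt, capped at
50 reflections. Large bead molecules may instead use contact forces via
point–triangle distance (per-type flag). Surface-bound molecules move by
**surface ray marching**: the in-plane displacement is advanced to the first
crossed edge (smallest positive edge-line parameter against the outward edge
normals), the residual is rotated about the shared edge into the neighbor's
plane, and the molecule's quaternion is rotated identically; iterating until
the target lies in the current triangle yields a geodesic of exactly the
commanded arc length. Displacements numerically on an edge are nudged toward
the triangle interior by a relative 1e−9 — the measure-zero vertex case must
not crash.

## Boundaries

Periodic boxes wrap positions half-open into [0, L) and use the minimum
image for separations (ties at +L/2 map to −L/2). Repulsive boxes mirror-fold
positions at the faces. Fixed-concentration boundaries remove any molecule
crossing the box and Poisson-inject new ones at rate N_hit = A·(l_n/2)·C per
species and step, where l_n = √(4DΔt/π) is the mean one-sided normal
displacement; insertion faces are chosen by area, in-face coordinates
uniformly, and the inward depth is √π·l_n·x̃ with x̃ drawn by inverse
transform from P(x̃) = 1 − exp(−x̃²) + √π·x̃·erfc(x̃) on a 4096-knot monotone
interpolant (density √π·erfc(x̃) ≥ 0). Insertions are not collision-resolved
against nearby meshes; the interior concentration equals the outside pool
concentration only for non-interacting species. Compartment meshes
intersecting the box boundary (absorbing/re-emitting "transparent" faces)
are not supported; meshes are closed confining volumes.

## Reactions

Unimolecular: each molecule stores the time of its next reaction, drawn once
from τ = ln(1/U)/k_t with k_t the sum of all its open path rates (molecule-
level channels of its type plus particle-level channels of its particles);
the timer is re-drawn whenever the channel set changes (conversion, particle
retyping, production/release execution). The executed path is chosen with
probability kᵢ/k_t. Product placement conventions: fission splits the educt
symmetrically, products at ±R/2 along a uniform random direction (separation
equal to the dissociation radius); production places each product on the
sphere of the emission radius; release puts the released molecule at the
emitting particle's position plus R times a random direction and optionally
retypes the particle; particle-level decay retypes the particle to the inert
`void` type (rigid geometry cannot lose a bead). Fusion products take the
midpoint of the reacting particle pair and the first educt's orientation.

Bimolecular: for each in-range educt pair the firing probability is
p = 1 − exp(−Σᵢ kᵢΔt) summed over the paths whose own radius covers the
current distance; on success the path is chosen ∝ kᵢ among those applicable.
Binding creates a harmonic bond with rest length equal to the formation
distance and user stiffness; unbinding is a per-bond exponential process.
Detailed balance for reversible reactions is not enforced. Surface reactions
use Euclidean, not geodesic, distances.

## Berendsen barostat

μ = (1 − (Δt/τ_P)(P0 − P))^(1/3) scales the box and the molecule centers
each step once t ≥ start_time; internal bead geometry is rigid and never
scaled. P is the instantaneous virial pressure. The scheme targets density
efficiently but underestimates pressure fluctuations (it is not a correct-
ensemble barostat); only isotropic coupling is implemented.

## Placement

- Poisson-disc (Bridson-style, polydisperse): candidates are drawn uniformly
  from the spherical annulus [d, 2d] around a random active point
  (volume-uniform radii, d = r_active + r_new), accepted if no existing
  sphere is closer than rᵢ + rⱼ, with k = 30 trials before retiring a point.
  Run to saturation this yields ≈30% volume fraction for monodisperse
  spheres — the practical density limit of the method. Stopped early via
  `max_n`, the accepted set is a connected patch around the seed point, not
  a uniform fill; use the dense packer for equilibrated starting states.
- Dense packing: random insertion, then position-based steepest-descent
  relaxation of harmonic overlaps (each overlapping pair separates along its
  center line by 0.55 × overlap per sweep) until every pair satisfies
  r ≥ (1−10⁻³)(rᵢ+rⱼ). The two-component benchmark (45 spheres of 10 nm +
  475 of 2.5 nm in a 75 nm box, a 52.05% nominal volume fraction) converges
  in a few hundred sweeps.
- Surface sampling: triangles area-weighted, square-root barycentric
  transform within a triangle, optional minimum Euclidean distance enforced
  by a spatial hash (cell edge d/√3, ±2-cell scan), optional face-group
  restriction.

## Observables

MSD is time- and ensemble-averaged on unwrapped coordinates over molecules
present in every frame; standard errors treat each molecule's time average
as one sample (walkers sharing time origins are correlated, so these are
slightly optimistic at long lags). The rotational correlation
P(τ) = (3/2)⟨(n(t+τ)·n(t))²⟩ − 1/2 uses a chosen body axis rotated to the
world frame; it is invariant under n → −n and decays as exp(−6 D_r τ) for
isotropic rotors. The RDF is the shell-normalized pair histogram with
minimum-image distances, valid up to half the box.

## Validation systems and problem sizes

The reference systems in `ridsim.systems` fix the study conditions:

- **Hard-sphere fluid**: 1 nm diameter, η = 0.3, D = 0.0859 nm²/ns,
  harmonic repulsion. For the structure/pressure checks the spring constant
  is k = 20000 kJ/(mol·nm²) with Δt = 4×10⁻⁴ ns: by the Barker–Henderson
  map the effective hard-sphere diameter is d_eff = σ − ½√(2πkT/k) ≈ 0.986σ,
  so the Percus–Yevick contact value and Carnahan–Starling pressure at
  η = 0.3 apply within a few percent (the tests use 10% bands to absorb the
  residual softness); the stability parameter DkΔt/kT ≈ 0.28. Runs use
  N = 400, ~1 ns equilibration and ~1.6 ns sampling.
- **NPT run**: same fluid with k = 100, Δt = 0.1 ns, barostat
  (P0 = 10 kJ/(mol·nm³), τ_P = 2.5 ns) on at 0.5 ns; N = 300–350, 150 ns
  total, pressure averaged over the final third. The feedback drives the
  pressure to P0 regardless of the potential's softness; softness only sets
  the equilibrium density reached.
- **Surface diffusion**: 1000 non-interacting walkers on an icosphere
  (radius 150 nm, 1280 faces) with D = 0.043 nm²/ns = 43 nm²/μs and
  Δt = 10 ns; ensemble MSD over the first six lags, slope/4. At these scales
  the sphere-curvature correction to the Euclidean MSD (~Dτ/R²) is ≪ 0.1%.
- **Poisson-disc saturation**: radius-1 spheres, 50 nm periodic box, k = 30,
  10 seeds; measured mean saturation ≈ 30.1%.
- **Binary packing**: the 45 + 475 composition above; the test suite runs a
  13 + 162 scaled variant in a 50 nm box at the same 52% fraction.

These systems are synthetic by construction: ideal (or harmonically
repulsive) spheres with exactly known diffusion coefficients, perfectly
closed meshes and exact rate constants. Passing them demonstrates that the
propagator, reaction sampler, neighbor search, geometry kernels, barostat
and estimators implement their mathematics correctly — not that any
particular biological parameterization is realistic; real systems add force-
field error, flexible molecules and hydrodynamic coupling, all outside this
model class (inter-molecule hydrodynamic interactions are deliberately not
computed; the 6N×6N problem would be rebuilt every step).

## Known limitations

- No angular (three-body) or torsion potentials; pairwise interactions only.
- No long-range electrostatics (no Ewald).
- Berendsen barostat does not sample the exact NPT ensemble.
- Surface reactions use Euclidean distances, a small error where reaction
  radii approach the local curvature radius.
- Fixed-concentration influx ignores collisions during insertion and
  supports box faces, not transparent mesh faces.
- Product placement does not resolve collisions; dense reactive systems need
  smaller time steps.
- Rate-based conversion (k_macro) uses translational diffusion of the
  molecule centers only; for strongly anisotropic reaction volumes the
  mapping is approximate.
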