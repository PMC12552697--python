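# Methods

This note records the models implemented in `sgbr`, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do
not establish about real data.

## Scaffold geometry

TPMS architectures are implicit level sets sampled at voxel centres:
gyroid `sin X cos Y + sin Y cos Z + sin Z cos X`, Schwarz P
`cos X + cos Y + cos Z`, with `(X,Y,Z) = 2π/L · (x,y,z)` and `L` the unit
cell size in mm. The solid phase is the sub-level set `{f ≤ t}` — the
network (single) gyroid; sheet-type variants are out of scope. The
iso-level is found by bisection on the voxel solid fraction (default
tolerance 10⁻³, 60-iteration cap). On coarse grids the attainable
fraction is quantized by voxel counts; the calibrator then returns the
bracket midpoint, which is within one quantization block of the target.

Pore size follows the largest-sphere definition: twice the maximum of the
Euclidean distance transform of the void phase, restricted to the void
component that percolates the cell, computed periodically by evaluating
the transform on a 3× tiling. For non-periodic masks the domain exterior
counts as solid (the sphere must fit inside the specimen). Strut size is
twice the minimum of the solid-phase distance transform over the solid
skeleton — the local thickness at the thinnest load path. Both metrics
converge as the grid refines (successive halvings change them by less
than the coarser spacing); they carry the intrinsic half-voxel
uncertainty of voxel-centre distances.

The measured pore size of the 3.5 mm / 50% gyroid (≈1.6 mm) matches the
design value, but the design pore size is treated as an input, not a
validation target: CAD kernels measure pores differently than the
distance-transform definition used here.

The BCC lattice joins cube corners to body centres in each 1.875 mm cell,
rotated about the build (z) axis. Beams are capsules of the specified
thickness, voxelized by exact point-segment distance. Warping — the
treatment of cells near an organic envelope — projects beam endpoints
that fall outside, or graze within one beam radius of, the envelope onto
the nearest surface voxel, so no beam terminates free in space; beams
with both endpoints outside the envelope are dropped. This realizes the
design intent (morphing boundary cells onto the surface) with a specific,
simple algorithm; the rendered boundary layer is therefore not identical
to any particular lattice-CAD package.

## Voxel finite elements

Every solid voxel is a trilinear 8-node hexahedron (2×2×2 Gauss
quadrature); materials are isotropic linear elastic, with an optional
per-voxel 6×6 elasticity field used by the macroscale growth model. This
is a deliberate divergence from tetrahedral meshing of real anatomy: on
structured phantom grids the continuum model is identical and the
structured form keeps assembly exact and fast. Systems are solved
directly (SuperLU, minimum-degree ordering) up to 80 000 free dofs and by
Jacobi-preconditioned conjugate gradients (relative residual 10⁻⁸)
beyond; element ordering is deterministic, so repeated runs are
bit-stable. Loads are distributed with trilinear-consistent face weights
(a uniform traction is reproduced exactly); Dirichlet patches may fix any
subset of components, on voxel corners or a single face plane. A
connected-component check rejects material islands whose constraint set
does not span all three directions, naming the island.

Interfaces between label pairs: **bonded** is the voxel-grid default
(shared nodes); **excluded** removes a material from the system entirely;
**frictional(μ)** duplicates the interface nodes of one side and couples
the pairs by penalty springs — normal springs act only in compression
(active-set iteration on the gap sign), tangential springs are capped at
μ times the normal pressure by a fixed-point scale update, and open pairs
retain a 10⁻⁸-relative regularization spring so the system stays
definite. The penalty stiffness is 100× the axial stiffness of the
stiffer neighbouring element. This is a simplification of true contact
(no large sliding, no geometric update); the package asserts only its
ordering and sign contracts (zero tensile transmission, bonded stiffer
than frictional), not contact-pressure distributions.

Fracture uses the maximum-principal-stress initiation ratio
`f = σ₁/σ_max` with strict exceedance and no compressive initiation.
Propagation is sequential element erosion: at a given load, the element
with the largest `f > 1` is removed and the system re-solved until no
element exceeds; over a strictly increasing load schedule, failure is the
first level where erosion does not arrest — the crack disconnects load
from support (checked by connected components), the system goes singular,
or the erosion budget (default 30% of the solid) is spent — refined by
bisection to 1% of the schedule span. A toughness surrogate limits the
allowable stress at crack-tip neighbours to
`min(σ_max, K_Ic/√(π·h/2))` with `h` the element size: an
element-size-scaled strength, standard for erosion-type fracture
surrogates, not an enriched-basis crack model. Crack paths are therefore
meaningful at the level of location and ordering, not tip fields.

## Homogenization

Unit cells are periodic by construction, so periodic boundary conditions
are used (not kinematic-uniform): displacements split into an affine part
from the macroscopic strain plus a periodic fluctuation, the fluctuation
solved per strain case with one node pinned; volume-averaged stress
assembles the effective tensor column by column. One factorization is
shared by all six strain cases; a homogeneous cell short-circuits (zero
fluctuation exactly). The void phase carries 10⁻⁶ of the stiffest
constituent's modulus to keep the system definite; effective diffusivity
uses the scalar analogue with three gradient cases.

Bone infill: the fill fraction of the void is linear in density,
`φ = (ρ − 0.05)/(1.62 − 0.05)` with 1.62 g/cm³ fully mineralized bone at
modulus 12 000 MPa (no separate immature-bone law; partially formed bone
differs only in how much of the cell it occupies). Deposition is
**conformal** — void voxels fill in increasing order of periodic distance
from the scaffold surface, ties broken lexicographically — because bone
apposes on scaffold walls; a uniform-random mode exists for comparison.
The diffusive phase of the effective diffusivity is the **new-bone**
phase: the model treats osteoblast migration as proceeding along
deposited matrix, which makes both stiffness and diffusivity monotone in
density. The macroscale transport adds a small baseline diffusivity for
the unfilled pore space (below).

Laminate verification note: with equal Poisson ratios and unequal
moduli, the exact across-layer engineering modulus of a bilayer exceeds
the harmonic (Reuss) mean because in-plane strains must match across the
interface; the test suite checks the Voigt/Reuss closed forms at ν = 0
(where they are exact) and the full bilayer closed form at ν = 0.3, and
keeps Reuss ≤ E ≤ Voigt as a variational bound everywhere.

## Ingrowth model

State per macro cell (one cell per 3.5 mm scaffold unit cell): bone
density ρ clamped to the table range [0.05, 1.62] g/cm³ and normalized
osteoblast concentration λ ∈ [0, 1]. Step order: (1) macroscale
elasticity with per-cell `C_eff(ρ)` and the scenario's ceramic-lattice
coupling (removed / frictional / tied); the stimulus ψ is the von Mises
norm of the homogenized Cauchy stress — chosen for frame invariance and
consistency with von Mises reporting of the stress analyses; (2) implicit
(backward-Euler) finite-volume diffusion of λ with harmonic-mean face
conductances, λ = 1 clamped on scaffold cells face-adjacent to host bone,
zero flux elsewhere — unconditionally stable, obeys the discrete maximum
principle; (3) explicit Euler density update by the lazy-zone law,
clamped to the table range; (4) mass bookkeeping
(`Σ (ρ − ρ_baseline) · cell volume`, mm³→cm³, plus volumes above 0.3 /
0.5 / 0.8 g/cm³).

Parameters with no established values, fixed once as the package's
reference conditions and exposed in `GrowthConfig`:

* **Reference stimulus ψ̄** — 20% of the peak initial interface stimulus,
  with lazy zone `l = 0.1 ψ̄`, calibrated at t = 0 per run. Understimulated
  cells never grow (one-sided law, no resorption).
* **Load** — mastication is intermittent; the reference run uses a 45 N
  static-equivalent downforce (≈10% duty of a 450 N peak premolar
  clench). With the deposition constant `c_s = 0.6` in (g/cm³)/(MPa·week),
  this puts the supra-threshold stimulus at order 1 MPa and deposition at
  the weeks scale on which bone actually fills a pore volume. The full
  450 N is used for the stress/fracture analyses.
* **Osteoblast motility D₀ = 50 mm²/week**, scaled by the cell-level
  relative diffusivity, plus a **baseline relative diffusivity of 0.02**
  for the unfilled pore space (granulation tissue): together these set a
  migration front that reaches the defect interior over several weeks and
  lets deposition bridge the 60 mm defect by week 24 — the
  interface-first-then-bridging chronology.
* **dt = 0.5 week** over 24 weeks, density maps kept at weeks
  {6, 10, 18, 24} (nearest whole step). At these rates the explicit
  density update is in its convergent regime: halving dt changes the
  week-24 mass by ≈0.4%.

The ceramic-lattice cells, when mechanically present, carry an isotropic
effective modulus of 3000 MPa (≈20% volume-weighted fraction of the
15 000 MPa ceramic — the open-lattice dilution); transport is unaffected
by the lattice scenario.

## Micro-CT volumetry

Scanner units; 50 µm grid. Median filter (default radius 1 voxel,
configurable; radius 0 skips it for noise-free input). New bone is the
window [1800, 5300); the ceramic is ≥ 5300 — the boundary value belongs
to the ceramic, since its threshold is defined as "and above" while the
bone window's upper end is unspecified. The ceramic mask underestimates
strut thickness (partial volume), so it is dilated by a Euclidean ball of
+200 µm (radius in voxels rounded nearest, ties to even; a sub-half-voxel
offset warns and does nothing) before Boolean subtraction from the bone
mask, together with the native-bone mask. The remainder is partitioned by
envelope membership — lattice envelope first, then frame, remainder
"outside" — so the three region volumes sum exactly to the total. In the
phantom pipeline all masks are exactly co-registered by construction;
rigid registration of real scans is out of scope.

## Synthetic phantoms — what they do and do not show

The mechanics/growth phantom is a rectangular bone bar (130 mm, 17.5 mm
square section) with a centred 60 mm defect: the defect cross-section's
outer shell is homogenized gyroid frame, the core is the ceramic-lattice
envelope; the posterior end face is fixed (condylar immobilisation) and a
downforce acts on the anterior top surface (premolar loading). The CT
phantom resolves actual gyroid and BCC geometry at 50 µm in a small patch
with ellipsoidal new-bone deposits — a third apposed to (tangent to)
lattice beams so the ceramic halo geometry is exercised, the rest clear
of the offset band, consistent with bone in the lattice forming discrete
islands. CT emulation maps labels to intensities (new bone 3000, ceramic
6500, polymer 900 — radiolucent, below the bone window), blurs with a
50 µm Gaussian point spread, and adds white noise (SD 150).

Everything is a pure function of (spec, seed): identical inputs are
byte-identical. These phantoms omit anatomical curvature, teeth,
cortical/trabecular distinction, scanner beam hardening and scatter; all
claims asserted on them are ordering and property claims (where bone
forms first, which interface is stiffer, that volumes are conserved),
not predictions of subject-specific magnitudes. Passing tests show the
machinery is self-consistent and matches its closed-form and brute-force
oracles at phantom scale — not that a particular animal's bone mass or
failure load would be reproduced.

## Numerical conventions

Axis order (x, y, z) with x fastest; voxel centres at
`origin + (i + ½)·spacing`; 0-based indices; lengths mm, moduli and
stresses MPa, densities g/cm³ with explicit mm³↔cm³ conversion (×10⁻³),
time in weeks. Stress Voigt order is (xx, yy, zz, yz, xz, xy) with
engineering shear. Problem sizes in the shipped tests and examples —
12³-voxel homogenization cells, a 37×5×5-cell growth phantom, 120³-voxel
CT patches — are chosen so the whole suite runs on a laptop core in
minutes; every resolution is a parameter, and the convergence tests
(Richardson metrics, dt halving, grid refinement oracles) document how
results move as they grow.

## Known limitations

* Erosion fracture has no crack-face contact, no fatigue, no geometric
  nonlinearity; failure loads bracket, not resolve, the instability.
* Frictional contact is penalty-based with axis-aligned interface
  normals; no large sliding.
* The deposition law is one-sided (no resorption) and single-load-case
  per step; masticatory cycling enters only through the static-equivalent
  load magnitude.
* The density→microstructure rule inside unit cells (conformal layer) is
  a modelling choice; the literature underdetermines it.
* Thresholds (1800/5300) are raw reconstruction values, scanner-specific,
  and exposed in the configuration rather than hard-wired into analyses.
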