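# Methods

## Scope and geometry idealization

The pipeline models magnetophoretic guidance of inhaled magnetite
microparticles toward the olfactory epithelium. Anatomy is replaced by a
**2-D sagittal surrogate**: an n-shaped channel in the (y, z) plane
(y anterior→posterior, z inferior→superior, SI units) with a nostril inlet
at the bottom anterior, a vestibule limb rising past a filleted bend, a
main passage under the roof, and a narrower nasopharynx limb descending to
the outlet. The olfactory region is a single segment on the superior roof
sized to a prescribed fraction (default 8 %) of the total wall length,
matching the olfactory share of the real nasal surface.

Why 2-D: the quantities of interest (trajectories, wall capture, regional
deposition) are conventionally presented in the sagittal plane, and the
magnet force field varies smoothly across the narrow airway width. All
forces are computed with full 3-D formulas evaluated in the plane
x = dx (the release line's sagittal offset from the septum, 2.5–3 mm per
protocol, with the magnets at x = −5 mm on the far side); the x-component
of motion is dropped.

Default dimensions: passage 0.07 × 0.05 m, vestibule/inlet width 0.01 m —
chosen so the 2-D mean inlet speed equals the 0.5 m/s inhalation boundary
condition (a 3-D nostril area of 1.32·10⁻⁴ m² cannot be carried into 2-D) —
main-passage thickness 0.012 m and nasopharynx width 0.006 m, which
reproduce the characteristic speed ordering of nasal CFD (slow near the
olfactory roof, faster mid-passage, fastest in the nasopharynx). The bend
fillet radius is 5 mm. Real triangulated surfaces can be read from STL
(via trimesh) but are not used by the tests.

What the surrogate deliberately omits: turbinates and meatus folds, the
true nasal valve constriction, 3-D secondary flows, septal asymmetry and
mucus. Passing tests therefore demonstrate correct physics and numerics on
an idealized airway, not anatomical deposition values; in particular the
olfactory capture fraction of the real geometry is not reproducible here
(see Limitations).

## Magnetostatics

Magnets are uniformly magnetized cuboids with M = B_r/μ₀. The field uses
the closed-form Coulombian (surface-charge) solution: in the body frame
with magnetization M ẑ and corner offsets X_i, Y_j, Z_k,

    H_x = −(M/4π) Σ (−1)^{i+j+k} ln(Y_j + R_ijk)
    H_y = −(M/4π) Σ (−1)^{i+j+k} ln(X_i + R_ijk)
    H_z = +(M/4π) Σ (−1)^{i+j+k} atan2(X_i Y_j, Z_k R_ijk)

(the atan2 sum yields B_z/μ₀ inside the body, so M is subtracted there).
General magnetization directions are superposed via cyclic coordinate
permutation; the Jacobian ∂H_i/∂x_j is differentiated analytically, so
exterior evaluations are curl- and divergence-free to rounding. Points on
edge singularities of the log terms are nudged by 10⁻⁹ m and flagged, never
raised, so a grazing trajectory cannot crash the tracer.

The magnet interior uses μ_r = 1 (pure Coulombian model); the ~1.05
material permeability of NdFeB is recorded on the `Magnet` for provenance
but not modeled — including it needs a volume solver and perturbs the
exterior field by a few percent at most. The closed form is an exact
open-boundary solution, so no far-field boundary condition is involved.
The shared remanence direction (0, 0.771, 0.919)/1.2 is adopted as given
for all protocols, with magnet bodies (not the remanence) rotated between
protocols 1 and 2. The in-plane magnet position defaults to
(y, z) = (0.015, 0.025) m — over the vestibule/valve area — and is a
config field, since only a pictorial placement is available.

## Airflow

Steady incompressible Navier–Stokes, laminar (inlet Reynolds number ≈ 300;
the solver refuses Re ≥ 2000), solved on a MAC staggered grid over the
surrogate's uniform lattice with mask-based stair-step walls. Pseudo-time
marching with first-order upwind advection (robust and steady-friendly at
this Re), backward-Euler implicit diffusion, and an exact pressure
projection per step using prefactorized sparse LU solves. Boundary
conditions: fixed normal velocity on inlet faces, zero-gradient velocity
plus pressure Dirichlet on outlet faces, no-slip walls (ghost reflection on
straight wall lines, so a grid-aligned channel recovers plane Poiseuille
flow to second order; irregular boundaries are first-order).

The march stops when the normalized momentum residual
max|Δu|·h/(Δt·u_in²) falls below the tolerance (default 10⁻⁶). The
pseudo-time step is CFL-limited (0.4) and halved automatically if the flow
accelerates beyond the budget. Divergence after projection is at the level
of the direct solve (~10⁻¹³), so global mass balance is exact to rounding.

Resolution: default grid spacing 0.8 mm (≥ 8 cells across every limb,
~2200 fluid cells) solves in a few seconds; halving the spacing changes the
peak speed by < 5 % (grid-convergence check in the tests). The plane-
Poiseuille validation uses 64 cells across the channel at Re = 20 so the
profile develops within the fixture length.

## Particle tracing

100 particles are released at rest, equally spaced on a horizontal line at
height dz above the inlet (dz = 7.1 mm for protocols 1–2, 3.1 mm for 3,
with sagittal offsets dx = 2.5–3 mm). The nominal 1.5 cm line length is
clipped to the surrogate's vestibule width, centred on the inlet
centreline: the surrogate nostril is narrower than the anatomical one, and
the release must lie in the fluid. Release is deterministic; an optional
along-line jitter activates only when a seed is supplied.

Integration: classical RK4 with fixed dt = τ/20 (a stiffness guard rejects
dt > τ/10); no adaptive control (documented limitation — the overdamped
dynamics make the fixed step accurate, as the step-halving test shows).
Fluid velocity is bilinearly interpolated from the staggered grid; wall
values are zero, so sampling near boundaries decays to no-slip, and
sampling is clamped at the lattice edge during the final partial step
before contact.

Termination: first wall contact sticks (center within R_p of a
WALL/OLFACTORY segment, or a step crossing one — crossings are intersected
exactly so fast particles cannot tunnel); crossing the OUTLET (or back out
the INLET) is an escape; particles still airborne at t_max = 10 s are
SUSPENDED, counted in the efficiency denominator but never the numerator.
Brownian motion, gravity, particle–particle interaction and mucus capture
kinetics are excluded.

## Delivery efficiency and protocols

Efficiency = 100 × (deposited on OLFACTORY)/(released). The flow is
magnet-independent and computed once per comparison run. The magnet-free
control (protocol 0) uses the protocol-3 release geometry.

## Numerical choices and tie-breaks

- Nearest-boundary label ties (corner points) resolve by fixed priority
  OLFACTORY > WALL > INLET > OUTLET.
- Degenerate inputs are rejected at construction: olfactory fraction
  outside (0, 1), grids coarser than 8 cells per inlet width, zero-length
  release lines, non-orthonormal magnet rotations, χ ≤ −3 in the exact
  force mode (pole of the susceptibility factor).
- u_in = 0 short-circuits to the exact null solution.
- All comparisons/exports use fixed float formatting, so identical configs
  reproduce byte-identical CSV outputs.

## Problem sizes

Defaults throughout are the study conditions themselves (100 particles,
0.8 mm grid, 10 s particle-time cap); the full three-protocol comparison,
including the flow solve, completes in well under a minute on one core.
Validation fixtures are sized for sharp oracles: 64 cells across the
Poiseuille channel, ~20 k Gauss–Legendre nodes per face for the
surface-charge oracle.

## Known limitations

- The surrogate cannot reproduce anatomy-specific deposition numbers; on
  the idealized channel the default protocols capture particles in the
  vestibule (bar magnets) or let them escape (plate magnet), with zero
  olfactory hits. The qualitative structure — capture concentrated where
  the field gradient peaks near the bar-magnet edge, weaker capture for
  the plate — mirrors the real-geometry behavior.
- First-order stair-step walls bias near-wall shear on oblique boundaries.
- The high-χ force limit overestimates the force for χ ≲ 10 (the exact
  mode is available but magnetite microparticle χ is not pinned down).
- 2-D in-plane motion ignores the lateral force component, which in the
  real airway can push particles toward the septum or lateral wall.
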