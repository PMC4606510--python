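# Methods

## Model structure

`sigdiff` solves coupled systems of reaction–diffusion PDEs and compartment
ODEs. The spatially resolved domain Ω is the region where transport matters:
the cytoplasmic shell of a single cell (the nucleus is *not* meshed — it is a
well-mixed compartment represented only by its interface), or the
extracellular space of a cell lattice (cells are unmeshed spherical holes).
Diffusing species obey

    ∂t u_i = ∇·(D̃_i ∇u_i) − v·∇u_i + ρ_i(u),

with ρ the net production of the reaction network (mass-action sublanguage
with analytic Jacobians, plus an escape hatch for arbitrary smooth rate
callables). Tagged boundary parts carry Robin conditions D ∂n u = g(u|Γ, w)
that may be nonlinear and may exchange mass with compartment variables w;
each compartment ODE is dw/dt = h(ū, w) plus the area-integrated exchange
flux divided by the compartment volume, where ū is the surface average over
that compartment's own interface (not all of ∂Ω; both conventions are
representable, the shared interface is the default).

Sign conventions are fixed globally: g > 0 is influx into the PDE domain
through the outward normal, and an ODE receiver with weight φ gains
φ·(−∫Γ g ds)/V. Declared exchanges therefore conserve mass identically at
the discrete level, because the compartment side books exactly the nodal
quadrature of the flux the field side received.

### Units

Lengths in μm, times in seconds, concentrations in molecules/μm³
(1 pM = 6.022·10⁻⁴ molecules/μm³); configuration files accept rates quoted
per hour and convert on load. Receptor and bound-ligand counts are plain
numbers in unit-volume bookkeeping compartments.

## Discretization

* **Space**: P1 (linear) simplex Galerkin elements, 2D and 3D. Reaction terms
  use the group-FE/row-sum-lumped quadrature `Ml ⊙ ρ(u_nodes)`; boundary
  fluxes use the lumped surface quadrature `b_Γ ⊙ g(u_nodes)`. Lumping these
  terms (the mass and stiffness matrices remain consistent) preserves the
  O(h²) L² convergence of P1 elements and makes conservation exact: the
  column sums of the stiffness matrix vanish identically and the lumped
  surface vector is shared between the PDE load and the ODE exchange term.
* **Time**: Rothe method with the implicit θ-scheme — backward Euler (θ=1)
  or Crank–Nicolson (θ=½) as the second-order representative. Each step
  solves the monolithic nonlinear system by a modified Newton iteration:
  the LU factorization of the Jacobian is cached per step size and refreshed
  only when the iteration stalls, with backtracking on residual growth.
  Sparse direct factorization (SuperLU) is the linear solver.
* **Segregated (splitting) mode**: per step, the PDE block is solved with
  the compartment values frozen, then the compartment ODEs are advanced with
  the updated traces; the exchange fluxes in the ODE stage are evaluated at
  exactly the frozen iterate the PDE stage saw (explicit in the compartment
  unknowns, implicit in everything else), so the splitting conserves mass
  identically while keeping the usual O(dt) splitting error. An optional
  sweep count iterates the pair toward the monolithic fixed point.
* **Adaptivity**: step doubling (one full step vs two half steps), error
  measured in a weighted RMS norm with per-species scales, controller
  dt' = clip(0.9·dt·(tol/err)^(1/(p+1)), dt_min, dt_max); rejected steps
  repeat with the reduced dt, and the refined two-half-step solution is the
  one carried forward.

### Error scales and singular start-ups

Species that grow from zero through a high-order tangency (an activated form
behind a smooth activation ramp, a cytokine field filling an empty domain)
have order-one *relative* local error at the first steps for any dt, so a
purely relative controller would drive dt → 0. The controller therefore
accepts per-species absolute scales (CVODE-style): the bundled models
declare one hundredth of their characteristic scale (total pool for the
intracellular pathways; 0.01 pM, 1 % of the activation threshold, and 1 % of
the feedback half-saturation for the lattice model). For the same reason all
bundled forcings switch on smoothly (cubic smoothstep over 60 s by default)
rather than discontinuously.

## Verification

The verification layer shares no assembly code with the engine:

* **Manufactured solutions** (sympy-derived sources): a radial profile on a
  2D annulus with vanishing normal derivative at both circles (so the
  induced boundary data are exactly zero) drives the spatial study; observed
  L² ratios under h → h/2 are ≈ 4. A Robin-coupled linear PDE/ODE pair with
  compatible initial data drives the temporal and splitting studies
  (backward Euler ratios ≈ 2, Crank–Nicolson ≈ 4, splitting difference
  O(dt)). Temporal orders are measured against a Crank–Nicolson reference at
  dt/8; incompatible initial data would pollute the Crank–Nicolson order
  through undamped stiff transients, which is why the benchmark starts at
  exchange equilibrium.
* **Radial oracle**: spherically symmetric shell problems are also solved by
  a conservative 1D finite-volume discretization in the radius, integrated
  by a tight-tolerance BDF method. The FE solution converges to it under
  mesh refinement (cross-method evidence, not self-consistency).
* **Well-mixed companion**: any model without explicitly space-dependent
  rates has a derivable companion ODE system (volume averages, area-scaled
  exchange); it is integrated independently (BDF, rtol 1e-9) and, for linear
  models, cross-checked against the matrix exponential. The companion also
  defines the "deviation to the well-mixed model" diagnostic: the absolute
  difference between each species' volume mean and its companion value.
  The package reports that deviation per time point; when a single summary
  number is needed it is normalized by the species' mean concentration.

## Diagnostics

The gradient metric is the maximum relative variation
(max − min)/max of a nodal field at a time point; for P1 fields the extrema
are at nodes, so the nodal scan is exact. The regime indicator D/(L²k)
classifies whether a spatial model is needed (≪ 1) or a well-mixed model
suffices (≫ 1). Lattice runs additionally report activated-cell counts
(receptor count above threshold; responders by default, since regulatory
cells are suppressors rather than signal targets) and the molecule balance
free + bound − secreted, which closes to solver precision because secretion
is integrated by per-secretor bookkeeping ODEs.

## Bundled pathway models and defaults

Kinetic *structures* follow the respective pathways; the default rate
*values* are stand-ins chosen once to land in the documented qualitative
regimes, and every one of them is configuration-exposed.

**Geometries** (defaults; the literature does not pin these cells' exact
dimensions): sphere cell R = 5 μm with nucleus r = 3 μm; box cell
30×20×10 μm with 10×8×6 μm nucleus; extensions: two cylinders, length 20 μm,
radius 1 μm, along ±x. 2D cross-sections (annulus, rectangle) are supported
for fast tests; all operators are dimension-generic.

**STAT-like** (all linear; dimer bookkeeping keeps it so): D = 15 μm²/s both
forms; membrane activation k_act = 0.1 μm/s modulated by the pJAK profile
(smoothstep 0→1 over 60 s); nuclear import 0.01 (inactive) and 0.05
(activated) μm/s; export 0.05 μm/s; nuclear dephosphorylation 0.005 1/s;
initial pool 1 molecule/μm³; horizon 200 min. Closed: total STAT conserved.
The anisotropic variant uses the trace-preserving tensor (principal entry
3ratio·D/(ratio+2), trace fixed at 3D) so anisotropic and isotropic runs are
comparable.

**SMAD-like**: D = 15 μm²/s for all forms (slow-trimer variant D = 1);
activation 0.02 μm/s (production-limited, which is what makes nuclear
accumulation buffer the nuclear trajectory); dimerization 0.1 μm³/(molec·s)
on, 0.01 1/s off; trimerization likewise; trimer import 0.1 μm/s; horizon
200 min. Conserved composition: monomer 1, dimer 2, trimer 3.

**IL-2 lattice**: cells of radius 4 μm at 10 μm center-to-center spacing
(box with reflecting outer walls — a closed tissue cutout); D = 10 μm²/s;
secretion q = 10⁶ molecules/h per secreting cell (alternate 1.5·10⁶),
ramped over 60 s; uptake k_on = 0.02 μm³/s per receptor; receptor
production 500/h, decay 0.5/h (constitutive level 1000); production
multiplied by 1 + 9·B²/(B² + K²) with B the cumulative bound count and
K = 5·10⁴; regulatory uptake multiplier 5; activation threshold 4000
receptors; extracellular degradation defaults to 0 (knob provided); horizon
30 h. On the bundled 3×3×3 cutout every absorber lies within ~17 μm of the
central secreter — inside the ~2-cell-distance activation range this
parameter set produces — so the single-secreter steady state activates all
responders; differential (shell-like) activation appears on larger lattices,
which these desk-scale defaults deliberately do not run.

## What the synthetic conditions do and do not show

All bundled experiments run on idealized generated geometries. They
demonstrate the mechanisms — geometry-amplified gradients, slow-diffusion
gradients, nuclear-accumulation buffering, localized cytokine competition
and regulatory suppression — and the correctness of the numerics, but not
quantitative gradients of any real cell: real cytoplasm is crowded and
heterogeneous (the diffusion coefficient here is a macroscopic effective
parameter), real cell shapes are irregular, and the kinetic constants are
order-of-magnitude stand-ins rather than fitted values. Voxel-meshed
geometries (extensions, lattices) have staircase boundaries whose surface
areas converge slowly; tests therefore compare like with like or in
directions that staircase artifacts cannot fake.

## Problem sizes

The shipped studies use coarse meshes and shortened horizons chosen as the
smallest sizes at which each phenomenon is unambiguous: sphere shells at
h = 1.5 μm (≈ 500 nodes), the box cell at h = 2.5 μm (≈ 840 nodes), lattices
3×3×3 at h = 2.5 μm (≈ 2200 nodes), convergence studies on 2D annuli with
three refinement levels. The 200-min intracellular horizon is kept in full
for the buffering comparison (truncating it mid-transient would overstate
the nuclear difference); single-cell gradient snapshots use 10–20 min, by
which time the variation series have plateaued.

## Known limitations

* P1 elements only; no stabilized advection (plain Galerkin with an element
  Péclet check that warns above 1).
* No spatial mesh adaptivity, moving meshes, or cell mechanics; adaptivity
  is in time only, by step doubling rather than goal-oriented estimators.
* The segregated mode's compartment stage treats exchange explicitly in the
  compartment unknowns; very stiff exchange rates may require smaller steps
  than the monolithic mode.
* Voxel meshes approximate curved surfaces to O(h) in area; the smooth
  icosphere-extrusion shells converge at O(h²) in volume and area.
* Microscopy-derived geometries and parameter fitting are out of scope.
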