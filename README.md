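# sigdiff

Coupled PDE/ODE reaction–diffusion simulation of intra- and inter-cellular
signaling gradients.

## The problem

Signaling molecules are activated at a cell's outer membrane, travel through
the cytoplasm, and are imported into the nucleus — or, in a tissue, are
secreted by some cells and absorbed by others. Whether the spatial transport
step matters is a quantitative question: if diffusion is fast compared to the
reactions (D/L² ≫ k), a well-mixed ODE model suffices; if not, concentration
gradients form and a spatially resolved model is needed.

`sigdiff` simulates the coupled system

```
∂t u_i = ∇·(D̃_i ∇u_i) − v·∇u_i − f_i(u)        in Ω (cytoplasm / medium)
D_i ∂n u_i = g_i(u_i|Γ, u_j)                     on tagged surfaces Γ ⊂ ∂Ω
du_j/dt = h_j(ū, u_j) − (1/V_j) ∫_Γ g ds         well-mixed compartments
```

where the diffusing species `u_i` live on a tagged simplex mesh of the
spatially resolved domain, well-mixed compartments (the nucleus, whole cells)
are ODE blocks coupled through Robin boundary conditions, `ū` is the surface
average over the shared interface, and the exchange terms conserve mass by
construction. Space is discretized with P1 Galerkin finite elements, time
with backward Euler or Crank–Nicolson (Rothe method), solved either
monolithically by Newton iteration or by an operator-splitting (segregated)
sweep, with step-doubling adaptive time-step control.

Three bundled pathway models exercise the framework:

* **STAT-like shuttling** — linear nucleocytoplasmic cycle driven by a
  prescribed phospho-JAK profile; closed (total STAT conserved).
* **SMAD-like oligomerization** — activated monomers dimerize/trimerize;
  trimers accumulate in the nucleus, buffering the nuclear signal against
  cytoplasmic gradients.
* **IL-2 competition** — secreting, responding and regulatory T cells on a
  cubic lattice compete for a diffusing cytokine through receptor-mediated
  uptake with positive feedback.

Everything runs on programmatically generated geometries (sphere shells, box
cells, cells with cytoplasmic extensions, multicellular lattices); no
external inputs are needed.

## Worked example

```python
import numpy as np
from sigdiff import CellGeometrySpec, build_cell_mesh, SolverConfig, solve
from sigdiff.pathways import StatPathwayParams, build_stat_model
from sigdiff.diagnostics import variation_series

sphere = build_cell_mesh(CellGeometrySpec(outer=5.0, nucleus=3.0, target_h=1.5))
extended = build_cell_mesh(
    CellGeometrySpec(kind="extended_shell", outer=5.0, nucleus=3.0, target_h=0.9)
)
cfg = SolverConfig(dt_init=15.0, dt_max=15.0, dt_min=1.0, adaptive=False)
for name, mesh in [("sphere", sphere), ("extended", extended)]:
    traj = solve(build_stat_model(mesh, StatPathwayParams(T=900.0)), cfg)
    var = variation_series(traj, "pSTAT", np.array([900.0]))[0]
    drift = max(abs(m["conservation_residual"]) for m in traj.step_meta)
    print(f"{name:9s} pSTAT gradient {100 * var:5.2f} %   mass drift {drift:.1e}")
```

prints

```
sphere    pSTAT gradient  0.40 %   mass drift 4.2e-13
extended  pSTAT gradient 12.29 %   mass drift 5.9e-13
```

i.e. on a round cell the activated pool is essentially homogeneous, while
two thin cytoplasmic extensions amplify the activated-STAT gradient by more
than an order of magnitude at identical kinetics — and in both cases the
closed model conserves total STAT to solver precision.

The same study is available from the shell:

```sh
sigdiff run --preset stat-sphere --outdir runs/sphere
sigdiff run --preset stat-extended --outdir runs/extended
sigdiff compare runs/sphere runs/extended
sigdiff verify          # built-in convergence/conservation suite
```

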