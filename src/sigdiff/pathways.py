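"""Bundled signaling-pathway models.

Three structurally faithful applications of the coupled PDE/ODE framework:

* a STAT5-like linear nucleocytoplasmic shuttling pathway (membrane
  activation driven by a prescribed phospho-JAK profile, nuclear import/
  export, nuclear dephosphorylation; closed and linear, total STAT
  conserved);
* a SMAD2-like pathway with nonlinear oligomerization (activated monomers
  dimerize and trimerize in the cytoplasm; trimers are imported into the
  nucleus, where they accumulate);
* an IL-2 competition model on a multicellular lattice (secreting cells
  release cytokine, absorbing cells take it up through receptors whose
  production is upregulated by the accumulated bound-ligand signal;
  regulatory cells absorb more strongly and can quench activation).

The kinetic forms are the pathways' published structure; the default rate
values are documented stand-ins chosen to land in the biologically reported
regimes (fast-diffusion homogeneity, slow-diffusion gradients, localized
cytokine uptake), since the quantitative fits live in specialised model
papers and are not reproduced here.  Every parameter is exposed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fem import Trajectory
from .geometry import (
    CELL_TAG_BASE,
    TAG_MEMBRANE,
    TAG_NUCLEUS,
    CellGeometrySpec,
    LatticeSpec,
    Mesh,
    build_cell_mesh,
    build_lattice_mesh,
)
from .model import (
    BoundaryCoupling,
    Compartment,
    ModelDefinition,
    ModelError,
    RateTerm,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    make_anisotropic_tensor,
)

HOUR = 3600.0


def smoothstep_profile(t_ramp: float = 60.0) -> Callable[[float], float]:
    """Smooth 0 -> 1 activation ramp over ``t_ramp`` seconds (C1 cubic)."""

    def p(t):
        s = min(max(t / t_ramp, 0.0), 1.0)
        return 3.0 * s * s - 2.0 * s**3

    return p


def _resolve_mesh(geom) -> Mesh:
    if isinstance(geom, Mesh):
        return geom
    if isinstance(geom, CellGeometrySpec):
        return build_cell_mesh(geom)
    if isinstance(geom, LatticeSpec):
        return build_lattice_mesh(geom)
    raise ModelError(f"cannot build a mesh from {type(geom).__name__}")


def _nucleus_volume(mesh: Mesh) -> float:
    geo = mesh.metadata.get("geometry")
    if geo is None:
        raise ModelError(
            "mesh carries no geometry metadata; pass a CellGeometrySpec or a "
            "mesh built by build_cell_mesh"
        )
    kind = geo["kind"]
    if kind in ("sphere_shell", "extended_shell"):
        r = float(geo["nucleus"])
        dim = mesh.dim
        return 4.0 / 3.0 * math.pi * r**3 if dim == 3 else math.pi * r**2
    nuc = np.asarray(geo["nucleus"], dtype=float)
    return float(np.prod(nuc[: mesh.dim]))


def _require_tags(mesh: Mesh, tags) -> None:
    have = set(mesh.boundary_tags())
    missing = [t for t in tags if t not in have]
    if missing:
        raise ModelError(f"mesh lacks required boundary tags {missing}")


# ---------------------------------------------------------------------------
# STAT5-like pathway (linear, closed)
# ---------------------------------------------------------------------------


@dataclass
class StatPathwayParams:
    """Linear nucleocytoplasmic shuttling parameters.

    Concentration variables describe STAT dimers, which keeps every rate
    law first-order and the whole model linear.  Units: um/s for membrane
    and interface rate coefficients, 1/s for the nuclear dephosphorylation,
    molecules/um^3 for the initial pool.  The pJAK forcing ``pjak(t)`` is a
    dimensionless prescribed profile standing in for the receptor module.
    """

    D: float = 15.0
    D_active: float | None = None
    k_act: float = 0.1
    k_import_inactive: float = 0.01
    k_import_active: float = 0.05
    k_export: float = 0.05
    k_dephos: float = 0.005
    stat_total: float = 1.0
    pjak: Callable[[float], float] | None = None
    t_ramp: float = 60.0
    anisotropy_ratio: float = 1.0
    anisotropy_axis: str = "y"
    T: float = 200.0 * 60.0

    def __post_init__(self):
        for name in ("k_act", "k_import_inactive", "k_import_active",
                     "k_export", "k_dephos", "stat_total", "D"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be nonnegative")


def build_stat_model(geom, params: StatPathwayParams | None = None) -> ModelDefinition:
    """Two cytoplasmic dimer species (STAT, pSTAT) + nuclear ODE pair.

    Membrane: STAT -> pSTAT at rate k_act * pjak(t) * [STAT] (a Robin flux
    pair that cancels in the total, so the total pool feels only the nuclear
    exchange).  Nuclear interface: import of both species, export of
    dephosphorylated nuclear STAT.  Closed: total STAT is conserved.
    """
    p = params or StatPathwayParams()
    mesh = _resolve_mesh(geom)
    _require_tags(mesh, [TAG_MEMBRANE, TAG_NUCLEUS])
    V_n = _nucleus_volume(mesh)
    pjak = p.pjak or smoothstep_profile(p.t_ramp)
    D_inact: float | tuple = p.D
    D_act: float | tuple = p.D_active if p.D_active is not None else p.D
    if p.anisotropy_ratio > 1.0:
        if mesh.dim != 3:
            raise ModelError("anisotropic transport is only meaningful in 3D")
        D_inact = make_anisotropic_tensor(p.D, p.anisotropy_ratio, p.anisotropy_axis)
        base_act = p.D_active if p.D_active is not None else p.D
        D_act = make_anisotropic_tensor(base_act, p.anisotropy_ratio, p.anisotropy_axis)

    net = ReactionNetwork(
        pde_species=["STAT", "pSTAT"],
        ode_species=["nSTAT", "npSTAT"],
        ode_reactions=[Reaction({"npSTAT": 1}, {"nSTAT": 1}, p.k_dephos)],
        conserved={"STAT": 1.0, "pSTAT": 1.0, "nSTAT": 1.0, "npSTAT": 1.0},
    )
    couplings = [
        # membrane activation: the pair of fluxes moves mass between the two
        # cytoplasmic species without creating any
        BoundaryCoupling(
            tag=TAG_MEMBRANE,
            species="STAT",
            flux=lambda t, x, tr, V: -p.k_act * pjak(t) * tr[:, 0],
            pde_deps=["STAT"],
            ode_deps=[],
        ),
        BoundaryCoupling(
            tag=TAG_MEMBRANE,
            species="pSTAT",
            flux=lambda t, x, tr, V: p.k_act * pjak(t) * tr[:, 0],
            pde_deps=["STAT"],
            ode_deps=[],
        ),
        # nuclear interface: import of inactive STAT and export of nuclear STAT
        BoundaryCoupling(
            tag=TAG_NUCLEUS,
            species="STAT",
            flux=lambda t, x, tr, V: -p.k_import_inactive * tr[:, 0]
            + p.k_export * V[0],
            receivers=[("nSTAT", 1.0)],
            pde_deps=["STAT"],
            ode_deps=["nSTAT"],
        ),
        # import of the activated form into the nuclear pool
        BoundaryCoupling(
            tag=TAG_NUCLEUS,
            species="pSTAT",
            flux=lambda t, x, tr, V: -p.k_import_active * tr[:, 1],
            receivers=[("npSTAT", 1.0)],
            pde_deps=["pSTAT"],
            ode_deps=[],
        ),
    ]
    return ModelDefinition(
        mesh=mesh,
        species=[
            SpeciesSpec("STAT", "pde", diffusion=D_inact),
            SpeciesSpec("pSTAT", "pde", diffusion=D_act),
            SpeciesSpec("nSTAT", "ode", compartment="nucleus"),
            SpeciesSpec("npSTAT", "ode", compartment="nucleus"),
        ],
        compartments={
            "nucleus": Compartment("nucleus", volume=V_n, surface_tag=TAG_NUCLEUS)
        },
        network=net,
        couplings=couplings,
        initial={"STAT": p.stat_total},
        T=p.T,
        composition={"STAT": 1.0, "pSTAT": 1.0, "nSTAT": 1.0, "npSTAT": 1.0},
        info={"pathway": "stat", "params": p},
    )


# ---------------------------------------------------------------------------
# SMAD-like pathway (nonlinear oligomerization, nuclear accumulation)
# ---------------------------------------------------------------------------


@dataclass
class SmadPathwayParams:
    """Oligomerizing pathway parameters.

    Activated monomers dimerize (k_on2/k_off2, um^3/(molecule s) and 1/s)
    and trimerize (dimer + monomer, k_on3/k_off3); trimers are imported at
    the nuclear interface (k_import_trimer, um/s) and accumulate.  The
    membrane activation flux coefficient k_act (um/s) is ramped by the same
    smooth profile as the STAT model.  Monomer equivalents are conserved.
    """

    D_monomer: float = 15.0
    D_dimer: float = 15.0
    D_trimer: float = 15.0
    k_act: float = 0.02
    k_on2: float = 0.1
    k_off2: float = 0.01
    k_on3: float = 0.1
    k_off3: float = 0.01
    k_import_trimer: float = 0.1
    smad_total: float = 1.0
    t_ramp: float = 60.0
    T: float = 200.0 * 60.0

    def __post_init__(self):
        for name in ("k_act", "k_on2", "k_off2", "k_on3", "k_off3",
                     "k_import_trimer", "smad_total"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be nonnegative")


def build_smad_model(geom, params: SmadPathwayParams | None = None) -> ModelDefinition:
    """Monomer/dimer/trimer cytoplasmic cascade with nuclear trimer ODE."""
    p = params or SmadPathwayParams()
    mesh = _resolve_mesh(geom)
    _require_tags(mesh, [TAG_MEMBRANE, TAG_NUCLEUS])
    V_n = _nucleus_volume(mesh)
    ramp = smoothstep_profile(p.t_ramp)
    composition = {"SMAD": 1.0, "pSMAD": 1.0, "dimer": 2.0, "trimer": 3.0,
                   "nuc_trimer": 3.0}
    net = ReactionNetwork(
        pde_species=["SMAD", "pSMAD", "dimer", "trimer"],
        ode_species=["nuc_trimer"],
        reactions=[
            Reaction({"pSMAD": 2}, {"dimer": 1}, p.k_on2),
            Reaction({"dimer": 1}, {"pSMAD": 2}, p.k_off2),
            Reaction({"dimer": 1, "pSMAD": 1}, {"trimer": 1}, p.k_on3),
            Reaction({"trimer": 1}, {"dimer": 1, "pSMAD": 1}, p.k_off3),
        ],
        conserved=composition,
    )
    couplings = [
        BoundaryCoupling(
            tag=TAG_MEMBRANE,
            species="SMAD",
            flux=lambda t, x, tr, V: -p.k_act * ramp(t) * tr[:, 0],
            pde_deps=["SMAD"],
            ode_deps=[],
        ),
        BoundaryCoupling(
            tag=TAG_MEMBRANE,
            species="pSMAD",
            flux=lambda t, x, tr, V: p.k_act * ramp(t) * tr[:, 0],
            pde_deps=["SMAD"],
            ode_deps=[],
        ),
        BoundaryCoupling(
            tag=TAG_NUCLEUS,
            species="trimer",
            flux=lambda t, x, tr, V: -p.k_import_trimer * tr[:, 3],
            receivers=[("nuc_trimer", 1.0)],
            pde_deps=["trimer"],
            ode_deps=[],
        ),
    ]
    return ModelDefinition(
        mesh=mesh,
        species=[
            SpeciesSpec("SMAD", "pde", diffusion=p.D_monomer),
            SpeciesSpec("pSMAD", "pde", diffusion=p.D_monomer),
            SpeciesSpec("dimer", "pde", diffusion=p.D_dimer),
            SpeciesSpec("trimer", "pde", diffusion=p.D_trimer),
            SpeciesSpec("nuc_trimer", "ode", compartment="nucleus"),
        ],
        compartments={
            "nucleus": Compartment("nucleus", volume=V_n, surface_tag=TAG_NUCLEUS)
        },
        network=net,
        couplings=couplings,
        initial={"SMAD": p.smad_total},
        T=p.T,
        composition=composition,
        info={"pathway": "smad", "params": p},
    )


# ---------------------------------------------------------------------------
# IL-2 competition on a lattice
# ---------------------------------------------------------------------------


@dataclass
class Il2Params:
    """Cytokine competition parameters.

    ``q`` molecules/h secreted per secreting cell; ``k_on`` um^3/s per
    receptor (multiply by 6.022e-4 molecules/um^3 to read it per pM);
    receptor production/decay in receptors/h and 1/h; receptor production is
    multiplied by ``1 + feedback_amp * B^n/(B^n + K^n)`` with B the
    cumulative bound-ligand count (Hill coefficient n = 2); regulatory cells
    multiply their uptake by ``regulatory_multiplier``.  Cells with more
    receptors than ``activation_threshold`` count as activated.
    """

    D: float = 10.0
    q: float = 1.0e6
    k_on: float = 0.02
    receptor_production: float = 500.0
    receptor_decay: float = 0.5
    feedback_amp: float = 9.0
    feedback_K: float = 5.0e4
    hill: float = 2.0
    regulatory_multiplier: float = 5.0
    receptor_init: float | None = None
    activation_threshold: float = 4000.0
    degradation: float = 0.0
    il2_init: float = 0.0
    t_ramp: float = 60.0
    T: float = 30.0 * HOUR

    def __post_init__(self):
        for name in ("D", "q", "k_on", "receptor_production", "receptor_decay",
                     "feedback_amp", "feedback_K", "regulatory_multiplier",
                     "degradation"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be nonnegative")

    @property
    def q_per_s(self) -> float:
        return self.q / HOUR

    @property
    def constitutive_receptors(self) -> float:
        if self.receptor_init is not None:
            return self.receptor_init
        return self.receptor_production / max(self.receptor_decay, 1e-300)


def build_il2_model(lattice, params: Il2Params | None = None) -> ModelDefinition:
    """Extracellular IL-2 field + per-cell receptor/bound-signal ODEs.

    Secreting cells impose a constant outward flux q/A_k on their surface;
    every absorbing cell removes ligand at rate k_on * R_k * (local trace)
    per area (scaled so the surface integral is k_on * R_k * mean surface
    concentration) and books it into its cumulative bound count B_k, which
    drives receptor upregulation.  Receptor counts live in per-cell unit
    compartments, so fluxes convert 1:1 into molecules.
    """
    p = params or Il2Params()
    mesh = _resolve_mesh(lattice)
    cells = mesh.metadata.get("cells")
    if not cells:
        raise ModelError("lattice mesh carries no per-cell metadata (types/tags)")
    types = cells["types"]
    tags = cells["tags"]
    n_cells = len(types)
    have_tags = set(mesh.boundary_tags())
    areas = {tag: mesh.surface_area(tag) for tag in tags if tag in have_tags}

    species = [SpeciesSpec("IL2", "pde", diffusion=p.D)]
    compartments: dict[str, Compartment] = {}
    couplings: list[BoundaryCoupling] = []
    extra_ode: list[RateTerm] = []
    ode_names: list[str] = []
    absorbers: list[dict] = []
    secretors: list[dict] = []

    prod_s = p.receptor_production / HOUR
    decay_s = p.receptor_decay / HOUR

    for k in range(n_cells):
        tag = tags[k]
        if tag not in have_tags:
            # fully enclosed? should not happen on these lattices
            raise ModelError(f"cell {k} surface tag {tag} missing from the mesh")
        A = areas[tag]
        if types[k] == "secreting":
            rate = p.q_per_s / A
            ramp = smoothstep_profile(p.t_ramp) if p.t_ramp > 0 else (lambda t: 1.0)

            def secrete(t, x, tr, V, rate=rate, ramp=ramp):
                return np.full(tr.shape[0], rate * ramp(t))

            # the secreted amount is integrated into a bookkeeping ODE with
            # weight -1, so the discrete molecule balance closes exactly
            Sname = f"S_{k}"
            comp = f"secretor_{k}"
            compartments[comp] = Compartment(comp, volume=1.0, surface_tag=tag)
            species.append(SpeciesSpec(Sname, "ode", compartment=comp,
                                       unit="molecules"))
            ode_names.append(Sname)
            secretors.append({"cell": k, "S": Sname, "tag": tag, "area": A})
            couplings.append(
                BoundaryCoupling(tag=tag, species="IL2", flux=secrete,
                                 receivers=[(Sname, -1.0)],
                                 pde_deps=[], ode_deps=[])
            )
            continue
        mult = p.regulatory_multiplier if types[k] == "regulatory" else 1.0
        Rname, Bname = f"R_{k}", f"B_{k}"
        comp = f"cell_{k}"
        compartments[comp] = Compartment(comp, volume=1.0, surface_tag=tag)
        species += [
            SpeciesSpec(Rname, "ode", compartment=comp, unit="receptors"),
            SpeciesSpec(Bname, "ode", compartment=comp, unit="molecules"),
        ]
        ode_names += [Rname, Bname]
        absorbers.append({"cell": k, "R": Rname, "B": Bname, "tag": tag,
                          "type": types[k], "area": A, "mult": mult})

    # index maps are only known once the species list is final
    oindex = {name: j for j, name in enumerate(ode_names)}
    for a in absorbers:
        jR, jB = oindex[a["R"]], oindex[a["B"]]
        coef = a["mult"] * p.k_on / a["area"]

        def uptake(t, x, tr, V, coef=coef, jR=jR):
            return -coef * V[jR] * tr[:, 0]

        couplings.append(
            BoundaryCoupling(
                tag=a["tag"],
                species="IL2",
                flux=uptake,
                receivers=[(a["B"], 1.0)],
                pde_deps=["IL2"],
                ode_deps=[a["R"]],
            )
        )

        def receptor_rate(t, ubar, V, jR=jR, jB=jB):
            B = max(V[jB], 0.0)
            hillterm = B**p.hill / (B**p.hill + p.feedback_K**p.hill) if B > 0 else 0.0
            return prod_s * (1.0 + p.feedback_amp * hillterm) - decay_s * V[jR]

        extra_ode.append(
            RateTerm(a["R"], receptor_rate, pde_deps=[], ode_deps=[a["R"], a["B"]])
        )

    reactions = []
    if p.degradation > 0:
        reactions.append(Reaction({"IL2": 1}, {}, p.degradation))
    net = ReactionNetwork(
        pde_species=["IL2"],
        ode_species=ode_names,
        reactions=reactions,
        extra_ode=extra_ode,
    )
    initial: dict[str, float] = {"IL2": p.il2_init}
    for a in absorbers:
        initial[a["R"]] = p.constitutive_receptors
        initial[a["B"]] = 0.0
    for srec in secretors:
        initial[srec["S"]] = 0.0
    n_secreting = len(secretors)
    return ModelDefinition(
        mesh=mesh,
        species=species,
        compartments=compartments,
        network=net,
        couplings=couplings,
        initial=initial,
        T=p.T,
        composition=None,
        info={
            "pathway": "il2",
            "params": p,
            "absorbers": absorbers,
            "secretors": secretors,
            "n_secreting": n_secreting,
            "secretion_rate_total": n_secreting * p.q_per_s,
        },
    )


def recommended_solver_config(model: ModelDefinition, **overrides):
    """Adaptive solver configuration with per-species absolute error scales.

    Species that grow from zero (activated forms, nuclear pools, cytokine
    fields) have order-one *relative* local error during start-up at any
    step size, so the controller needs an absolute floor per species set by
    the pathway's characteristic scale: the total pool for the intracellular
    models, and the scales documented in :func:`il2_solver_config` for the
    lattice model.
    """
    from .fem import SolverConfig

    pathway = model.info.get("pathway")
    if pathway == "il2":
        return il2_solver_config(model, **overrides)
    p = model.info["params"]
    scale = p.stat_total if pathway == "stat" else p.smad_total
    atol = {s.name: 0.01 * scale for s in model.species}
    base = dict(dt_init=10.0, dt_min=1e-3, dt_max=600.0, adapt_tol=1e-3,
                species_atol=atol)
    base.update(overrides)
    return SolverConfig(**base)


def il2_solver_config(model: ModelDefinition, **overrides) -> "SolverConfig":
    """Recommended adaptive configuration for IL-2 lattice runs.

    Declares per-species absolute error scales (one hundredth of a
    characteristic value: 0.01 pM for the cytokine field, 1 % of the
    activation threshold for receptor counts, 1 % of the feedback
    half-saturation for the bound-ligand signal), which keeps the step
    controller from chasing the singular start-up of the secretion field.
    """
    from .fem import SolverConfig
    from .model import PM_TO_MOLECULES_PER_UM3

    p: Il2Params = model.info["params"]
    atol = {"IL2": 0.01 * PM_TO_MOLECULES_PER_UM3}
    for a in model.info["absorbers"]:
        atol[a["R"]] = 0.01 * p.activation_threshold
        atol[a["B"]] = 0.01 * p.feedback_K
    for srec in model.info["secretors"]:
        atol[srec["S"]] = 0.01 * p.q
    base = dict(
        dt_init=10.0,
        dt_min=1e-3,
        dt_max=HOUR,
        adapt_tol=1e-3,
        species_atol=atol,
    )
    base.update(overrides)
    return SolverConfig(**base)


def count_activated(traj: Trajectory, threshold: float,
                    include_regulatory: bool = False) -> np.ndarray:
    """Cells whose receptor count exceeds the threshold, per output time.

    Counts responder cells by default (regulatory cells are suppressors, not
    signal targets); pass ``include_regulatory=True`` to count every
    non-secreting cell.
    """
    absorbers = traj.model.info.get("absorbers")
    if absorbers is None:
        raise ModelError("trajectory does not come from an IL-2 lattice model")
    kinds = ("responder", "regulatory") if include_regulatory else ("responder",)
    counts = np.zeros(len(traj.states), dtype=int)
    for a in absorbers:
        if a["type"] not in kinds:
            continue
        series = traj.ode_series(a["R"])
        counts += (series > threshold).astype(int)
    return counts


def molecule_balance_residual(traj: Trajectory) -> float:
    """Max |(free + bound) - (initial + secreted)| over the run, relative to
    cumulative secretion.

    Secretion is read from the per-secretor bookkeeping ODEs, which integrate
    exactly the discrete flux the field received, so for a degradation-free
    run the residual reflects only the nonlinear-solver tolerance.  With
    degradation enabled the degraded amount is approximated by trapezoidal
    quadrature of the free pool and the residual is no longer exact.
    """
    from .model import lumped_mass_vector

    model = traj.model
    p: Il2Params = model.info["params"]
    w = lumped_mass_vector(model.mesh)
    times = traj.times
    free = np.array([float(w @ s.fields["IL2"]) for s in traj.states])
    bound = np.zeros_like(free)
    for a in model.info["absorbers"]:
        bound += traj.ode_series(a["B"])
    secreted = np.zeros_like(free)
    for srec in model.info["secretors"]:
        secreted += traj.ode_series(srec["S"])
    if p.degradation > 0:
        deg = np.concatenate(
            [[0.0], np.cumsum(0.5 * (free[1:] + free[:-1]) * np.diff(times))]
        ) * p.degradation
    else:
        deg = np.zeros_like(free)
    residual = (free - free[0]) + (bound - bound[0]) - secreted + deg
    denom = max(float(secreted[-1]), 1e-300)
    return float(np.max(np.abs(residual)) / denom)
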