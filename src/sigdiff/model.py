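"""Coupled PDE/ODE model definitions.

A model couples diffusing species in a meshed domain (cytoplasm or
extracellular space) to well-mixed ODE compartments (nucleus, whole cells)
through Robin boundary conditions on tagged surfaces:

* in the domain:      du_i/dt = div(D_i grad u_i) - v . grad u_i + rho_i(u)
* on a tagged surface Gamma:  D_i dn u_i = g_i(trace u, u_ode)
* in a compartment:   du_j/dt = h_j(ubar, u_ode) + sum of exchanged fluxes

Sign conventions (fixed once, everywhere):

* ``rho`` is the *production* rate (du/dt contribution); the kinetic term
  ``f`` of the reaction-diffusion equation written as du/dt = D Lap u - f
  is ``f = -rho``.
* ``g > 0`` is influx into the PDE domain through the surface (the normal
  is outward).  An ODE species listed as a receiver of a coupling with
  weight ``w`` gains ``w * (-integral_Gamma g ds) / V`` per unit time, so a
  declared exchange conserves mass by construction.
* ``ubar`` entering a compartment ODE is the surface average of the PDE
  species over that compartment's own coupling surface (its ``surface_tag``),
  not over all of the boundary.

Units: um, s, molecules/um^3 internally; 1 pM = 6.022e-4 molecules/um^3.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import Mesh

#: molecules per um^3 corresponding to 1 pM
PM_TO_MOLECULES_PER_UM3 = 6.02214076e-4


class ModelError(ValueError):
    """Invalid model construction."""


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSpec:
    """One chemical species: a diffusing PDE field or a well-mixed ODE scalar.

    ``diffusion`` is a scalar D (um^2/s) or a length-dim diagonal tensor.
    ``velocity`` is an optional constant advection velocity (um/s).
    ODE species carry the name of their host compartment instead.
    """

    name: str
    kind: str = "pde"
    diffusion: float | tuple | None = None
    velocity: tuple | None = None
    compartment: str | None = None
    unit: str = "molecules/um^3"

    def __post_init__(self):
        if self.kind not in ("pde", "ode"):
            raise ModelError(f"species kind must be pde or ode, got {self.kind!r}")
        if self.kind == "pde":
            if self.diffusion is None:
                raise ModelError(f"pde species {self.name!r} needs a diffusion rate")
            d = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
            if np.any(d < 0):
                raise ModelError(f"diffusion entries of {self.name!r} must be >= 0")
        else:
            if self.diffusion is not None or self.velocity is not None:
                raise ModelError(f"ode species {self.name!r} must not carry transport")
            if not self.compartment:
                raise ModelError(f"ode species {self.name!r} needs a host compartment")

    def diffusion_tensor(self, dim: int) -> np.ndarray:
        d = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        if d.size == 1:
            return np.full(dim, float(d[0]))
        if d.size != dim:
            raise ModelError(
                f"diffusion tensor of {self.name!r} has {d.size} entries for dim {dim}"
            )
        return d.astype(float)


@dataclass
class Compartment:
    """Well-mixed compartment with volume (um^3) and its coupling surface tag."""

    name: str
    volume: float
    surface_tag: int | None = None

    def __post_init__(self):
        if self.volume <= 0:
            raise ModelError(f"compartment {self.name!r} must have positive volume")


def make_anisotropic_tensor(D: float, ratio: float, axis: int | str = "y") -> tuple:
    """Trace-preserving diagonal diffusion tensor.

    The principal axis gets ``ratio`` times the off-axis entries while the
    trace is held at 3 D (so the anisotropic tensor is comparable to the
    isotropic one): principal = 3 ratio D / (ratio + 2), off-axis
    = 3 D / (ratio + 2).  ``ratio=1`` returns the isotropic tensor.
    """
    if D <= 0:
        raise ModelError("D must be positive")
    if ratio < 1:
        raise ModelError("ratio must be >= 1 (swap the axis to slow a direction)")
    ax = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if ax not in (0, 1, 2):
        raise ModelError(f"axis must be x/y/z or 0/1/2, got {axis!r}")
    off = 3.0 * D / (ratio + 2.0)
    out = [off, off, off]
    out[ax] = ratio * off
    return tuple(out)


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """Mass-action reaction: rate = k * prod(conc^stoich over reactants)."""

    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float

    def __post_init__(self):
        if self.rate_constant < 0:
            raise ModelError("rate constants must be nonnegative")
        for d in (self.reactants, self.products):
            for sp, nu in d.items():
                if int(nu) < 0:
                    raise ModelError(f"stoichiometry of {sp!r} must be nonnegative")


@dataclass
class RateTerm:
    """Escape hatch: arbitrary smooth production-rate term for one species.

    ``fn(t, X, U, V) -> (N,)`` for PDE terms (X nodal coordinates, U the
    (N, P) matrix of PDE fields, V the (Q,) ODE vector); for ODE terms
    ``fn(t, ubar, V) -> float`` with ``ubar`` the (P,) surface averages of
    the host compartment.  ``ode_deps``/``pde_deps`` restrict the species the
    term actually depends on (finite-difference Jacobians only probe those).
    ``x_dependent`` marks explicit space dependence (such terms have no
    well-mixed companion).
    """

    species: str
    fn: Callable
    pde_deps: Sequence[str] | None = None
    ode_deps: Sequence[str] | None = None
    x_dependent: bool = False


class ReactionNetwork:
    """Mass-action sublanguage plus arbitrary-rate escape hatch.

    ``reactions`` act among PDE species everywhere in the domain;
    ``ode_reactions`` act among ODE species inside their compartments.
    ``conserved`` optionally declares a composition vector (per-species
    weights) that must annihilate the stoichiometry of every reaction.
    """

    def __init__(
        self,
        pde_species: Sequence[str],
        ode_species: Sequence[str] = (),
        reactions: Sequence[Reaction] = (),
        ode_reactions: Sequence[Reaction] = (),
        extra_pde: Sequence[RateTerm] = (),
        extra_ode: Sequence[RateTerm] = (),
        conserved: dict[str, float] | None = None,
    ):
        self.pde_species = list(pde_species)
        self.ode_species = list(ode_species)
        self.reactions = list(reactions)
        self.ode_reactions = list(ode_reactions)
        self.extra_pde = list(extra_pde)
        self.extra_ode = list(extra_ode)
        self.conserved = dict(conserved) if conserved else None
        self._pidx = {s: i for i, s in enumerate(self.pde_species)}
        self._oidx = {s: i for i, s in enumerate(self.ode_species)}
        self._stoich, self._orders = self._tabulate(self.reactions, self._pidx)
        self._ostoich, self._oorders = self._tabulate(self.ode_reactions, self._oidx)
        for term in self.extra_pde:
            if term.species not in self._pidx:
                raise ModelError(f"extra rate references unknown pde species {term.species!r}")
        for term in self.extra_ode:
            if term.species not in self._oidx:
                raise ModelError(f"extra rate references unknown ode species {term.species!r}")
        if self.conserved is not None:
            self.check_conservative()

    @staticmethod
    def _tabulate(reactions, index):
        R, S = len(reactions), len(index)
        stoich = np.zeros((S, R))
        orders = np.zeros((S, R))
        for j, rx in enumerate(reactions):
            for sp, nu in rx.reactants.items():
                if sp not in index:
                    raise ModelError(f"reaction references unknown species {sp!r}")
                orders[index[sp], j] += nu
                stoich[index[sp], j] -= nu
            for sp, nu in rx.products.items():
                if sp not in index:
                    raise ModelError(f"reaction references unknown species {sp!r}")
                stoich[index[sp], j] += nu
        return stoich, orders

    def check_conservative(self) -> None:
        w_p = np.array([self.conserved.get(s, 0.0) for s in self.pde_species])
        w_o = np.array([self.conserved.get(s, 0.0) for s in self.ode_species])
        for stoich, w, what in ((self._stoich, w_p, "pde"), (self._ostoich, w_o, "ode")):
            if stoich.size and np.max(np.abs(w @ stoich)) > 1e-12:
                raise ModelError(
                    f"declared composition vector does not annihilate the {what} stoichiometry"
                )

    # -- mass-action evaluation ---------------------------------------------

    @staticmethod
    def _ma_rates(conc: np.ndarray, orders: np.ndarray, ks: np.ndarray) -> np.ndarray:
        """conc (N, S) -> reaction rates (N, R)."""
        N = conc.shape[0]
        R = orders.shape[1]
        rates = np.tile(ks, (N, 1))
        for s, j in zip(*np.nonzero(orders)):
            rates[:, j] *= conc[:, s] ** orders[s, j]
        return rates

    def production(self, t: float, X: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Nodal production rates rho (N, P) for all PDE species."""
        N = U.shape[0]
        out = np.zeros((N, len(self.pde_species)))
        if self.reactions:
            ks = np.array([rx.rate_constant for rx in self.reactions])
            rates = self._ma_rates(U, self._orders, ks)
            out += rates @ self._stoich.T
        for term in self.extra_pde:
            out[:, self._pidx[term.species]] += term.fn(t, X, U, V)
        return out

    def production_jac(self, t, X, U, V, eps: float = 1e-7):
        """(d rho/d U) as (N, P, P) and (d rho/d V) as (N, P, Q).

        Mass-action parts are analytic; extra terms are probed by central
        finite differences over their declared dependencies.
        """
        N, P = U.shape
        Q = len(self.ode_species)
        JU = np.zeros((N, P, P))
        JV = np.zeros((N, P, Q))
        if self.reactions:
            ks = np.array([rx.rate_constant for rx in self.reactions])
            for k in range(P):  # d rates / d U_k, analytic power rule
                orders_k = self._orders[k]
                if not np.any(orders_k):
                    continue
                dr = np.zeros((N, len(self.reactions)))
                for j in np.nonzero(orders_k)[0]:
                    d = np.tile(ks[j], N)
                    for s in np.nonzero(self._orders[:, j])[0]:
                        nu = self._orders[s, j]
                        if s == k:
                            d = d * nu * _safe_pow(U[:, s], nu - 1)
                        else:
                            d = d * U[:, s] ** nu
                    dr[:, j] = d
                JU[:, :, k] += dr @ self._stoich.T
        for term in self.extra_pde:
            i = self._pidx[term.species]
            pdeps = (
                [self._pidx[s] for s in term.pde_deps]
                if term.pde_deps is not None
                else range(P)
            )
            odeps = (
                [self._oidx[s] for s in term.ode_deps]
                if term.ode_deps is not None
                else range(Q)
            )
            for k in pdeps:
                dU = np.zeros_like(U)
                step = eps * (1.0 + np.abs(U[:, k]))
                dU[:, k] = step
                JU[:, i, k] += (term.fn(t, X, U + dU, V) - term.fn(t, X, U - dU, V)) / (2 * step)
            for q in odeps:
                dV = np.zeros_like(V)
                step = eps * (1.0 + abs(V[q]))
                dV[q] = step
                JV[:, i, q] += (term.fn(t, X, U, V + dV) - term.fn(t, X, U, V - dV)) / (2 * step)
        return JU, JV

    def ode_production(self, t: float, ubar: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Compartment production rates (Q,).

        ``ubar`` is (Q, P): row j holds the surface averages seen by ODE
        species j's compartment.
        """
        Q = len(self.ode_species)
        out = np.zeros(Q)
        if self.ode_reactions:
            ks = np.array([rx.rate_constant for rx in self.ode_reactions])
            rates = self._ma_rates(V[None, :], self._oorders, ks)
            out += (rates @ self._ostoich.T)[0]
        for term in self.extra_ode:
            j = self._oidx[term.species]
            out[j] += term.fn(t, ubar[j], V)
        return out

    def ode_production_jac(self, t, ubar, V, eps: float = 1e-7):
        """(d h/d ubar) per (j, p) and (d h/d V) as (Q, Q)."""
        Q = len(self.ode_species)
        P = len(self.pde_species)
        JU = np.zeros((Q, P))
        JV = np.zeros((Q, Q))
        if self.ode_reactions:
            ks = np.array([rx.rate_constant for rx in self.ode_reactions])
            for k in range(Q):
                orders_k = self._oorders[k]
                if not np.any(orders_k):
                    continue
                dr = np.zeros(len(self.ode_reactions))
                for j in np.nonzero(orders_k)[0]:
                    d = ks[j]
                    for s in np.nonzero(self._oorders[:, j])[0]:
                        nu = self._oorders[s, j]
                        if s == k:
                            d = d * nu * _safe_pow(np.array([V[s]]), nu - 1)[0]
                        else:
                            d = d * V[s] ** nu
                    dr[j] = d
                JV[:, k] += self._ostoich @ dr
        for term in self.extra_ode:
            j = self._oidx[term.species]
            pdeps = (
                [self._pidx[s] for s in term.pde_deps]
                if term.pde_deps is not None
                else range(P)
            )
            odeps = (
                [self._oidx[s] for s in term.ode_deps]
                if term.ode_deps is not None
                else range(Q)
            )
            for p in pdeps:
                db = np.zeros(P)
                step = eps * (1.0 + abs(ubar[j, p]))
                db[p] = step
                JU[j, p] += (term.fn(t, ubar[j] + db, V) - term.fn(t, ubar[j] - db, V)) / (2 * step)
            for q in odeps:
                dV = np.zeros(Q)
                step = eps * (1.0 + abs(V[q]))
                dV[q] = step
                JV[j, q] += (term.fn(t, ubar[j], V + dV) - term.fn(t, ubar[j], V - dV)) / (2 * step)
        return JU, JV

    @property
    def x_dependent(self) -> bool:
        return any(term.x_dependent for term in self.extra_pde)


def _safe_pow(x: np.ndarray, p: float) -> np.ndarray:
    """x**p with the convention 0**0 = 1 and 0**negative = 0 (for Jacobians)."""
    if p == 0:
        return np.ones_like(x)
    if p < 0:
        out = np.zeros_like(x)
        nz = x != 0
        out[nz] = x[nz] ** p
        return out
    return x ** p


# ---------------------------------------------------------------------------
# Boundary coupling
# ---------------------------------------------------------------------------


@dataclass
class BoundaryCoupling:
    """Robin flux for one PDE species on one tagged surface.

    ``flux(t, x, traces, V) -> (nb,)`` returns the influx density in
    molecules/(um^2 s); ``x`` are the coordinates of the boundary nodes,
    ``traces`` the (nb, P) matrix of all PDE species traces there, ``V`` the
    ODE vector.  ``receivers`` lists ``(ode_species, weight)`` pairs: each
    receiver gains ``weight * (-integral g ds) / V_compartment``.
    ``pde_deps`` / ``ode_deps`` restrict finite-difference Jacobians.
    """

    tag: int
    species: str
    flux: Callable
    receivers: Sequence[tuple[str, float]] = ()
    pde_deps: Sequence[str] | None = None
    ode_deps: Sequence[str] | None = None


# ---------------------------------------------------------------------------
# Model definition and state
# ---------------------------------------------------------------------------


@dataclass
class ModelDefinition:
    """Complete coupled PDE/ODE model on a tagged mesh."""

    mesh: Mesh
    species: list[SpeciesSpec]
    compartments: dict[str, Compartment]
    network: ReactionNetwork
    couplings: list[BoundaryCoupling]
    initial: dict[str, float | np.ndarray | Callable]
    T: float
    composition: dict[str, float] | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def pde_names(self) -> list[str]:
        return [s.name for s in self.species if s.kind == "pde"]

    @property
    def ode_names(self) -> list[str]:
        return [s.name for s in self.species if s.kind == "ode"]

    def species_by_name(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise ModelError(f"unknown species {name!r}")

    def ode_volumes(self) -> np.ndarray:
        return np.array(
            [self.compartments[self.species_by_name(n).compartment].volume for n in self.ode_names]
        )

    def validate(self) -> None:
        if not (0.0 <= self.T < np.inf):
            raise ModelError("time horizon must satisfy 0 <= T < inf")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species names")
        tags = set(self.mesh.boundary_tags())
        for c in self.couplings:
            if c.tag not in tags:
                raise ModelError(f"coupling references missing boundary tag {c.tag}")
            if c.species not in self.pde_names:
                raise ModelError(f"coupling references non-pde species {c.species!r}")
            for ode_name, _ in c.receivers:
                if ode_name not in self.ode_names:
                    raise ModelError(f"coupling receiver {ode_name!r} is not an ode species")
        for s in self.species:
            if s.kind == "ode" and s.compartment not in self.compartments:
                raise ModelError(f"species {s.name!r} references unknown compartment")
        for comp in self.compartments.values():
            if comp.surface_tag is not None and comp.surface_tag not in tags:
                raise ModelError(
                    f"compartment {comp.name!r} references missing tag {comp.surface_tag}"
                )
        if set(self.network.pde_species) != set(self.pde_names) or set(
            self.network.ode_species
        ) != set(self.ode_names):
            raise ModelError("network species do not match the model species")
        for name in self.initial:
            if name not in names:
                raise ModelError(f"initial condition for unknown species {name!r}")

    def initial_state(self) -> "State":
        X = self.mesh.nodes
        fields = {}
        for name in self.pde_names:
            ic = self.initial.get(name, 0.0)
            if callable(ic):
                fields[name] = np.asarray(ic(X), dtype=float)
            else:
                fields[name] = np.full(self.mesh.n_nodes, float(np.asarray(ic)))
                if np.ndim(ic) == 1:
                    fields[name] = np.asarray(ic, dtype=float).copy()
        ode = {name: float(self.initial.get(name, 0.0)) for name in self.ode_names}
        return State(t=0.0, fields=fields, ode=ode)


@dataclass
class State:
    """Concentrations at one time point: nodal PDE fields + ODE scalars."""

    t: float
    fields: dict[str, np.ndarray]
    ode: dict[str, float]

    def copy(self) -> "State":
        return State(
            t=self.t,
            fields={k: v.copy() for k, v in self.fields.items()},
            ode=dict(self.ode),
        )

    def validate(self, model: ModelDefinition) -> None:
        if not np.isfinite(self.t):
            raise ModelError("state time must be finite")
        for name in model.pde_names:
            if self.fields[name].shape != (model.mesh.n_nodes,):
                raise ModelError(f"field {name!r} shape does not match mesh")
        for name in model.ode_names:
            if name not in self.ode:
                raise ModelError(f"missing ode value {name!r}")


# ---------------------------------------------------------------------------
# Standalone quadrature-consistent operations
# ---------------------------------------------------------------------------


def lumped_mass_vector(mesh: Mesh) -> np.ndarray:
    """Row sums of the P1 mass matrix: nodal quadrature weights, summing to |Omega|."""
    vols = mesh.element_volumes()
    w = np.zeros(mesh.n_nodes)
    for k in range(mesh.dim + 1):
        np.add.at(w, mesh.elements[:, k], vols / (mesh.dim + 1))
    return w


def boundary_lumped_vector(mesh: Mesh, tag: int) -> np.ndarray:
    """Nodal quadrature weights on the tagged surface, summing to |Gamma_tag|."""
    sel = mesh.facet_tags == tag
    facets = mesh.boundary_facets[sel]
    areas = mesh.facet_areas()[sel]
    b = np.zeros(mesh.n_nodes)
    for k in range(mesh.dim):
        np.add.at(b, facets[:, k], areas / mesh.dim)
    return b


def surface_average(mesh: Mesh, field: np.ndarray | State, tag: int,
                    species: str | None = None) -> float:
    """(1/|Gamma|) integral of the field over the tagged surface.

    Uses the same nodal quadrature as the boundary assembly, so values feed
    consistently into compartment ODEs.
    """
    if isinstance(field, State):
        if species is None:
            raise ModelError("species name required when passing a State")
        field = field.fields[species]
    b = boundary_lumped_vector(mesh, tag)
    area = b.sum()
    if area <= 0:
        raise ModelError(f"boundary tag {tag} has zero total area")
    return float(b @ field / area)


def evaluate_rates(state: State, network: ReactionNetwork,
                   X: np.ndarray | None = None) -> dict[str, np.ndarray | float]:
    """Production rates (du/dt contributions) for every species in the network."""
    U = np.column_stack([state.fields[s] for s in network.pde_species]) if network.pde_species else np.zeros((1, 0))
    V = np.array([state.ode[s] for s in network.ode_species])
    if X is None:
        X = np.zeros((U.shape[0], 3))
    rho = network.production(state.t, X, U, V)
    out: dict[str, np.ndarray | float] = {
        s: rho[:, i] for i, s in enumerate(network.pde_species)
    }
    Q = len(network.ode_species)
    if Q:
        ubar = np.zeros((Q, max(len(network.pde_species), 1)))
        h = network.ode_production(state.t, ubar, V)
        out.update({s: float(h[j]) for j, s in enumerate(network.ode_species)})
    return out


def total_mass(model: ModelDefinition, state: State,
               composition: dict[str, float] | None = None) -> float:
    """sum_i w_i integral(u_i) + sum_j w_j V_j u_j in molecules."""
    comp = composition if composition is not None else model.composition
    if comp is None:
        comp = {s.name: 1.0 for s in model.species}
    w = lumped_mass_vector(model.mesh)
    out = 0.0
    for name in model.pde_names:
        out += comp.get(name, 0.0) * float(w @ state.fields[name])
    vols = model.ode_volumes()
    for j, name in enumerate(model.ode_names):
        out += comp.get(name, 0.0) * vols[j] * state.ode[name]
    return out
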