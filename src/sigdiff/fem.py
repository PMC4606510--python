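"""Galerkin finite-element discretization and time integration.

Space: P1 (linear) simplex elements.  Time: Rothe method — implicit theta
scheme (backward Euler, theta=1, or Crank-Nicolson, theta=1/2) with either a
monolithic Newton solve of the coupled PDE/ODE system per step or a
segregated (operator-splitting) sweep that alternates the PDE and ODE
blocks.  Adaptive step control uses step doubling with a standard
safety-factor controller.

Discrete structure per step (theta scheme, unknown U = all nodal fields
stacked plus the ODE scalars):

    M (u - u_old)/dt + theta F(t_new, U) + (1-theta) F(t_old, U_old) = 0

where F collects stiffness, reaction (group-FE with row-sum lumping of the
reaction quadrature, which makes declared conservation exact), and the
lumped Robin boundary terms.  ODE compartments receive the *same* nodal
quadrature of the boundary flux that the PDE side sees, so every declared
exchange conserves mass to solver precision.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh
from .model import (
    BoundaryCoupling,
    ModelDefinition,
    State,
    boundary_lumped_vector,
    total_mass,
)

_THETA = {"backward_euler": 1.0, "crank_nicolson": 0.5}
_ORDER = {"backward_euler": 1, "crank_nicolson": 2}


class SolverError(RuntimeError):
    """Unrecoverable integration failure."""


class StepFailure(RuntimeError):
    """A single implicit step failed (Newton/fixed point divergence); retryable."""


class AssemblyError(ValueError):
    """Mesh/model cannot be assembled."""


@dataclass
class SolverConfig:
    """Time integration configuration.

    ``adapt_tol`` is the target local error per step, measured in a weighted
    RMS norm that is relative per species: each component is scaled by
    ``adapt_atol * max|species| + |component|``, so species living on very
    different magnitudes (receptor counts vs picomolar fields) are
    controlled on their own scale.  The controller is
    dt' = clip(0.9 dt (tol/err)^(1/(p+1)), dt_min, dt_max).
    """

    scheme: str = "backward_euler"
    mode: str = "fully_coupled"
    dt_init: float = 10.0
    dt_min: float = 1e-6
    dt_max: float = 600.0
    adaptive: bool = True
    adapt_tol: float = 1e-4
    adapt_atol: float = 1e-2
    newton_tol: float = 1e-11
    newton_max_iter: int = 25
    segregated_sweeps: int = 1
    linear_solver: str = "direct"
    max_rejects: int = 40
    rng_seed: int = 0
    #: optional per-species absolute error scales (CVODE-style atol); species
    #: listed here are controlled against this fixed floor instead of a
    #: fraction of their current magnitude — essential when a field grows
    #: from zero through a singular start-up (point-source secretion)
    species_atol: dict | None = None

    def __post_init__(self):
        if self.scheme not in _THETA:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.mode not in ("segregated", "fully_coupled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt_init <= dt_max")
        if self.adapt_tol <= 0 or self.newton_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def theta(self) -> float:
        return _THETA[self.scheme]

    @property
    def order(self) -> int:
        return _ORDER[self.scheme]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class DiscreteOperators:
    """Assembled P1 operators for one model on one mesh."""

    M: sp.csr_matrix
    Ml: np.ndarray
    K: dict[str, sp.csr_matrix]
    boundary: dict[int, np.ndarray]  # lumped surface quadrature vectors per tag
    areas: dict[int, float]
    volume: float
    grads: np.ndarray  # (n_elem, d+1, d) P1 shape gradients
    vols: np.ndarray

    def boundary_vector(self, tag: int) -> np.ndarray:
        return self.boundary[tag]


def _element_geometry(mesh: Mesh):
    vecs = mesh.nodes[mesh.elements[:, 1:]] - mesh.nodes[mesh.elements[:, :1]]
    dets = np.linalg.det(vecs)
    if np.any(dets <= 0):
        bad = int(np.argmin(dets))
        raise AssemblyError(f"element {bad} is inverted or degenerate (det={dets[bad]:.3e})")
    vols = dets / math.factorial(mesh.dim)
    inv = np.linalg.inv(vecs)
    gk = np.transpose(inv, (0, 2, 1))  # rows: grad of barycentric coords 1..d
    grads = np.concatenate([-gk.sum(axis=1, keepdims=True), gk], axis=1)
    return grads, vols


def _scatter(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    d1 = mesh.dim + 1
    rows = np.repeat(mesh.elements, d1, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, d1)).ravel()
    A = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes))
    return A.tocsr()


def assemble(mesh: Mesh, model: ModelDefinition) -> DiscreteOperators:
    """Assemble mass, per-species stiffness (+ advection), boundary weights.

    A diagonal diffusion tensor with equal entries reduces exactly to the
    scalar assembly; advection uses plain Galerkin and warns if the element
    Peclet number exceeds 1.
    """
    grads, vols = _element_geometry(mesh)
    d = mesh.dim
    d1 = d + 1
    Mloc = (np.ones((d1, d1)) + np.eye(d1)) / ((d1) * (d1 + 1.0))
    M = _scatter(mesh, vols[:, None, None] * Mloc[None, :, :])
    Ml = np.asarray(M.sum(axis=1)).ravel()
    K: dict[str, sp.csr_matrix] = {}
    for spec in model.species:
        if spec.kind != "pde":
            continue
        Dt = spec.diffusion_tensor(d)
        kloc = np.einsum("eid,d,ejd->eij", grads, Dt, grads) * vols[:, None, None]
        if spec.velocity is not None:
            v = np.asarray(spec.velocity, dtype=float)
            if v.shape != (d,):
                raise AssemblyError(f"velocity of {spec.name!r} must have {d} components")
            h_e = vols ** (1.0 / d)
            dmin = max(Dt.min(), 1e-300)
            peclet = float(np.max(h_e) * np.linalg.norm(v) / (2.0 * dmin))
            if peclet > 1.0:
                warnings.warn(
                    f"element Peclet number {peclet:.2f} > 1 for species "
                    f"{spec.name!r}; plain Galerkin advection may oscillate",
                    stacklevel=2,
                )
            vg = np.einsum("ejd,d->ej", grads, v)
            kloc = kloc + (vols / d1)[:, None, None] * vg[:, None, :]
        K[spec.name] = _scatter(mesh, kloc)
    tags = {c.tag for c in model.couplings}
    tags |= {
        comp.surface_tag
        for comp in model.compartments.values()
        if comp.surface_tag is not None
    }
    boundary = {tag: boundary_lumped_vector(mesh, tag) for tag in tags}
    areas = {tag: float(b.sum()) for tag, b in boundary.items()}
    for tag, a in areas.items():
        if a <= 0:
            raise AssemblyError(f"boundary tag {tag} has zero area")
    return DiscreteOperators(
        M=M,
        Ml=Ml,
        K=K,
        boundary=boundary,
        areas=areas,
        volume=float(vols.sum()),
        grads=grads,
        vols=vols,
    )


# ---------------------------------------------------------------------------
# Quadrature utilities (diagnostics / verification)
# ---------------------------------------------------------------------------

_QUAD_BARY = {
    2: (
        np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]]),
        np.array([1.0 / 3.0] * 3),
    ),
    3: (
        np.array(
            [
                [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
                [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
                [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
                [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
            ]
        ),
        np.array([0.25] * 4),
    ),
}


def l2_norm(mesh: Mesh, nodal: np.ndarray) -> float:
    bary, w = _QUAD_BARY[mesh.dim]
    vols = mesh.element_volumes()
    vals = nodal[mesh.elements] @ bary.T  # (n_e, nq)
    return math.sqrt(float(np.einsum("q,eq,e->", w, vals**2, vols)))


def l2_error(mesh: Mesh, nodal: np.ndarray, exact, t: float | None = None) -> float:
    """||u_h - u*||_L2 with a degree-2 quadrature; ``exact(X)`` or ``exact(t, X)``."""
    bary, w = _QUAD_BARY[mesh.dim]
    vols = mesh.element_volumes()
    pts = np.einsum("qk,ekd->eqd", bary, mesh.nodes[mesh.elements])
    flat = pts.reshape(-1, mesh.dim)
    ex = exact(flat) if t is None else exact(t, flat)
    ex = np.asarray(ex, dtype=float).reshape(pts.shape[0], pts.shape[1])
    vals = nodal[mesh.elements] @ bary.T
    return math.sqrt(float(np.einsum("q,eq,e->", w, (vals - ex) ** 2, vols)))


# ---------------------------------------------------------------------------
# The coupled stepper
# ---------------------------------------------------------------------------


class _CompiledCoupling:
    def __init__(self, c: BoundaryCoupling, mesh: Mesh, ops: DiscreteOperators,
                 pidx: dict[str, int], oidx: dict[str, int]):
        self.tag = c.tag
        self.sp = pidx[c.species]
        b = ops.boundary[c.tag]
        self.nodes = np.nonzero(b > 0)[0]
        self.b = b[self.nodes]
        self.x = mesh.nodes[self.nodes]
        self.flux = c.flux
        self.receivers = [(oidx[name], float(w)) for name, w in c.receivers]
        self.pde_deps = (
            [pidx[s] for s in c.pde_deps] if c.pde_deps is not None else [self.sp]
        )
        self.ode_deps = (
            [oidx[s] for s in c.ode_deps]
            if c.ode_deps is not None
            else list(range(len(oidx)))
        )


class Stepper:
    """Implicit theta-scheme stepper for one assembled model."""

    def __init__(self, model: ModelDefinition, ops: DiscreteOperators, config: SolverConfig):
        self.model = model
        self.ops = ops
        self.config = config
        self.mesh = model.mesh
        self.pde = model.pde_names
        self.ode = model.ode_names
        self.P, self.Q, self.N = len(self.pde), len(self.ode), model.mesh.n_nodes
        self.pidx = {s: i for i, s in enumerate(self.pde)}
        self.oidx = {s: j for j, s in enumerate(self.ode)}
        self.vols = model.ode_volumes() if self.Q else np.zeros(0)
        self.couplings = [
            _CompiledCoupling(c, model.mesh, ops, self.pidx, self.oidx)
            for c in model.couplings
        ]
        # surface over which each ODE species' compartment averages the traces
        self.comp_tag = []
        for name in self.ode:
            comp = model.compartments[model.species_by_name(name).compartment]
            self.comp_tag.append(comp.surface_tag)
        self.X = model.mesh.nodes
        self._base_cache: dict[tuple, list] = {}
        self._lu_cache: dict[tuple, object] = {}

    # -- packing ------------------------------------------------------------

    def pack(self, state: State) -> np.ndarray:
        parts = [state.fields[s] for s in self.pde]
        parts.append(np.array([state.ode[s] for s in self.ode]))
        return np.concatenate(parts)

    def unpack(self, vec: np.ndarray, t: float) -> State:
        fields = {
            s: vec[i * self.N : (i + 1) * self.N].copy() for i, s in enumerate(self.pde)
        }
        ode = {s: float(vec[self.P * self.N + j]) for j, s in enumerate(self.ode)}
        return State(t=t, fields=fields, ode=ode)

    def _split(self, vec):
        U = vec[: self.P * self.N].reshape(self.P, self.N).T  # (N, P)
        V = vec[self.P * self.N :]
        return U, V

    # -- pieces of the spatial operator F ------------------------------------

    def _ubar(self, U: np.ndarray) -> np.ndarray:
        """(Q, P) surface averages seen by each ODE species' compartment."""
        out = np.zeros((self.Q, self.P))
        for j, tag in enumerate(self.comp_tag):
            if tag is None:
                continue
            b = self.ops.boundary[tag]
            out[j] = b @ U / self.ops.areas[tag]
        return out

    def _coupling_values(self, t, U, V, Vflux=None):
        """Flux values per coupling; Vflux optionally overrides the ODE vector
        the fluxes see (used by the segregated ODE stage)."""
        Vf = V if Vflux is None else Vflux
        vals = []
        for c in self.couplings:
            traces = U[c.nodes, :]
            vals.append(np.asarray(c.flux(t, c.x, traces, Vf), dtype=float))
        return vals

    def spatial_residual(self, t, U, V, Vflux=None):
        """F(t, U, V): (N, P) PDE part and (Q,) ODE part (time-derivative signs)."""
        FP = np.zeros((self.N, self.P))
        for i, s in enumerate(self.pde):
            FP[:, i] = self.ops.K[s] @ U[:, i]
        rho = self.model.network.production(t, self.X, U, V)
        FP -= self.ops.Ml[:, None] * rho
        FO = np.zeros(self.Q)
        if self.Q:
            ubar = self._ubar(U)
            FO -= self.model.network.ode_production(t, ubar, V)
        gvals = self._coupling_values(t, U, V, Vflux)
        for c, g in zip(self.couplings, gvals):
            FP[c.nodes, c.sp] -= c.b * g
            if c.receivers:
                flux_int = float(c.b @ g)
                for j, w in c.receivers:
                    FO[j] -= w * (-flux_int) / self.vols[j]
        return FP, FO

    # -- Jacobian -------------------------------------------------------------

    def _base_blocks(self, dt, theta):
        key = (dt, theta)
        if key not in self._base_cache:
            blocks = []
            for s in self.pde:
                A = (self.ops.M / dt + theta * self.ops.K[s]).tocoo()
                blocks.append((A.row, A.col, A.data))
            self._base_cache[key] = blocks
            if len(self._base_cache) > 8:
                self._base_cache.pop(next(iter(self._base_cache)))
        return self._base_cache[key]

    def jacobian(self, t, U, V, dt, theta, pde_only=False):
        N, P, Q = self.N, self.P, self.Q
        n = N * P + (0 if pde_only else Q)
        rows, cols, data = [], [], []
        base = self._base_blocks(dt, theta)
        for i in range(P):
            r, c, d = base[i]
            rows.append(r + i * N)
            cols.append(c + i * N)
            data.append(d)
        JU, JV = self.model.network.production_jac(t, self.X, U, V)
        idx = np.arange(N)
        for i in range(P):
            for k in range(P):
                col = JU[:, i, k]
                if np.any(col):
                    rows.append(idx + i * N)
                    cols.append(idx + k * N)
                    data.append(-theta * self.ops.Ml * col)
            if not pde_only:
                for q in range(Q):
                    col = JV[:, i, q]
                    if np.any(col):
                        rows.append(idx + i * N)
                        cols.append(np.full(N, P * N + q))
                        data.append(-theta * self.ops.Ml * col)
        # boundary couplings: finite differences over declared dependencies
        eps = 1e-7
        for c in self.couplings:
            traces = U[c.nodes, :]
            for k in c.pde_deps:
                step = eps * (1.0 + np.abs(traces[:, k]))
                tp = traces.copy()
                tp[:, k] += step
                tm = traces.copy()
                tm[:, k] -= step
                dg = (
                    np.asarray(c.flux(t, c.x, tp, V)) - np.asarray(c.flux(t, c.x, tm, V))
                ) / (2 * step)
                if not np.any(dg):
                    continue
                rows.append(c.nodes + c.sp * N)
                cols.append(c.nodes + k * N)
                data.append(-theta * c.b * dg)
                if not pde_only and c.receivers:
                    # FO gains +w*flux_int/V, so these rows enter with +theta
                    for j, w in c.receivers:
                        rows.append(np.full(c.nodes.size, P * N + j))
                        cols.append(c.nodes + k * N)
                        data.append(theta * w / self.vols[j] * c.b * dg)
            if not pde_only:
                for q in c.ode_deps:
                    step = eps * (1.0 + abs(V[q]))
                    Vp = V.copy()
                    Vp[q] += step
                    Vm = V.copy()
                    Vm[q] -= step
                    dg = (
                        np.asarray(c.flux(t, c.x, traces, Vp))
                        - np.asarray(c.flux(t, c.x, traces, Vm))
                    ) / (2 * step)
                    if not np.any(dg):
                        continue
                    rows.append(c.nodes + c.sp * N)
                    cols.append(np.full(c.nodes.size, P * N + q))
                    data.append(-theta * c.b * dg)
                    for j, w in c.receivers:
                        rows.append(np.array([P * N + j]))
                        cols.append(np.array([P * N + q]))
                        data.append(np.array([theta * w / self.vols[j] * float(c.b @ dg)]))
        if not pde_only and Q:
            ubar = self._ubar(U)
            JHu, JHv = self.model.network.ode_production_jac(t, ubar, V)
            for j in range(Q):
                tag = self.comp_tag[j]
                if tag is not None:
                    bavg = self.ops.boundary[tag] / self.ops.areas[tag]
                    nz = np.nonzero(bavg)[0]
                    for k in range(P):
                        if JHu[j, k]:
                            rows.append(np.full(nz.size, P * N + j))
                            cols.append(nz + k * N)
                            data.append(-theta * JHu[j, k] * bavg[nz])
                for q in range(Q):
                    val = 1.0 / dt if q == j else 0.0
                    val -= theta * JHv[j, q]
                    if val:
                        rows.append(np.array([P * N + j]))
                        cols.append(np.array([P * N + q]))
                        data.append(np.array([val]))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    # -- Newton ---------------------------------------------------------------

    def _factorize(self, J):
        try:
            return splu(J.tocsc())
        except RuntimeError as exc:
            raise StepFailure(f"linear solve failed: {exc}") from exc

    def _store_lu(self, cache_key, lu) -> None:
        if cache_key is None:
            return
        # adaptive runs produce a fresh dt (hence key) per step: keep the
        # cache tiny or factorizations accumulate without bound
        self._lu_cache[cache_key] = lu
        while len(self._lu_cache) > 4:
            self._lu_cache.pop(next(iter(self._lu_cache)))

    def _newton(self, vec0, residual_fn, jac_fn, cache_key=None):
        """Modified Newton: the LU factorization is cached per (dt, block)
        and refreshed only when the iteration stalls, which makes linear and
        mildly nonlinear steps cost one back-substitution each."""
        cfg = self.config
        vec = vec0.copy()
        R = residual_fn(vec)
        ref = max(np.linalg.norm(R), 1e-300)
        unorm = np.linalg.norm(vec) + 1.0
        if ref <= 1e-15 * unorm:
            return vec, 0, ref
        lu = self._lu_cache.get(cache_key) if cache_key is not None else None
        lu_age = 1
        if lu is None:
            lu = self._factorize(jac_fn(vec))
            lu_age = 0
            self._store_lu(cache_key, lu)
        prev = np.inf
        for it in range(1, cfg.newton_max_iter + 1):
            delta = lu.solve(-R)
            # backtracking keeps overshooting full steps from diverging
            lam = 1.0
            for _ in range(5):
                cand = vec + lam * delta
                Rc = residual_fn(cand)
                rnorm = np.linalg.norm(Rc)
                if np.isfinite(rnorm) and (rnorm <= prev or lam <= 0.1):
                    break
                lam *= 0.5
            if not np.isfinite(rnorm):
                raise StepFailure("Newton residual became non-finite")
            vec, R = cand, Rc
            unorm = np.linalg.norm(vec) + 1.0
            if rnorm <= cfg.newton_tol * ref + 1e-14 * unorm or (
                lam * np.linalg.norm(delta) <= 1e-13 * unorm
            ):
                return vec, it, rnorm
            if rnorm > 0.3 * prev and lu_age > 0:
                lu = self._factorize(jac_fn(vec))
                lu_age = 0
                self._store_lu(cache_key, lu)
            else:
                lu_age += 1
            prev = rnorm
        raise StepFailure(f"Newton did not converge in {cfg.newton_max_iter} iterations")

    # -- full step -------------------------------------------------------------

    def step_fully_coupled(self, state: State, dt: float):
        theta = self.config.theta
        t0, t1 = state.t, state.t + dt
        vec0 = self.pack(state)
        U0, V0 = self._split(vec0)
        FP0, FO0 = (
            self.spatial_residual(t0, U0, V0) if theta < 1.0 else (None, None)
        )

        def residual(vec):
            U, V = self._split(vec)
            FP, FO = self.spatial_residual(t1, U, V)
            RP = (self.ops.M @ (U - U0)) / dt + theta * FP
            RO = (V - V0) / dt + theta * FO
            if theta < 1.0:
                RP = RP + (1.0 - theta) * FP0
                RO = RO + (1.0 - theta) * FO0
            return np.concatenate([RP.T.ravel(), RO])

        def jac(vec):
            U, V = self._split(vec)
            return self.jacobian(t1, U, V, dt, theta)

        vec, iters, rnorm = self._newton(vec0, residual, jac, cache_key=("full", dt))
        new = self.unpack(vec, t1)
        return new, {"newton_iters": iters, "residual": rnorm}

    # -- segregated step --------------------------------------------------------

    def step_segregated(self, state: State, dt: float):
        """Splitting step: PDE with frozen ODE values, then compartment ODEs.

        The ODE stage evaluates the exchange fluxes at exactly the frozen ODE
        iterate the PDE stage used (explicit in the ODE unknowns, implicit in
        the traces), so the exchange bookkeeping conserves mass identically;
        the compartment kinetics remain implicit.  Optional extra sweeps
        iterate the pair toward the monolithic fixed point.
        """
        theta = self.config.theta
        t0, t1 = state.t, state.t + dt
        vec0 = self.pack(state)
        U0, V0 = self._split(vec0)
        FP0, FO0 = (
            self.spatial_residual(t0, U0, V0) if theta < 1.0 else (None, None)
        )
        Vwork = V0.copy()
        total_iters = 0
        for _ in range(max(1, self.config.segregated_sweeps)):
            # PDE stage, ODE values frozen at Vwork
            def residual_p(uvec, Vw=Vwork):
                U = uvec.reshape(self.P, self.N).T
                FP, _ = self.spatial_residual(t1, U, Vw)
                RP = (self.ops.M @ (U - U0)) / dt + theta * FP
                if theta < 1.0:
                    RP = RP + (1.0 - theta) * FP0
                return RP.T.ravel()

            def jac_p(uvec, Vw=Vwork):
                U = uvec.reshape(self.P, self.N).T
                return self.jacobian(t1, U, Vw, dt, theta, pde_only=True)

            uvec, it_p, _ = self._newton(
                vec0[: self.P * self.N], residual_p, jac_p, cache_key=("pde", dt)
            )
            U1 = uvec.reshape(self.P, self.N).T
            # ODE stage: exchange fluxes pinned at (U1, Vwork), kinetics implicit
            gnew = self._coupling_values(t1, U1, V0, Vflux=Vwork)
            exch = np.zeros(self.Q)
            for c, g in zip(self.couplings, gnew):
                for j, w in c.receivers:
                    exch[j] += w * (-float(c.b @ g)) / self.vols[j]
            ubar1 = self._ubar(U1)

            def residual_o(V):
                H = self.model.network.ode_production(t1, ubar1, V) + exch
                RO = (V - V0) / dt - theta * H
                if theta < 1.0:
                    RO = RO + (1.0 - theta) * FO0
                return RO

            def jac_o(V):
                _, JHv = self.model.network.ode_production_jac(t1, ubar1, V)
                J = np.eye(self.Q) / dt - theta * JHv
                return sp.csr_matrix(J)

            if self.Q:
                Vnew, it_o, _ = self._newton(V0.copy(), residual_o, jac_o)
            else:
                Vnew, it_o = V0, 0
            total_iters += it_p + it_o
            if np.allclose(Vnew, Vwork, rtol=1e-14, atol=1e-300):
                Vwork = Vnew
                break
            Vwork = Vnew
        vec = np.concatenate([U1.T.ravel(), Vwork])
        new = self.unpack(vec, t1)
        return new, {"newton_iters": total_iters, "residual": 0.0}

    def step(self, state: State, dt: float):
        if self.config.mode == "fully_coupled":
            return self.step_fully_coupled(state, dt)
        return self.step_segregated(state, dt)


# Public single-step wrappers --------------------------------------------------


def step_fully_coupled(state: State, dt: float, ops: DiscreteOperators,
                       model: ModelDefinition, config: SolverConfig):
    """One monolithic implicit step; returns (new_state, metadata)."""
    return Stepper(model, ops, config).step_fully_coupled(state, dt)


def step_segregated(state: State, dt: float, ops: DiscreteOperators,
                    model: ModelDefinition, config: SolverConfig):
    """One operator-splitting step; returns (new_state, metadata)."""
    return Stepper(model, ops, config).step_segregated(state, dt)


def adapt_timestep(err_est: float, dt: float, config: SolverConfig,
                   order: int | None = None) -> float:
    """Safety-factor controller: dt' = clip(0.9 dt (tol/err)^(1/(p+1)), dt_min, dt_max)."""
    if err_est < 0:
        raise ValueError("error estimate must be nonnegative")
    p = config.order if order is None else order
    if err_est == 0.0:
        return config.dt_max
    fac = 0.9 * (config.adapt_tol / err_est) ** (1.0 / (p + 1))
    dt_new = dt * min(fac, 5.0)
    if dt_new < config.dt_min:
        raise SolverError(
            f"required time step {dt_new:.3e} fell below dt_min={config.dt_min:.3e}"
        )
    return float(min(dt_new, config.dt_max))


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-ordered states plus per-step metadata."""

    model: ModelDefinition
    config: SolverConfig
    states: list[State] = field(default_factory=list)
    step_meta: list[dict] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def ode_series(self, name: str) -> np.ndarray:
        return np.array([s.ode[name] for s in self.states])

    def field_matrix(self, name: str) -> np.ndarray:
        return np.vstack([s.fields[name] for s in self.states])

    def at_time(self, t: float) -> State:
        """State at time t by linear interpolation between stored steps."""
        times = self.times
        if t <= times[0]:
            return self.states[0].copy()
        if t >= times[-1]:
            return self.states[-1].copy()
        k = int(np.searchsorted(times, t))
        t0, t1 = times[k - 1], times[k]
        w = (t - t0) / (t1 - t0)
        s0, s1 = self.states[k - 1], self.states[k]
        fields = {
            n: (1 - w) * s0.fields[n] + w * s1.fields[n] for n in s0.fields
        }
        ode = {n: (1 - w) * s0.ode[n] + w * s1.ode[n] for n in s0.ode}
        return State(t=t, fields=fields, ode=ode)

    def sample(self, times: Sequence[float]) -> list[State]:
        return [self.at_time(t) for t in times]

    def mass_series(self, composition: dict[str, float] | None = None) -> np.ndarray:
        return np.array([total_mass(self.model, s, composition) for s in self.states])

    def summary_frame(self):
        """Per-time scalar summary (pandas DataFrame): ODE values, field means,
        surface averages are deliberately not included here (see diagnostics)."""
        import pandas as pd

        w = None
        rows = []
        from .model import lumped_mass_vector

        w = lumped_mass_vector(self.model.mesh)
        vol = w.sum()
        for s in self.states:
            row = {"t": s.t}
            for name, vals in s.fields.items():
                row[f"mean_{name}"] = float(w @ vals / vol)
                mx = float(vals.max())
                row[f"max_{name}"] = mx
                row[f"min_{name}"] = float(vals.min())
            for name, val in s.ode.items():
                row[name] = val
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def _wrms(stepper: Stepper, vec2: np.ndarray, vec1: np.ndarray, frac: float,
          species_atol: dict | None = None) -> float:
    """Weighted RMS of vec2-vec1 with per-species scaling.

    Each species block is weighted by ``atol_s + |component|`` where
    ``atol_s`` is the declared absolute scale for that species if given,
    else ``frac`` times the species' current max magnitude.
    """
    N, P, Q = stepper.N, stepper.P, stepper.Q
    names = stepper.pde + stepper.ode
    blocks = [slice(i * N, (i + 1) * N) for i in range(P)]
    blocks += [slice(P * N + j, P * N + j + 1) for j in range(Q)]
    atols = species_atol or {}
    err2, n = 0.0, 0
    for name, b in zip(names, blocks):
        if name in atols:
            floor = float(atols[name])
        else:
            s = max(np.max(np.abs(vec2[b])), np.max(np.abs(vec1[b])), 0.0)
            if s == 0.0:
                continue
            floor = frac * s
        d = floor + np.abs(vec2[b])
        err2 += float(np.sum(((vec2[b] - vec1[b]) / d) ** 2))
        n += vec2[b].size
    return math.sqrt(err2 / max(n, 1))


def solve(model: ModelDefinition, config: SolverConfig | None = None,
          record_mass: bool = True) -> Trajectory:
    """Integrate the coupled system over [0, T].

    Deterministic: no hidden randomness, so identical configurations produce
    bit-identical trajectories.  With ``adaptive`` the local error is
    estimated by step doubling and the refined (two half-step) solution is
    carried forward.
    """
    config = config or SolverConfig()
    ops = assemble(model.mesh, model)
    stepper = Stepper(model, ops, config)
    state = model.initial_state()
    state.validate(model)
    traj = Trajectory(model=model, config=config)
    mass0 = total_mass(model, state) if record_mass and model.composition else None
    traj.states.append(state.copy())
    traj.step_meta.append(
        {"dt": 0.0, "newton_iters": 0, "residual": 0.0, "err_est": 0.0,
         "conservation_residual": 0.0, "rejects": 0}
    )
    t, T = 0.0, model.T
    dt = min(config.dt_init, T) if T > 0 else config.dt_init
    rejects_total = 0
    while t < T - 1e-12 * max(T, 1.0):
        dt = min(dt, T - t)
        if not config.adaptive:
            new, meta = stepper.step(state, dt)
            err = 0.0
        else:
            rejects = 0
            while True:
                try:
                    full, meta1 = stepper.step(state, dt)
                    half, meta2 = stepper.step(state, dt / 2)
                    new, meta3 = stepper.step(half, dt / 2)
                    meta = {
                        "newton_iters": meta1["newton_iters"]
                        + meta2["newton_iters"]
                        + meta3["newton_iters"],
                        "residual": meta3["residual"],
                    }
                    denom = 2**config.order - 1
                    err = _wrms(stepper, stepper.pack(new), stepper.pack(full),
                                config.adapt_atol, config.species_atol) / denom
                except StepFailure:
                    err = None
                if err is not None and err <= config.adapt_tol:
                    break
                rejects += 1
                rejects_total += 1
                if rejects > config.max_rejects:
                    raise SolverError(
                        f"step at t={t:.4g} rejected {rejects} times; giving up"
                    )
                dt = (
                    max(dt / 2, config.dt_min)
                    if err is None
                    else adapt_timestep(err, dt, config)
                )
                if err is not None and dt >= (T - t):
                    dt = max((T - t) / 2, config.dt_min)
                dt = min(dt, T - t)
                if dt <= config.dt_min and rejects > config.max_rejects // 2:
                    raise SolverError("time step pinned at dt_min without acceptance")
        t = new.t
        state = new
        cons = 0.0
        if mass0 is not None:
            cons = (total_mass(model, state) - mass0) / max(abs(mass0), 1e-300)
        traj.states.append(state.copy())
        traj.step_meta.append(
            {
                "dt": dt,
                "newton_iters": meta["newton_iters"],
                "residual": meta["residual"],
                "err_est": err or 0.0,
                "conservation_residual": cons,
                "rejects": rejects_total,
            }
        )
        if config.adaptive and t < T - 1e-12 * max(T, 1.0):
            dt = adapt_timestep(err, dt, config) if err else config.dt_max
            dt = min(dt, T - t)
    return traj
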