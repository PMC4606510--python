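import numpy as np
import pytest

from sigdiff.fem import (
    AssemblyError,
    SolverConfig,
    SolverError,
    Stepper,
    adapt_timestep,
    assemble,
    solve,
    step_fully_coupled,
    step_segregated,
)
from sigdiff.geometry import TAG_MEMBRANE, TAG_NUCLEUS, CellGeometrySpec, build_cell_mesh
from sigdiff.model import (
    BoundaryCoupling,
    Compartment,
    ModelDefinition,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
)
from sigdiff.pathways import StatPathwayParams, build_stat_model
from sigdiff.verification import generate_fixture, make_manufactured


def simple_model(mesh, D=1.0, reactions=(), couplings=(), ode=False, T=1.0,
                 initial=1.0):
    species = [SpeciesSpec("u", "pde", diffusion=D)]
    compartments = {}
    ode_names = []
    init = {"u": initial}
    if ode:
        species.append(SpeciesSpec("v", "ode", compartment="nuc"))
        compartments["nuc"] = Compartment("nuc", volume=5.0, surface_tag=TAG_NUCLEUS)
        ode_names = ["v"]
        init["v"] = 0.0
    return ModelDefinition(
        mesh=mesh,
        species=species,
        compartments=compartments,
        network=ReactionNetwork(["u"], ode_names, reactions=list(reactions)),
        couplings=list(couplings),
        initial=init,
        T=T,
    )


class TestAssembly:
    def test_pure_diffusion_stiffness_annihilates_constants(self, annulus2d):
        model = simple_model(annulus2d)
        ops = assemble(annulus2d, model)
        w = np.ones(annulus2d.n_nodes)
        assert np.max(np.abs(ops.K["u"] @ w)) < 1e-12

    def test_mass_matrix_sums_to_domain_measure(self, annulus2d):
        ops = assemble(annulus2d, simple_model(annulus2d))
        assert ops.M.sum() == pytest.approx(annulus2d.volume(), rel=1e-12)
        assert ops.Ml.sum() == pytest.approx(annulus2d.volume(), rel=1e-12)

    def test_equal_tensor_entries_reduce_to_scalar_assembly(self, sphere_shell_coarse):
        iso = assemble(sphere_shell_coarse, simple_model(sphere_shell_coarse, D=7.0))
        tens = assemble(
            sphere_shell_coarse,
            ModelDefinition(
                mesh=sphere_shell_coarse,
                species=[SpeciesSpec("u", "pde", diffusion=(7.0, 7.0, 7.0))],
                compartments={},
                network=ReactionNetwork(["u"]),
                couplings=[],
                initial={"u": 0.0},
                T=1.0,
            ),
        )
        diff = (iso.K["u"] - tens.K["u"]).toarray()
        assert np.max(np.abs(diff)) < 1e-13 * 7.0

    def test_inverted_element_raises_naming_element(self, annulus2d):
        import dataclasses

        bad = dataclasses.replace(annulus2d, elements=annulus2d.elements.copy())
        bad.elements[3, [0, 1]] = bad.elements[3, [1, 0]]
        with pytest.raises(AssemblyError, match="element 3"):
            assemble(bad, simple_model(annulus2d))

    def test_advection_warns_above_unit_peclet(self, annulus2d):
        model = ModelDefinition(
            mesh=annulus2d,
            species=[SpeciesSpec("u", "pde", diffusion=1e-4, velocity=(1.0, 0.0))],
            compartments={},
            network=ReactionNetwork(["u"]),
            couplings=[],
            initial={"u": 0.0},
            T=1.0,
        )
        with pytest.warns(UserWarning, match="Peclet"):
            assemble(annulus2d, model)


class TestSingleSteps:
    def test_equilibrium_state_unchanged_for_any_dt(self, annulus2d):
        model = simple_model(annulus2d, initial=2.5)
        ops = assemble(annulus2d, model)
        cfg = SolverConfig(adaptive=False)
        state = model.initial_state()
        for dt in (0.1, 10.0, 1000.0):
            new, _ = step_fully_coupled(state, dt, ops, model, cfg)
            np.testing.assert_allclose(new.fields["u"], 2.5, rtol=1e-12)

    def test_pure_decay_matches_backward_euler_closed_form(self, annulus2d):
        k = 0.3
        model = simple_model(annulus2d, reactions=[Reaction({"u": 1}, {}, k)],
                             initial=1.0)
        ops = assemble(annulus2d, model)
        state = model.initial_state()
        dt = 0.7
        new, _ = step_fully_coupled(state, dt, ops, model,
                                    SolverConfig(adaptive=False))
        np.testing.assert_allclose(new.fields["u"], 1.0 / (1.0 + k * dt), rtol=1e-10)

    def test_coupled_linear_step_matches_dense_oracle(self):
        """One monolithic backward-Euler step equals a dense linear solve of
        the same discrete system assembled by an independent element loop."""
        mesh = build_cell_mesh(CellGeometrySpec(outer=2.0, nucleus=1.0,
                                                target_h=0.7, dim=2))
        k_x, V_n, D, dt = 0.08, 5.0, 1.0, 0.5
        coupling = BoundaryCoupling(
            tag=TAG_NUCLEUS, species="u",
            flux=lambda t, x, tr, V: k_x * (V[0] - tr[:, 0]),
            receivers=[("v", 1.0)], pde_deps=["u"], ode_deps=["v"],
        )
        model = ModelDefinition(
            mesh=mesh,
            species=[SpeciesSpec("u", "pde", diffusion=D),
                     SpeciesSpec("v", "ode", compartment="nuc")],
            compartments={"nuc": Compartment("nuc", volume=V_n,
                                             surface_tag=TAG_NUCLEUS)},
            network=ReactionNetwork(["u"], ["v"]),
            couplings=[coupling],
            initial={"u": 1.0, "v": 0.2},
            T=1.0,
        )
        ops = assemble(mesh, model)
        state = model.initial_state()
        new, _ = step_fully_coupled(state, dt, ops, model,
                                    SolverConfig(adaptive=False))
        # independent naive assembly: element loops, dense algebra
        n = mesh.n_nodes
        M = np.zeros((n, n))
        K = np.zeros((n, n))
        for el in mesh.elements:
            X = mesh.nodes[el]
            A = np.vstack([X[1] - X[0], X[2] - X[0]])
            area = abs(np.linalg.det(A)) / 2.0
            grads = np.zeros((3, 2))
            grads[1:] = np.linalg.inv(A).T
            grads[0] = -grads[1] - grads[2]
            K[np.ix_(el, el)] += area * grads @ grads.T * D
            M[np.ix_(el, el)] += area / 12.0 * (np.ones((3, 3)) + np.eye(3))
        b = np.zeros(n)
        for facet, tag, fa in zip(mesh.boundary_facets, mesh.facet_tags,
                                  mesh.facet_areas()):
            if tag == TAG_NUCLEUS:
                b[facet] += fa / 2.0
        # unknowns [u; v]; backward Euler
        A_sys = np.zeros((n + 1, n + 1))
        A_sys[:n, :n] = M / dt + K + k_x * np.diag(b)
        A_sys[:n, n] = -k_x * b
        A_sys[n, :n] = -k_x * b / V_n
        A_sys[n, n] = 1.0 / dt + k_x * b.sum() / V_n
        rhs = np.concatenate([M @ state.fields["u"] / dt, [state.ode["v"] / dt]])
        sol = np.linalg.solve(A_sys, rhs)
        np.testing.assert_allclose(new.fields["u"], sol[:n], rtol=1e-8)
        assert new.ode["v"] == pytest.approx(sol[n], rel=1e-8)

    def test_segregated_equals_monolithic_when_uncoupled(self, annulus2d):
        model = simple_model(annulus2d, reactions=[Reaction({"u": 1}, {}, 0.2)],
                             ode=True)
        ops = assemble(annulus2d, model)
        cfg = SolverConfig(adaptive=False)
        state = model.initial_state()
        full, _ = step_fully_coupled(state, 0.5, ops, model, cfg)
        seg, _ = step_segregated(state, 0.5, ops, model, cfg)
        np.testing.assert_allclose(seg.fields["u"], full.fields["u"], rtol=1e-10)


class TestAdaptivity:
    def test_controller_formula_at_tolerance(self):
        cfg = SolverConfig(adapt_tol=1e-3, dt_min=1e-4, dt_init=1.0, dt_max=100.0)
        assert adapt_timestep(1e-3, 1.0, cfg) == pytest.approx(0.9)

    def test_zero_error_caps_at_dt_max(self):
        cfg = SolverConfig(adapt_tol=1e-3, dt_min=1e-4, dt_init=1.0, dt_max=77.0)
        assert adapt_timestep(0.0, 1.0, cfg) == 77.0

    def test_step_below_dt_min_is_hard_failure(self):
        cfg = SolverConfig(adapt_tol=1e-6, dt_min=0.5, dt_init=1.0, dt_max=10.0)
        with pytest.raises(SolverError):
            adapt_timestep(1e3, 1.0, cfg)

    def test_negative_error_estimate_rejected(self):
        cfg = SolverConfig()
        with pytest.raises(ValueError):
            adapt_timestep(-1.0, 1.0, cfg)

    def test_stiff_transient_shrinks_then_reexpands_dt(self, annulus2d):
        """A sharp activation switch-on forces the controller down and it
        recovers afterwards with a bounded number of rejected steps."""
        t_on = 60.0
        profile = generate_fixture("stiff_transient", t_on=t_on, width=0.5)
        model = build_stat_model(
            build_cell_mesh(CellGeometrySpec(outer=2.0, nucleus=1.0,
                                             target_h=0.5, dim=2)),
            StatPathwayParams(pjak=profile, T=160.0),
        )
        cfg = SolverConfig(dt_init=5.0, dt_min=1e-4, dt_max=20.0, adapt_tol=1e-3,
                           species_atol={s.name: 0.01 for s in model.species})
        traj = solve(model, cfg)
        dts = np.array([m["dt"] for m in traj.step_meta[1:]])
        times = traj.times[1:]
        # the controller's tightest step sits at the switch-on...
        t_min = times[np.argmin(dts)]
        assert abs(t_min - t_on) < 10.0
        # ... and it re-expands well above the transient floor afterwards
        assert dts[times > t_on + 60].max() > 4 * dts.min()
        assert traj.step_meta[-1]["rejects"] <= 30


class TestSolveDriver:
    def test_trajectory_starts_at_initial_condition_with_increasing_times(
        self, annulus2d
    ):
        model = simple_model(annulus2d, reactions=[Reaction({"u": 1}, {}, 0.1)],
                             T=2.0)
        traj = solve(model, SolverConfig(dt_init=0.5, dt_max=0.5, dt_min=0.01,
                                         adaptive=False))
        np.testing.assert_array_equal(traj.states[0].fields["u"],
                                      model.initial_state().fields["u"])
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[-1] == pytest.approx(2.0)

    def test_identical_configs_give_bit_identical_trajectories(self, annulus2d):
        model = simple_model(annulus2d, reactions=[Reaction({"u": 2}, {"u": 1}, 0.4)],
                             T=1.0, initial=1.5)
        cfg = SolverConfig(dt_init=0.25, dt_max=0.25, dt_min=0.01, adaptive=False)
        a = solve(model, cfg)
        b = solve(model, cfg)
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa.fields["u"], sb.fields["u"])

    def test_nonnegativity_preserved_without_clipping(self, sphere_shell_coarse):
        model = build_stat_model(sphere_shell_coarse, StatPathwayParams(T=600.0))
        traj = solve(model, SolverConfig(dt_init=30.0, dt_max=30.0, dt_min=1.0,
                                         adaptive=False))
        for s in traj.states:
            for name, vals in s.fields.items():
                assert vals.min() >= -1e-8 * max(vals.max(), 1e-30)

    def test_interpolation_reproduces_stored_states(self, annulus2d):
        model = simple_model(annulus2d, reactions=[Reaction({"u": 1}, {}, 0.1)],
                             T=1.0)
        traj = solve(model, SolverConfig(dt_init=0.2, dt_max=0.2, dt_min=0.01,
                                         adaptive=False))
        s = traj.at_time(traj.times[3])
        np.testing.assert_allclose(s.fields["u"], traj.states[3].fields["u"])
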