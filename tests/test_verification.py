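import numpy as np
import pytest
from scipy.linalg import expm

from sigdiff.fem import SolverConfig, solve
from sigdiff.geometry import (
    TAG_NUCLEUS,
    CellGeometrySpec,
    build_cell_mesh,
)
from sigdiff.model import (
    BoundaryCoupling,
    Compartment,
    ModelDefinition,
    ReactionNetwork,
    SpeciesSpec,
    lumped_mass_vector,
)
from sigdiff.verification import (
    DEFAULT_SEED,
    RadialShellParams,
    generate_fixture,
    linear_companion_matrix,
    make_manufactured,
    radial_benchmark_model,
    radial_oracle,
    wellmixed_oracle,
)


class TestManufactured:
    @pytest.mark.parametrize("seed", range(0, 20))
    def test_residual_vanishes_at_quadrature_points_for_seeded_profiles(self, seed,
                                                                        rng):
        prob = make_manufactured("generic2d", seed=seed)
        pts = rng.uniform(-1.5, 1.5, (40, 2))
        for t in (0.0, 0.3, 1.7):
            assert np.max(np.abs(prob.residual(t, pts))) <= 1e-10

    def test_radial_profile_residual_is_identically_zero(self, rng):
        prob = make_manufactured("radial2d")
        pts = rng.uniform(1.05, 1.95, (30, 1))
        ang = rng.uniform(0, 2 * np.pi, 30)
        X = np.column_stack([pts[:, 0] * np.cos(ang), pts[:, 0] * np.sin(ang)])
        assert np.max(np.abs(prob.residual(0.5, X))) <= 1e-10

    def test_constant_solution_induces_zero_sources(self, rng):
        prob = make_manufactured("constant")
        X = rng.uniform(-1, 1, (20, 2))
        assert np.all(prob.residual(0.7, X) == 0)
        mesh = prob.geometry(0.4)
        model = prob.build_model(mesh, 1.0)
        traj = solve(model, SolverConfig(dt_init=0.25, dt_max=0.25, dt_min=0.01,
                                         adaptive=False))
        np.testing.assert_allclose(traj.states[-1].fields["u"], 1.0, rtol=1e-12)


class TestWellmixedOracle:
    def _closed_linear_model(self):
        """Exchange-only linear model: autonomous companion, expm closed form."""
        mesh = build_cell_mesh(CellGeometrySpec(outer=2.0, nucleus=1.0,
                                                target_h=0.4, dim=2))
        k_x, V_n = 0.08, np.pi
        coupling = BoundaryCoupling(
            tag=TAG_NUCLEUS, species="u",
            flux=lambda t, x, tr, V: k_x * (V[0] - tr[:, 0]),
            receivers=[("v", 1.0)], pde_deps=["u"], ode_deps=["v"],
        )
        return ModelDefinition(
            mesh=mesh,
            species=[SpeciesSpec("u", "pde", diffusion=2.0),
                     SpeciesSpec("v", "ode", compartment="nuc")],
            compartments={"nuc": Compartment("nuc", volume=V_n,
                                             surface_tag=TAG_NUCLEUS)},
            network=ReactionNetwork(["u"], ["v"]),
            couplings=[coupling],
            initial={"u": 1.0, "v": 0.1},
            T=30.0,
        )

    def test_linear_closed_model_matches_matrix_exponential(self):
        model = self._closed_linear_model()
        times = np.array([0.0, 5.0, 15.0, 30.0])
        numeric = wellmixed_oracle(model, times)
        A, c = linear_companion_matrix(model)
        assert np.max(np.abs(c)) < 1e-14  # homogeneous
        y0 = np.array([1.0, 0.1])
        for i, t in enumerate(times):
            exact = expm(A * t) @ y0
            assert numeric["u"][i] == pytest.approx(exact[0], abs=1e-8)
            assert numeric["v"][i] == pytest.approx(exact[1], abs=1e-8)

    def test_zero_rate_model_stays_constant(self, annulus2d):
        model = ModelDefinition(
            mesh=annulus2d,
            species=[SpeciesSpec("u", "pde", diffusion=1.0)],
            compartments={},
            network=ReactionNetwork(["u"]),
            couplings=[],
            initial={"u": 0.8},
            T=5.0,
        )
        out = wellmixed_oracle(model, np.linspace(0, 5, 6))
        np.testing.assert_allclose(out["u"], 0.8, rtol=1e-9)

    def test_fem_volume_means_near_oracle_at_high_diffusion(self):
        """The spatial model collapses onto the companion as D grows."""
        from sigdiff.pathways import StatPathwayParams, build_stat_model

        mesh = build_cell_mesh(CellGeometrySpec(outer=2.0, nucleus=1.0,
                                                target_h=0.4, dim=2))
        model = build_stat_model(mesh, StatPathwayParams(D=1500.0, T=300.0))
        traj = solve(model, SolverConfig(scheme="crank_nicolson", dt_init=1.0,
                                         dt_max=1.0, dt_min=0.05,
                                         adaptive=False))
        times = np.linspace(30, 300, 7)
        companion = wellmixed_oracle(model, times)
        w = lumped_mass_vector(mesh)
        vol = w.sum()
        for name in ("STAT", "pSTAT"):
            means = np.array(
                [float(w @ traj.at_time(t).fields[name]) / vol for t in times]
            )
            scale = np.max(np.abs(companion[name])) or 1.0
            assert np.max(np.abs(means - companion[name])) < 0.01 * scale


class TestRadialOracle:
    def test_pure_diffusion_with_uniform_data_stays_constant(self):
        par = RadialShellParams(k_membrane=0.0, k_exchange=0.0, u0=0.7, v0=0.3)
        res = radial_oracle(par, np.linspace(0, 50, 6), resolution=100)
        np.testing.assert_allclose(res.u, 0.7, rtol=1e-7)
        np.testing.assert_allclose(res.v, 0.3, rtol=1e-7)

    def test_self_convergence_is_second_order(self):
        par = RadialShellParams()
        times = np.array([0.0, 20.0])
        ref = radial_oracle(par, times, resolution=800)
        errs = [
            abs(radial_oracle(par, times, resolution=n).v[-1] - ref.v[-1])
            for n in (100, 200)
        ]
        assert 3.0 <= errs[0] / errs[1] <= 6.0

    def test_fem_converges_to_oracle_under_mesh_refinement(self):
        par = RadialShellParams()
        T = 20.0
        oracle = radial_oracle(par, np.array([0.0, T]))
        errs = []
        for h in (1.5, 0.75):
            mesh = build_cell_mesh(CellGeometrySpec(outer=par.r_out,
                                                    nucleus=par.r_in, target_h=h))
            model = radial_benchmark_model(mesh, par, T=T)
            traj = solve(model, SolverConfig(scheme="crank_nicolson", dt_init=0.2,
                                             dt_max=0.2, dt_min=0.02,
                                             adaptive=False), record_mass=False)
            w = lumped_mass_vector(mesh)
            mean = float(w @ traj.states[-1].fields["u"] / w.sum())
            errs.append(abs(mean - oracle.volume_mean()[-1]))
        assert errs[1] < errs[0]
        assert errs[1] / abs(oracle.volume_mean()[-1]) < 0.02


class TestFixtures:
    def test_same_seed_reproduces_fixture(self, annulus2d):
        a = generate_fixture("random_field", seed=7, mesh=annulus2d)
        b = generate_fixture("random_field", seed=7, mesh=annulus2d)
        np.testing.assert_array_equal(a, b)

    def test_random_field_respects_requested_range(self, annulus2d):
        f = generate_fixture("random_field", seed=DEFAULT_SEED, mesh=annulus2d,
                             low=0.2, high=0.9)
        assert f.min() >= 0.2 and f.max() <= 0.9

    def test_lattice_case_has_single_central_secreter(self):
        mesh = generate_fixture("lattice_case", seed=3, grid=(3, 3, 3),
                                target_h=4.0)
        cells = mesh.metadata["cells"]
        assert cells["types"].count("secreting") == 1
        centers = np.asarray(cells["centers"])
        sec = cells["types"].index("secreting")
        centroid = centers.mean(axis=0)
        assert np.allclose(centers[sec], centroid)
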