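import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigdiff.geometry import TAG_MEMBRANE, TAG_NUCLEUS
from sigdiff.model import (
    Compartment,
    ModelDefinition,
    ModelError,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    State,
    evaluate_rates,
    make_anisotropic_tensor,
    surface_average,
    total_mass,
)


class TestSurfaceAverage:
    def test_constant_field_averages_to_constant(self, sphere_shell_coarse):
        field = np.full(sphere_shell_coarse.n_nodes, 3.7)
        for tag in (TAG_MEMBRANE, TAG_NUCLEUS):
            assert surface_average(sphere_shell_coarse, field, tag) == pytest.approx(3.7)

    def test_odd_function_averages_to_zero_on_sphere(self, sphere_shell_coarse):
        z = sphere_shell_coarse.nodes[:, 2]
        avg = surface_average(sphere_shell_coarse, z, TAG_MEMBRANE)
        assert abs(avg) < 1e-10

    def test_matches_facet_by_facet_quadrature_oracle(self, annulus2d, rng):
        field = rng.uniform(0.0, 2.0, annulus2d.n_nodes)
        # independent brute-force loop: per facet, length * mean of nodal values
        areas = annulus2d.facet_areas()
        total, area = 0.0, 0.0
        for facet, fa, tag in zip(annulus2d.boundary_facets, areas,
                                  annulus2d.facet_tags):
            if tag != TAG_MEMBRANE:
                continue
            total += fa * field[facet].mean()
            area += fa
        assert surface_average(annulus2d, field, TAG_MEMBRANE) == pytest.approx(
            total / area, rel=1e-12
        )

    def test_linear_and_bounded_by_nodal_extrema(self, annulus2d, rng):
        f = rng.uniform(0.0, 1.0, annulus2d.n_nodes)
        g = rng.uniform(0.0, 1.0, annulus2d.n_nodes)
        sa = lambda x: surface_average(annulus2d, x, TAG_NUCLEUS)  # noqa: E731
        assert sa(2 * f + 3 * g) == pytest.approx(2 * sa(f) + 3 * sa(g), rel=1e-12)
        bnodes = annulus2d.boundary_nodes(TAG_NUCLEUS)
        assert f[bnodes].min() - 1e-12 <= sa(f) <= f[bnodes].max() + 1e-12

    def test_zero_area_tag_is_an_error(self, annulus2d):
        with pytest.raises(ModelError):
            surface_average(annulus2d, np.ones(annulus2d.n_nodes), 99)


class TestMassActionRates:
    def test_dimerization_follows_mass_action_law(self):
        net = ReactionNetwork(["A", "A2"],
                              reactions=[Reaction({"A": 2}, {"A2": 1}, 0.5)])
        state = State(t=0.0, fields={"A": np.array([2.0]), "A2": np.array([0.0])},
                      ode={})
        rates = evaluate_rates(state, net)
        assert rates["A"][0] == pytest.approx(-4.0)
        assert rates["A2"][0] == pytest.approx(2.0)

    def test_zero_concentrations_give_zero_rates(self):
        net = ReactionNetwork(
            ["A", "B"],
            reactions=[Reaction({"A": 1, "B": 1}, {"A": 2}, 1.3),
                       Reaction({"B": 2}, {}, 0.7)],
        )
        state = State(t=0.0, fields={"A": np.zeros(4), "B": np.zeros(4)}, ode={})
        rates = evaluate_rates(state, net)
        assert np.all(rates["A"] == 0) and np.all(rates["B"] == 0)

    def test_negative_rate_constant_rejected_at_build(self):
        with pytest.raises(ModelError):
            Reaction({"A": 1}, {}, -0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_network_matches_brute_force_interpreter(self, seed):
        """Mass-action evaluation equals a naive per-reaction interpreter."""
        rng = np.random.default_rng(seed)
        n_sp = rng.integers(2, 6)
        names = [f"S{i}" for i in range(n_sp)]
        reactions = []
        for _ in range(rng.integers(1, 8)):
            react = {names[i]: int(rng.integers(1, 3))
                     for i in rng.choice(n_sp, rng.integers(1, 3), replace=False)}
            prod = {names[i]: int(rng.integers(1, 3))
                    for i in rng.choice(n_sp, rng.integers(0, 3), replace=False)}
            reactions.append(Reaction(react, prod, float(rng.uniform(0, 2))))
        net = ReactionNetwork(names, reactions=reactions)
        U = rng.uniform(0, 3, (5, n_sp))
        rho = net.production(0.0, np.zeros((5, 3)), U, np.zeros(0))
        expected = np.zeros_like(rho)
        for rx in reactions:
            rate = rx.rate_constant * np.ones(5)
            for sp, nu in rx.reactants.items():
                rate = rate * U[:, names.index(sp)] ** nu
            for sp, nu in rx.reactants.items():
                expected[:, names.index(sp)] -= nu * rate
            for sp, nu in rx.products.items():
                expected[:, names.index(sp)] += nu * rate
        np.testing.assert_allclose(rho, expected, rtol=1e-12, atol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_analytic_jacobian_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        names = ["A", "B", "C"]
        reactions = [
            Reaction({"A": 2}, {"B": 1}, float(rng.uniform(0.1, 2))),
            Reaction({"B": 1, "C": 1}, {"A": 1}, float(rng.uniform(0.1, 2))),
            Reaction({"C": 1}, {}, float(rng.uniform(0.1, 2))),
        ]
        net = ReactionNetwork(names, reactions=reactions)
        U = rng.uniform(0.1, 2.0, (4, 3))
        X = np.zeros((4, 3))
        JU, _ = net.production_jac(0.0, X, U, np.zeros(0))
        eps = 1e-6
        for k in range(3):
            dU = np.zeros_like(U)
            dU[:, k] = eps
            fd = (net.production(0.0, X, U + dU, np.zeros(0))
                  - net.production(0.0, X, U - dU, np.zeros(0))) / (2 * eps)
            np.testing.assert_allclose(JU[:, :, k], fd, rtol=1e-6, atol=1e-8)

    def test_conservation_vector_checked_against_stoichiometry(self):
        with pytest.raises(ModelError, match="annihilate"):
            ReactionNetwork(
                ["A", "A2"],
                reactions=[Reaction({"A": 2}, {"A2": 1}, 1.0)],
                conserved={"A": 1.0, "A2": 1.0},  # wrong: dimer counts twice
            )
        ReactionNetwork(  # correct composition passes
            ["A", "A2"],
            reactions=[Reaction({"A": 2}, {"A2": 1}, 1.0)],
            conserved={"A": 1.0, "A2": 2.0},
        )


class TestTotalMass:
    def _model(self, mesh):
        return ModelDefinition(
            mesh=mesh,
            species=[SpeciesSpec("u", "pde", diffusion=1.0),
                     SpeciesSpec("v", "ode", compartment="nuc")],
            compartments={"nuc": Compartment("nuc", volume=10.0,
                                             surface_tag=TAG_NUCLEUS)},
            network=ReactionNetwork(["u"], ["v"]),
            couplings=[],
            initial={"u": 1.0, "v": 0.0},
            T=1.0,
        )

    def test_uniform_field_gives_domain_volume(self, annulus2d):
        model = self._model(annulus2d)
        state = model.initial_state()
        m = total_mass(model, state, {"u": 1.0})
        assert m == pytest.approx(annulus2d.volume(), rel=1e-12)

    def test_empty_composition_gives_zero(self, annulus2d):
        model = self._model(annulus2d)
        assert total_mass(model, model.initial_state(), {}) == 0.0

    def test_matches_per_element_quadrature_oracle(self, annulus2d, rng):
        model = self._model(annulus2d)
        state = model.initial_state()
        state.fields["u"] = rng.uniform(0, 2, annulus2d.n_nodes)
        state.ode["v"] = 0.4
        vols = annulus2d.element_volumes()
        brute = sum(
            v * state.fields["u"][el].mean()
            for el, v in zip(annulus2d.elements, vols)
        ) + 10.0 * 0.4 * 2.0
        got = total_mass(model, state, {"u": 1.0, "v": 2.0})
        assert got == pytest.approx(brute, rel=1e-10)


class TestAnisotropicTensor:
    def test_isotropic_limit(self):
        assert make_anisotropic_tensor(15.0, 1.0) == pytest.approx((15.0, 15.0, 15.0))

    def test_reported_anisotropy_example(self):
        d = make_anisotropic_tensor(15.0, 5.5, axis="y")
        assert d[1] == pytest.approx(33.0)
        assert d[0] == pytest.approx(6.0) and d[2] == pytest.approx(6.0)
        assert sum(d) == pytest.approx(45.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(1.0, 50.0))
    def test_trace_always_three_d(self, D, ratio):
        assert sum(make_anisotropic_tensor(D, ratio)) == pytest.approx(3 * D, rel=1e-12)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ModelError):
            make_anisotropic_tensor(15.0, 0.5)


class TestModelValidation:
    def test_missing_boundary_tag_rejected(self, annulus2d):
        from sigdiff.model import BoundaryCoupling

        with pytest.raises(ModelError, match="missing boundary tag"):
            ModelDefinition(
                mesh=annulus2d,
                species=[SpeciesSpec("u", "pde", diffusion=1.0)],
                compartments={},
                network=ReactionNetwork(["u"]),
                couplings=[BoundaryCoupling(tag=42, species="u",
                                            flux=lambda t, x, tr, V: tr[:, 0])],
                initial={"u": 0.0},
                T=1.0,
            )

    def test_infinite_horizon_rejected(self, annulus2d):
        with pytest.raises(ModelError):
            ModelDefinition(
                mesh=annulus2d,
                species=[SpeciesSpec("u", "pde", diffusion=1.0)],
                compartments={},
                network=ReactionNetwork(["u"]),
                couplings=[],
                initial={"u": 0.0},
                T=np.inf,
            )

    def test_ode_species_cannot_carry_transport(self):
        with pytest.raises(ModelError):
            SpeciesSpec("v", "ode", diffusion=1.0, compartment="nuc")
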