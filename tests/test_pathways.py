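import numpy as np
import pytest

from sigdiff.fem import SolverConfig, Trajectory, solve
from sigdiff.geometry import CellGeometrySpec, build_cell_mesh
from sigdiff.model import ModelError, State, lumped_mass_vector, total_mass
from sigdiff.pathways import (
    HOUR,
    Il2Params,
    SmadPathwayParams,
    StatPathwayParams,
    build_il2_model,
    build_smad_model,
    build_stat_model,
    count_activated,
    il2_solver_config,
    molecule_balance_residual,
)
from sigdiff.verification import generate_fixture


@pytest.fixture(scope="module")
def annulus():
    return build_cell_mesh(
        CellGeometrySpec(kind="sphere_shell", outer=2.0, nucleus=1.0,
                         target_h=0.4, dim=2)
    )


def fixed(dt, **kw):
    return SolverConfig(dt_init=dt, dt_max=dt, dt_min=dt / 100, adaptive=False, **kw)


class TestStatModel:
    def test_no_forcing_means_no_dynamics_beyond_exchange(self, annulus):
        """With pjak = 0 and no nuclear pool there is nothing to move: the
        initial condition is a steady state."""
        p = StatPathwayParams(pjak=lambda t: 0.0, k_import_inactive=0.0,
                              k_export=0.0, T=50.0)
        traj = solve(build_stat_model(annulus, p), fixed(10.0))
        for s in traj.states:
            np.testing.assert_allclose(s.fields["STAT"], 1.0, rtol=1e-12)
            np.testing.assert_allclose(s.fields["pSTAT"], 0.0, atol=1e-14)

    def test_total_stat_conserved(self, annulus):
        traj = solve(build_stat_model(annulus, StatPathwayParams(T=100.0)),
                     fixed(5.0))
        masses = traj.mass_series()
        assert np.max(np.abs(masses - masses[0])) <= 1e-9 * masses[0]

    def test_exact_linear_superposition(self, annulus):
        """Doubling the initial pool doubles every field at every time."""
        t1 = solve(build_stat_model(annulus, StatPathwayParams(stat_total=1.0,
                                                               T=100.0)),
                   fixed(10.0))
        t2 = solve(build_stat_model(annulus, StatPathwayParams(stat_total=2.0,
                                                               T=100.0)),
                   fixed(10.0))
        for s1, s2 in zip(t1.states, t2.states):
            for name in s1.fields:
                np.testing.assert_allclose(2 * s1.fields[name], s2.fields[name],
                                           rtol=1e-9, atol=1e-12)
            for name in s1.ode:
                assert 2 * s1.ode[name] == pytest.approx(s2.ode[name], rel=1e-8,
                                                         abs=1e-10)

    def test_missing_tags_raise(self):
        lattice = generate_fixture("lattice_case", seed=0, grid=(2, 2, 1),
                                   target_h=4.0)
        with pytest.raises(ModelError, match="tags"):
            build_stat_model(lattice, StatPathwayParams())

    def test_anisotropic_variant_builds_with_trace_preserving_tensor(
        self, sphere_shell_coarse
    ):
        p = StatPathwayParams(anisotropy_ratio=5.5, T=10.0)
        model = build_stat_model(sphere_shell_coarse, p)
        d = model.species_by_name("STAT").diffusion
        assert sum(d) == pytest.approx(3 * p.D)


class TestSmadModel:
    def test_monomer_equivalents_conserved_through_oligomerization(self, annulus):
        p = SmadPathwayParams(T=200.0)
        traj = solve(build_smad_model(annulus, p), fixed(10.0))
        masses = traj.mass_series()
        assert np.max(np.abs(masses - masses[0])) <= 1e-9 * masses[0]
        # trimers actually form and accumulate in the nucleus
        assert traj.states[-1].ode["nuc_trimer"] > 0

    def test_zero_oligomerization_reduces_to_linear_shuttling(self, annulus):
        """With all oligomerization off, monomer dynamics equal the linear
        two-species model under matched rates."""
        ps = SmadPathwayParams(k_on2=0.0, k_off2=0.0, k_on3=0.0, k_off3=0.0,
                               k_act=0.05, T=100.0)
        pt = StatPathwayParams(k_act=0.05, k_import_inactive=0.0,
                               k_import_active=0.0, k_export=0.0, T=100.0)
        ts = solve(build_smad_model(annulus, ps), fixed(5.0))
        tt = solve(build_stat_model(annulus, pt), fixed(5.0))
        np.testing.assert_allclose(ts.states[-1].fields["SMAD"],
                                   tt.states[-1].fields["STAT"], rtol=1e-9)
        np.testing.assert_allclose(ts.states[-1].fields["pSMAD"],
                                   tt.states[-1].fields["pSTAT"], rtol=1e-9,
                                   atol=1e-14)


class TestIl2Model:
    def test_receptors_relax_to_constitutive_steady_state_without_ligand(
        self, lattice_center_secreter
    ):
        """q = 0: the field stays empty and each receptor count follows the
        linear production/decay closed form."""
        p = Il2Params(q=0.0, receptor_init=2000.0, T=4 * HOUR)
        model = build_il2_model(lattice_center_secreter, p)
        traj = solve(model, fixed(600.0))
        assert np.max(np.abs(traj.states[-1].fields["IL2"])) < 1e-14
        k = p.receptor_decay / HOUR
        R_inf = (p.receptor_production / HOUR) / k
        a = model.info["absorbers"][0]
        series = traj.ode_series(a["R"])
        times = traj.times
        exact = R_inf + (2000.0 - R_inf) * np.exp(-k * times)
        # backward Euler at dt=600 s on a 2 h decay: matches within 2 %
        np.testing.assert_allclose(series, exact, rtol=2e-2)
        assert np.max(np.abs(traj.ode_series(a["B"]))) < 1e-14

    def test_mean_concentration_grows_at_secretion_rate_without_uptake(
        self, lattice_center_secreter
    ):
        p = Il2Params(k_on=0.0, T=2 * HOUR, t_ramp=60.0)
        model = build_il2_model(lattice_center_secreter, p)
        traj = solve(model, fixed(300.0))
        w = lumped_mass_vector(model.mesh)
        vol = w.sum()
        means = np.array([float(w @ s.fields["IL2"]) / vol for s in traj.states])
        times = traj.times
        sel = times > 3600.0  # past the ramp
        slope = np.polyfit(times[sel], means[sel], 1)[0]
        assert slope == pytest.approx(p.q_per_s / vol, rel=1e-6)

    def test_mesh_without_cell_labels_rejected(self, sphere_shell_coarse):
        with pytest.raises(ModelError, match="metadata"):
            build_il2_model(sphere_shell_coarse, Il2Params())


class TestCountActivated:
    def _tiny_traj(self, lattice_center_secreter):
        model = build_il2_model(lattice_center_secreter, Il2Params(T=10.0))
        state = model.initial_state()
        values = iter([5000.0, 3000.0, 4001.0] * 10)
        for a in model.info["absorbers"]:
            state.ode[a["R"]] = next(values)
        return Trajectory(model=model, config=SolverConfig(), states=[state],
                          step_meta=[{}])

    def test_threshold_counting(self, lattice_center_secreter):
        traj = self._tiny_traj(lattice_center_secreter)
        # 26 absorbers cycling through 5000/3000/4001: 9 + 8 exceed 4000
        assert count_activated(traj, 4000.0)[0] == 17
        assert count_activated(traj, np.inf)[0] == 0

    def test_counts_nonincreasing_in_threshold(self, lattice_center_secreter):
        traj = self._tiny_traj(lattice_center_secreter)
        thresholds = [0.0, 2999.0, 4000.0, 4999.0, 6000.0]
        counts = [count_activated(traj, thr)[0] for thr in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
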