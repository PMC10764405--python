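import dataclasses
import math

import numpy as np
import pytest

import phyllofield as pf
from phyllofield import _engine
from phyllofield.simulator import _State, admissible_arcs, place_primordia, step


def costoid_params(**kw):
    return pf.get_preset("fig2c_costoid").params.replace(**kw)


class TestParamsValidation:
    def test_new_model_rejects_bad_values(self):
        with pytest.raises(ValueError):
            costoid_params(N=0.0)
        with pytest.raises(ValueError):
            costoid_params(gamma_S=-1.0)
        with pytest.raises(ValueError):
            costoid_params(alpha_Y=0.0)

    def test_edc2_rejects_bad_values(self):
        with pytest.raises(ValueError):
            pf.EDC2Params(N=1 / 3, gamma=0.0, alpha=3.0, A=10.0, B=0.0)

    def test_config_rejects_bad_values(self):
        with pytest.raises(ValueError):
            pf.SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            pf.SimulationConfig(angular_resolution=0.7)  # does not divide 360

    def test_run_validates_before_stepping(self):
        with pytest.raises(ValueError):
            pf.run(pf.EDC2Params(N=1 / 3, gamma=1.9, alpha=3.0, A=10.0, B=0.0),
                   schedule=pf.EnlargementSchedule(3.2, 1.71, 0.82, 1.0, 1.79))


class TestGammaSchedule:
    SCHED = pf.EnlargementSchedule(gamma_S_i=3.2, gamma_S_f=1.71, t_i=0.82,
                                   tau=1.0, gamma_Y_f=1.79)

    def test_midpoint(self):
        g_S, g_Y = pf.gamma_schedule(0.82, self.SCHED)
        assert g_S == pytest.approx((3.2 + 1.71) / 2)
        assert g_Y == pytest.approx(g_S * 1.79 / 1.71)

    def test_asymptotic_limits(self):
        assert pf.gamma_schedule(-1e6, self.SCHED)[0] == pytest.approx(3.2)
        assert pf.gamma_schedule(1e6, self.SCHED)[0] == pytest.approx(1.71)

    def test_monotone_between_limits(self):
        g = [pf.gamma_schedule(t, self.SCHED)[0] for t in np.linspace(-5, 8, 60)]
        assert np.all(np.diff(g) < 0)
        assert np.all((np.array(g) > 1.71) & (np.array(g) < 3.2))


class TestAdmissibleArcs:
    GRID = np.arange(3600) * 0.1

    def test_full_circle_is_one_arc(self):
        Y = np.full(3600, 2.0)
        S = np.full(3600, 0.5)
        arcs = admissible_arcs(self.GRID, Y, S, 1.0, 1.0)
        assert len(arcs) == 1
        assert len(arcs[0]) == 3600

    def test_no_admissible_points(self):
        Y = np.zeros(3600)
        S = np.zeros(3600)
        assert admissible_arcs(self.GRID, Y, S, 1.0, 1.0) == []

    def test_wraparound_is_a_single_arc(self):
        Y = np.zeros(3600)
        S = np.ones(3600) * 2.0
        for i in (3598, 3599, 0, 1):
            Y[i] = 2.0
            S[i] = 0.5
        arcs = admissible_arcs(self.GRID, Y, S, 1.0, 1.0)
        assert len(arcs) == 1
        assert sorted(arcs[0]) == [0, 1, 3598, 3599]

    def test_disjoint_arcs_are_split(self):
        Y = np.full(3600, 2.0)
        S = np.full(3600, 2.0)
        S[100:110] = 0.5
        S[2000:2020] = 0.5
        arcs = admissible_arcs(self.GRID, Y, S, 1.0, 1.0)
        assert [len(a) for a in arcs] == [10, 20]


class TestPlacePrimordia:
    def test_minimum_of_inhibition_within_arc(self):
        S = np.full(3600, 2.0)
        S[50:60] = np.linspace(0.9, 0.5, 10)  # minimum at index 59
        arcs = [np.arange(50, 60)]
        assert place_primordia(arcs, None, S) == [59]

    def test_one_primordium_per_disjoint_arc(self):
        S = np.full(3600, 2.0)
        S[100] = 0.3
        S[1900] = 0.4
        arcs = [np.array([99, 100, 101]), np.array([1899, 1900, 1901])]
        assert place_primordia(arcs, None, S) == [100, 1900]

    def test_tie_breaks_to_lowest_grid_index(self):
        S = np.full(3600, 2.0)
        S[200:210] = 0.7  # flat tie across the arc
        assert place_primordia([np.arange(200, 210)], None, S) == [200]


class TestEngineKernels:
    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(0)
        J = 720
        n = 7
        cos_table = np.cos(np.radians(rng.uniform(0, 360, (n, J))))
        ages = rng.uniform(0.0, 2.0, n)
        args = (n, ages, 1 / 3, 1 / 4.08, 4.0, 20.0, 0.64, 1 / 3.0, 2.0, 10.0, 0.0)
        Y1, S1 = np.empty(J), np.empty(J)
        Y2, S2 = np.empty(J), np.empty(J)
        _engine.accumulate_dual(Y1, S1, cos_table, *args)
        _engine.accumulate_dual_numpy(Y2, S2, cos_table, *args)
        assert np.allclose(Y1, Y2, rtol=1e-10)
        assert np.allclose(S1, S2, rtol=1e-10)

        I1, I2 = np.empty(J), np.empty(J)
        targs = (n, ages, 1 / 3, 1 / 1.1, 3.0, 10.0, 0.0)
        _engine.accumulate_tanh(I1, cos_table, *targs)
        _engine.accumulate_tanh_numpy(I2, cos_table, *targs)
        assert np.allclose(I1, I2, rtol=1e-10)

    def test_engine_matches_reference_field_strength(self):
        g = pf.ApexGeometry(N=1 / 3)
        spec_Y = pf.FieldSpec(3.5, 4.0, pf.AgeFactorParams(20.0, 0.64))
        spec_S = pf.FieldSpec(3.0, 2.0, pf.AgeFactorParams(10.0, 0.0))
        prims = [pf.Primordium(index=1, theta=0.0, t=0.7),
                 pf.Primordium(index=2, theta=55.9, t=0.1)]
        J = 360
        grid = np.arange(J) * 1.0
        cos_table = np.stack([np.cos(np.radians(grid - p.theta)) for p in prims])
        ages = np.array([p.t for p in prims])
        Y, S = np.empty(J), np.empty(J)
        _engine.accumulate_dual(Y, S, cos_table, 2, ages, 1 / 3,
                                1.0 / (3.5 ** 2 / 3), 4.0, 20.0, 0.64,
                                1.0 / (3.0 ** 2 / 3), 2.0, 10.0, 0.0)
        assert np.allclose(Y, pf.field_strength(grid, prims, spec_Y, g), rtol=1e-9)
        assert np.allclose(S, pf.field_strength(grid, prims, spec_S, g), rtol=1e-9)


class TestStep:
    def test_ages_advance_without_initiation(self):
        # inductive emission far in the future: nothing can form
        params = costoid_params(B_Y=50.0)
        config = pf.SimulationConfig(max_primordia=10)
        state = _State(params, config, None, True)
        assert state.n == 1
        placed = step(state)
        assert placed == []
        assert state.t_sim == pytest.approx(config.dt)
        assert (state.t_sim - state.t_em[0]) == pytest.approx(config.dt)

    def test_first_initiation_matches_one_primordium_theory(self):
        # with a single primordium the engine realizes the simplified
        # situation: emergence at t*, displaced by theta*
        params = costoid_params()
        result = pf.run(params, pf.SimulationConfig(max_primordia=2))
        t_star = pf.solve_tstar(params)[0]
        th_star = pf.theta_star(t_star, params)
        assert result.n_primordia == 2
        assert result.emergence_times[1] == pytest.approx(t_star, abs=2e-3)
        dv = abs(pf.divergence_series(result.thetas)[0])
        assert dv == pytest.approx(th_star, abs=0.2)


class TestRunSymmetries:
    def test_rotation_equivariance(self):
        config = pf.SimulationConfig(max_primordia=6)
        base = pf.run(costoid_params(), config)
        rotated = pf.run(costoid_params(),
                         dataclasses.replace(config, initial_theta=90.0))
        assert np.allclose((rotated.thetas - base.thetas) % 360.0, 90.0)
        assert np.allclose(rotated.emergence_times, base.emergence_times)

    def test_mirror_symmetry_via_chirality_convention(self):
        config = pf.SimulationConfig(max_primordia=6)
        ccw = pf.run(costoid_params(), config)
        cw = pf.run(costoid_params(),
                    dataclasses.replace(config, chirality="cw"))
        assert np.allclose((-cw.thetas) % 360.0, ccw.thetas % 360.0)
        assert np.allclose(cw.emergence_times, ccw.emergence_times)

    def test_deterministic_reruns_are_bitwise_identical(self):
        config = pf.SimulationConfig(max_primordia=5)
        a = pf.run(costoid_params(), config)
        b = pf.run(costoid_params(), config)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.emergence_times, b.emergence_times)


class TestEDC2Reduction:
    def test_always_on_induction_reduces_to_inhibition_only(self):
        # induction saturated from the start: the dual-field engine must
        # reproduce the pure inhibitory-field run exactly
        params = costoid_params(B_Y=-1.0)
        config = pf.SimulationConfig(max_primordia=10)
        dual = pf.run(params, config)
        inhibition_only = pf.run(params, config, induction_test=False)
        assert np.array_equal(dual.thetas, inhibition_only.thetas)
        assert np.array_equal(dual.emergence_times, inhibition_only.emergence_times)
        # the inductive threshold was indeed satisfied at every initiation
        assert np.all(dual.initiation_Y[1:] > params.Y_th)

    def test_edc2_tanh_run_initiates_below_threshold(self):
        params = pf.EDC2Params(N=1 / 3, gamma=3.0, alpha=3.0, A=10.0, B=0.0)
        result = pf.run(params, pf.SimulationConfig(max_primordia=8))
        assert result.n_primordia == 8
        assert np.all(result.initiation_S[1:] < params.E_th)
        assert np.all(np.isnan(result.initiation_Y))


class TestStoppingRules:
    def test_max_primordia(self, costoid_result):
        assert costoid_result.termination == "max_primordia"
        assert costoid_result.n_primordia == 30
        assert np.all(np.diff(costoid_result.emergence_times) >= 0)

    def test_formation_failure_with_late_induction(self):
        result = pf.run(costoid_params(B_Y=1.0), pf.SimulationConfig(max_primordia=30))
        assert result.n_primordia == 1
        assert result.termination in ("gap_exceeded", "time_budget")

    def test_gap_monitor_fires_when_budget_is_loose(self):
        config = pf.SimulationConfig(max_primordia=30, max_gap_G=1.5,
                                     t_budget_factor=10.0)
        result = pf.run(costoid_params(B_Y=1.0), config)
        assert result.termination == "gap_exceeded"
        assert result.n_primordia == 1


class TestEnlargement:
    def test_schedule_trace_records_declining_ranges(self, enlargement_result):
        trace = enlargement_result.schedule_trace
        assert trace is not None and trace.shape[1] == 3
        assert np.all(np.diff(trace[:, 1]) < 0)  # Gamma_S shrinks as the SAM grows
        ratio = trace[:, 2] / trace[:, 1]
        assert np.allclose(ratio, 1.79 / 1.71, rtol=1e-12)

    def test_divergence_decreases_to_steep_spiral(self, enlargement_result):
        dv = np.abs(pf.divergence_series(enlargement_result.thetas))
        assert np.all(np.diff(dv) <= 1.0)
        assert dv[-1] < 80.0
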