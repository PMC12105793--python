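"""Unit and property tests of the haemodynamic forward model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import invaert_cvsim as ic
from invaert_cvsim.cvsim6 import (MMHG_TO_BARYE, CVSimError,
                                  SimulationConfig, _reference_pressures)


class TestVentricularCapacitances:
    def test_phase_endpoints(self, default_params):
        p = default_params
        ttot = p.cycle_length
        cl0, _, cr0, _ = ic.ventricular_capacitances(0.0, p)
        assert cl0 == pytest.approx(7.50e-3)
        assert cr0 == pytest.approx(1.50e-2)
        cls, _, crs, _ = ic.ventricular_capacitances(p.rsys * ttot, p)
        assert cls == pytest.approx(3.00e-4)
        assert crs == pytest.approx(9.00e-4)

    def test_minimum_at_end_systole(self, default_params):
        p = default_params
        t = np.linspace(0, p.cycle_length, 4001)
        cl, _, _, _ = ic.ventricular_capacitances(t, p)
        assert t[np.argmin(cl)] == pytest.approx(p.rsys * p.cycle_length,
                                                 abs=1e-3)
        assert cl.min() >= p.Cl_sys - 1e-15
        assert cl.max() <= p.Cl_dia + 1e-15

    @given(st.floats(0.0, 10.0))
    def test_periodicity(self, t):
        p = ic.default_parameters()
        a = ic.ventricular_capacitances(t, p)
        b = ic.ventricular_capacitances(t + p.cycle_length, p)
        assert a == pytest.approx(b, rel=1e-9)

    @given(st.floats(1e-3, 2.0))
    def test_analytic_derivative_matches_finite_difference(self, t):
        p = ic.default_parameters()
        h = 1e-6
        cl_m, _, cr_m, _ = ic.ventricular_capacitances(t - h, p)
        cl_p, _, cr_p, _ = ic.ventricular_capacitances(t + h, p)
        _, dcl, _, dcr = ic.ventricular_capacitances(t, p)
        # away from the non-smooth phase joints the O(h^2) stencil applies
        ttot = p.cycle_length
        tau = t % ttot
        joints = np.array([0.0, p.rsys * ttot, ttot])
        if np.min(np.abs(tau - joints)) > 1e-4:
            assert dcl == pytest.approx((cl_p - cl_m) / (2 * h), rel=1e-4,
                                        abs=1e-9)
            assert dcr == pytest.approx((cr_p - cr_m) / (2 * h), rel=1e-4,
                                        abs=1e-9)

    def test_invalid_rsys_rejected(self, default_params):
        bad = default_params.replace(rsys=1.5)
        with pytest.raises(CVSimError):
            ic.ventricular_capacitances(0.1, bad)


class TestValveFlows:
    def test_open_mitral_flow_value(self, default_params):
        # (10 - 5) mmHg across Rl_in = 13.33 -> 500.08 ml/s
        P = np.array([5.0, 0, 0, 0, 0, 10.0]) * MMHG_TO_BARYE
        q = ic.valve_flows(P, 0.0, default_params)
        assert q[0] == pytest.approx(500.08, abs=0.01)

    def test_closed_mitral_valve(self, default_params):
        P = np.array([10.0, 0, 0, 0, 0, 5.0]) * MMHG_TO_BARYE
        q = ic.valve_flows(P, 0.0, default_params)
        assert q[0] == 0.0

    def test_unvalved_systemic_flow(self, default_params):
        P = np.array([0, 100.0, 5.0, 0, 0, 0]) * MMHG_TO_BARYE
        q = ic.valve_flows(P, 0.0, default_params)
        assert q[2] == pytest.approx(95.0, rel=1e-12)
        # reversed gradient flows backwards (no valve)
        q = ic.valve_flows(P[::-1] * 0 + P[[0, 2, 1, 3, 4, 5]], 0.0,
                           default_params)
        assert q[2] == pytest.approx(-95.0, rel=1e-12)

    def test_valved_flows_nonnegative_along_trajectory(self, default_traj):
        assert (default_traj.flows[:, [0, 1, 3, 4]] >= 0.0).all()


class TestRhs:
    def test_arterial_balance_value(self, default_params):
        # Ql_out = 0, Qa = 95 ml/s, Ca = 1.2e-3 -> dPa/dt = -59.38 mmHg/s
        P = np.array([0.0, 100.0, 5.0, 0, 0, 0]) * MMHG_TO_BARYE
        dP = ic.rhs(0.0, P, default_params)
        assert dP[1] / MMHG_TO_BARYE == pytest.approx(-59.38, abs=0.01)

    def test_quiescent_passive_compartments(self, default_params):
        # equal pressures -> zero flows; passive compartments at rest
        P = np.full(6, 10.0) * MMHG_TO_BARYE
        dP = ic.rhs(0.0, P, default_params)
        assert dP[[1, 2, 4]] == pytest.approx(np.zeros(3), abs=1e-12)

    def test_finite_difference_consistency_along_trajectory(
            self, default_traj, default_params):
        # centred differences of the solution match the vector field O(dt^2)
        t = default_traj.t
        P = default_traj.pressures_barye
        dt = t[1] - t[0]
        idx = np.arange(2000, 9000, 500)
        for i in idx:
            fd = (P[i + 1] - P[i - 1]) / (2 * dt)
            f = ic.rhs(t[i], P[i], default_params)
            scale = np.abs(f).max() + 1e3
            assert np.abs(fd - f).max() / scale < 5e-3

    def test_kernel_matches_reference_implementation(self, default_params,
                                                     rng):
        from invaert_cvsim.cvsim6 import _jac_kernel, _rhs_kernel
        theta = default_params.to_array()
        for _ in range(25):
            P = rng.normal(0.0, 2e4, size=6)
            t = rng.uniform(0.0, 3.0)
            np.testing.assert_allclose(
                _rhs_kernel(t, P, theta), ic.rhs(t, P, default_params),
                rtol=1e-12)
            np.testing.assert_allclose(
                _jac_kernel(t, P, theta),
                ic.system_matrix(t, P, default_params)[0], rtol=1e-12)


class TestInitialConditions:
    def test_zero_stressed_volume_gives_reference_pressures(
            self, default_params):
        p = default_params
        P0 = ic.initial_conditions(p, p.total_unstressed_volume)
        np.testing.assert_allclose(P0, _reference_pressures(p), atol=1e-9)

    def test_matches_least_squares_oracle(self, default_params):
        p = default_params
        P0 = ic.initial_conditions(p, 5000.0)
        # independent solve of the same constraints
        C = np.array([p.Cl_dia, p.Ca, p.Cv, p.Cr_dia, p.Cpa, p.Cpv])
        ref = _reference_pressures(p)
        M = np.zeros((6, 6))
        b = np.zeros(6)
        for i in range(5):
            M[i, i], M[i, i + 1] = 1.0, -1.0
            b[i] = ref[i] - ref[i + 1]
        M[5], b[5] = C, (5000.0 - p.total_unstressed_volume) + C @ ref
        lsq = np.linalg.lstsq(M, b, rcond=None)[0]
        np.testing.assert_allclose(P0, lsq, atol=1e-10 * np.abs(P0).max())

    @given(st.floats(3825.0, 7000.0))
    def test_mass_conservation_row(self, tbv):
        p = ic.default_parameters()
        P0 = ic.initial_conditions(p, tbv)
        C = np.array([p.Cl_dia, p.Ca, p.Cv, p.Cr_dia, p.Cpa, p.Cpv])
        stressed = C @ (P0 - _reference_pressures(p))
        assert stressed == pytest.approx(tbv - p.total_unstressed_volume,
                                         abs=1e-8)

    def test_insufficient_volume_rejected(self, default_params):
        with pytest.raises(CVSimError):
            ic.initial_conditions(default_params, 100.0)


class TestSimulate:
    def test_stressed_volume_conserved_default_run(self, default_traj):
        v = default_traj.total_stressed_volume
        assert np.abs(v - v[0]).max() / v[0] < 1e-6

    def test_stressed_volume_conserved_random_prior_draws(self):
        prior = ic.PriorSpec.synthetic()
        V = ic.sample_prior(prior, 20, seed=99)
        cfg = SimulationConfig(n_cycles=4)
        for row in V:
            traj = ic.simulate(ic.ParameterSet.from_array(row), cfg)
            assert traj.ok
            v = traj.total_stressed_volume
            assert np.abs(v - v[0]).max() / v[0] < 1e-6

    def test_periodic_convergence_of_outputs(self, default_traj,
                                             default_params):
        # outputs from the last three cycles vs the three preceding ones;
        # sub-mmHg components (right-heart diastolic pressures) are compared
        # on the scale of their measurement std instead of their tiny value
        from invaert_cvsim.cvsim6 import OUTPUT_STDS
        ttot = default_params.cycle_length
        y_last = ic.extract_outputs(default_traj,
                                    window=(9 * ttot, 12 * ttot)).to_array()
        y_prev = ic.extract_outputs(default_traj,
                                    window=(8 * ttot, 11 * ttot)).to_array()
        dev = np.abs(y_last - y_prev) / np.maximum(np.abs(y_last),
                                                   OUTPUT_STDS)
        assert dev.max() < 5e-3

    def test_explicit_rk4_instability_signature(self, default_traj,
                                                default_params):
        # with a 20 ms step the ventricular pressure drops below the
        # arterial pressure while the reference has the aortic valve open
        tr = ic.simulate(default_params,
                         SimulationConfig(solver="rk4", output_dt=2e-2))
        assert tr.ok
        ref = default_traj
        idx = np.clip(np.searchsorted(ref.t, tr.t), 0, ref.t.size - 1)
        ref_open = ref.pressures[idx, 0] > ref.pressures[idx, 1]
        pathologic = (ref_open & (tr.pressures[:, 0] < tr.pressures[:, 1])
                      & (tr.t > default_params.cycle_length))
        assert pathologic.sum() >= 10

    def test_invalid_cycle_count_rejected(self, default_params):
        with pytest.raises(CVSimError):
            ic.simulate(default_params, SimulationConfig(n_cycles=0))

    def test_lsoda_close_to_radau(self, default_traj, default_params):
        from invaert_cvsim.data import GENERATION_CONFIG
        tr = ic.simulate(default_params, GENERATION_CONFIG)
        y_fast = ic.extract_outputs(tr).to_array()
        y_ref = ic.extract_outputs(default_traj).to_array()
        assert np.abs((y_fast - y_ref) / y_ref).max() < 1e-3


class TestVolumes:
    def test_reference_pressure_gives_unstressed_volume(self, default_params):
        p = default_params
        t = np.array([0.0, 0.1])
        from invaert_cvsim.cvsim6 import _volumes_from_pressures
        P = np.tile(_reference_pressures(p), (2, 1))
        V, total = _volumes_from_pressures(t, P, p)
        np.testing.assert_allclose(
            V[0], [p.Vl0, p.Va0, p.Vv0, p.Vr0, p.Vpa0, p.Vpv0], atol=1e-10)
        np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_ventricular_volume_definition_at_start(self, default_traj,
                                                    default_params):
        p = default_params
        pl0 = default_traj.pressures_barye[0, 0]
        expected = p.Cl_dia * (pl0 - p.Pth * MMHG_TO_BARYE) + p.Vl0
        assert default_traj.volumes[0, 0] == pytest.approx(expected,
                                                           rel=1e-9)

    def test_recompute_matches_stored(self, default_traj):
        V, total = ic.compartment_volumes(default_traj)
        np.testing.assert_allclose(V, default_traj.volumes, rtol=1e-12)
        np.testing.assert_allclose(total, default_traj.total_stressed_volume,
                                   rtol=1e-9, atol=1e-9)


class TestExtractOutputs:
    def test_heart_rate_copied_and_invariants(self, default_traj,
                                              default_params):
        y = ic.extract_outputs(default_traj)
        assert y.Hr == default_params.Hr
        assert y.Pa_sys >= y.Pa_dia
        assert y.Ppa_sys >= y.Ppa_dia
        assert y.Vl_dia >= y.Vl_sys
        assert 0.0 <= y.LVEF <= 1.0

    def test_ejection_fraction_arithmetic(self):
        y = ic.ClinicalOutputs.from_array(np.ones(16))
        y.Vl_dia, y.Vl_sys = 120.0, 50.0
        assert (y.Vl_dia - y.Vl_sys) / y.Vl_dia == pytest.approx(70 / 120)

    def test_cardiac_output_consistent_with_stroke_volume(self,
                                                          default_traj):
        y = ic.extract_outputs(default_traj)
        sv = y.Vl_dia - y.Vl_sys                      # ml
        co_sv = sv * y.Hr / 1000.0                    # L/min
        assert abs(y.CO - co_sv) / y.CO < 0.02

    def test_vascular_resistances_equal_bed_resistances(self, default_traj,
                                                        default_params):
        # over an exact number of periodic cycles the mean flow through the
        # systemic (pulmonary) bed equals CO, so SVR = Ra and PVR = Rpv
        y = ic.extract_outputs(default_traj)
        assert y.SVR == pytest.approx(default_params.Ra, rel=1e-3)
        assert y.PVR == pytest.approx(default_params.Rpv, rel=2e-3)

    def test_short_trajectory_rejected(self, default_params):
        traj = ic.simulate(default_params, SimulationConfig(n_cycles=2))
        with pytest.raises(CVSimError):
            ic.extract_outputs(traj)


class TestParameterIO:
    def test_json_and_csv_round_trip(self, default_params, tmp_path):
        jp, cp = tmp_path / "p.json", tmp_path / "p.csv"
        default_params.to_json(jp)
        default_params.to_csv(cp)
        assert ic.ParameterSet.from_json(jp) == default_params
        assert ic.ParameterSet.from_csv(cp) == default_params

    def test_array_round_trip_and_validation(self, default_params):
        arr = default_params.to_array()
        assert ic.ParameterSet.from_array(arr) == default_params
        with pytest.raises(CVSimError):
            ic.ParameterSet.from_dict({"Hr": 70.0})
        with pytest.raises(CVSimError):
            default_params.replace(Cl_sys=1.0).validate()  # C_sys > C_dia

    def test_trajectory_hdf5_round_trip(self, default_params, tmp_path):
        traj = ic.simulate(default_params, SimulationConfig(n_cycles=3))
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = ic.Trajectory.from_hdf5(path)
        np.testing.assert_array_equal(back.pressures, traj.pressures)
        assert back.params == default_params
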