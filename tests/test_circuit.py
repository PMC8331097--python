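"""Circuit model: derivatives, integration, interventions, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgtremor.circuit import (
    CircuitState,
    DEFAULT_PARAMS,
    EPSILON_DA,
    REFERENCE_STATE,
    STATE_NAMES,
    IntegrationError,
    Intervention,
    InterventionSchedule,
    SimulationConfig,
    SteadyStateError,
    circuit_derivatives,
    integrate_circuit,
    mean_abs_percentage_error,
    steady_state,
)

ZERO_COUPLINGS = {name: 0.0 for name in (
    "a1Thal", "a2Ex", "a2DP", "a2IP", "a3Ex", "a3M1", "a3SNc", "a4DRN",
    "a5Ex", "a5DRN", "G", "a7Ex", "a7DA", "a8Ex", "alphaIP",
)}


class TestDerivatives:
    def test_zero_drives_zero_state_is_fixed_point(self):
        params = DEFAULT_PARAMS.replace(
            a2Ex=0.0, a3Ex=0.0, a5Ex=0.0, a7Ex=0.0, a8Ex=0.0, alphaIP=0.0)
        zero = CircuitState(**{name: 0.0 for name in STATE_NAMES})
        rates = circuit_derivatives(zero, params, t=0.3)
        assert rates.to_array() == pytest.approx(np.zeros(8), abs=1e-15)

    def test_hand_evaluated_serotonin_rate(self):
        # d(5HT)/dt = a4DRN*DRN - tau5HT*5HT at the reference point
        rates = circuit_derivatives(REFERENCE_STATE, DEFAULT_PARAMS)
        assert rates.fiveHT == pytest.approx(-0.0025944, abs=1e-7)

    def test_hand_evaluated_snc_rate(self):
        # d(SNc)/dt = a5Ex - a5DRN*DRN - tauSNc*SNc at the reference point
        rates = circuit_derivatives(REFERENCE_STATE, DEFAULT_PARAMS)
        assert rates.SNc == pytest.approx(-0.024534, abs=1e-6)

    def test_oscillatory_term_divides_by_guarded_da(self):
        params = DEFAULT_PARAMS
        t = 0.21
        state_hi = CircuitState(**{**REFERENCE_STATE.to_dict(), "DA": 2.0})
        state_lo = CircuitState(**{**REFERENCE_STATE.to_dict(), "DA": 0.0})
        base = params.a8Ex - params.tauIP * state_hi.IP
        osc = params.alphaIP * np.sin(params.fIP * t)
        assert circuit_derivatives(state_hi, params, t).IP == pytest.approx(
            base + osc / 2.0, rel=1e-12)
        # DA at zero falls back to the epsilon guard, not a division by zero
        assert circuit_derivatives(state_lo, params, t).IP == pytest.approx(
            base + osc / EPSILON_DA, rel=1e-12)

    def test_nonfinite_state_names_offending_variable(self):
        bad = CircuitState(**{**REFERENCE_STATE.to_dict(), "SNc": np.nan})
        with pytest.raises(IntegrationError) as err:
            circuit_derivatives(bad, DEFAULT_PARAMS)
        assert err.value.variable == "SNc"

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="tauSNc"):
            DEFAULT_PARAMS.replace(tauSNc=-1.0)


class TestIntegration:
    def test_linear_decay_matches_exponential_euler(self):
        # all couplings off, tauM1 = 1: dM1/dt = -M1, M1(0) = 1
        params = DEFAULT_PARAMS.replace(**ZERO_COUPLINGS, tauM1=1.0)
        y0 = CircuitState(**{**{n: 0.0 for n in STATE_NAMES}, "M1": 1.0})
        config = SimulationConfig(duration=5.0, dt=0.01,
                                  initial_state=y0, method="euler")
        traj = integrate_circuit(config, params)
        exact = np.exp(-traj.time)
        # explicit Euler: first-order global error, ~ dt/2 * t * e^-t peak
        assert np.max(np.abs(traj.series("M1") - exact)) < 5e-3

    def test_linear_decay_matches_exponential_rk4(self):
        params = DEFAULT_PARAMS.replace(**ZERO_COUPLINGS, tauM1=1.0)
        y0 = CircuitState(**{**{n: 0.0 for n in STATE_NAMES}, "M1": 1.0})
        config = SimulationConfig(duration=5.0, dt=0.1,
                                  initial_state=y0, method="rk4")
        traj = integrate_circuit(config, params)
        exact = np.exp(-traj.time)
        assert np.max(np.abs(traj.series("M1") - exact)) < 1e-6

    @pytest.mark.parametrize("method", ["euler", "rk4"])
    def test_fixed_point_is_preserved(self, quiet_params, method):
        config = SimulationConfig(duration=50.0, dt=0.1,
                                  initial_state=REFERENCE_STATE, method=method)
        traj = integrate_circuit(config, quiet_params)
        drift = np.abs(traj.states - REFERENCE_STATE.to_array()[None, :])
        assert drift.max() < 1e-9

    def test_trajectory_shape_and_grid(self, balanced_params):
        config = SimulationConfig(duration=10.0, dt=0.1)
        traj = integrate_circuit(config, balanced_params)
        assert traj.states.shape == (101, 8)
        assert traj.time[0] == 0.0
        assert traj.time[-1] == pytest.approx(10.0)
        assert np.all(np.diff(traj.time) > 0)

    def test_determinism_bit_identical(self, balanced_params):
        config = SimulationConfig(duration=30.0, dt=0.1)
        schedule = InterventionSchedule((Intervention(10.0, "tauSNc", 1.25),))
        a = integrate_circuit(config, balanced_params, schedule)
        b = integrate_circuit(config, balanced_params, schedule)
        assert np.array_equal(a.states, b.states)

    def test_intervention_locality(self, balanced_params):
        config = SimulationConfig(duration=40.0, dt=0.1)
        schedule = InterventionSchedule((Intervention(20.0, "tauSNc", 1.25),))
        plain = integrate_circuit(config, balanced_params)
        lesioned = integrate_circuit(config, balanced_params, schedule)
        before = plain.time <= 20.0 + 1e-9
        assert np.array_equal(plain.states[before], lesioned.states[before])
        after = plain.time > 25.0
        assert not np.allclose(plain.states[after], lesioned.states[after])

    def test_interventions_compose_multiplicatively(self, balanced_params):
        config = SimulationConfig(duration=30.0, dt=0.1)
        two_steps = InterventionSchedule((
            Intervention(5.0, "tauSNc", 1.2),
            Intervention(5.0, "tauSNc", 1.5),
        ))
        one_step = InterventionSchedule((Intervention(5.0, "tauSNc", 1.8),))
        a = integrate_circuit(config, balanced_params, two_steps)
        b = integrate_circuit(config, balanced_params, one_step)
        assert np.array_equal(a.states, b.states)

    def test_snc_lesion_direction_of_effects(self, balanced_params):
        # mild dopaminergic lesion: SNc and DA fall, DRN and 5-HT rise
        config = SimulationConfig(duration=200.0, dt=0.1)
        schedule = InterventionSchedule((
            Intervention(75.0, "tauSNc", 1.25),
            Intervention(75.0, "alphaIP", 1.11),
        ))
        traj = integrate_circuit(config, balanced_params, schedule)
        pre = traj.window_mean(60.0, 75.0)
        post = traj.window_mean(150.0, 200.0)
        assert post.SNc < pre.SNc
        assert post.DA < pre.DA
        assert post.DRN > pre.DRN
        assert post.fiveHT > pre.fiveHT
        assert post.Thal < pre.Thal
        assert post.M1 < pre.M1

    def test_blow_up_names_variable_and_time(self):
        # the published vector is dynamically inconsistent with the
        # reference state: DA collapses and the guarded 1/DA oscillation
        # blows the loop up within tens of seconds
        config = SimulationConfig(duration=300.0, dt=0.1)
        with pytest.raises(IntegrationError) as err:
            integrate_circuit(config, DEFAULT_PARAMS)
        assert err.value.variable in STATE_NAMES
        assert 0 < err.value.time <= 300.0

    def test_clamp_keeps_states_nonnegative(self):
        config = SimulationConfig(duration=300.0, dt=0.1,
                                  clamp_nonnegative=True)
        traj = integrate_circuit(config, DEFAULT_PARAMS)
        assert np.nanmin(traj.states) >= 0.0

    def test_csv_writer_header_and_rows(self, balanced_params, tmp_path):
        config = SimulationConfig(duration=1.0, dt=0.1)
        traj = integrate_circuit(config, balanced_params)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time,M1,Thal,DRN,fiveHT,SNc,DA,DP,IP"
        assert len(lines) == 12  # header + 11 samples


class TestSteadyState:
    def test_zero_drives_give_zero_steady_state(self):
        params = DEFAULT_PARAMS.replace(
            a2Ex=0.0, a3Ex=0.0, a5Ex=0.0, a7Ex=0.0, a8Ex=0.0, alphaIP=0.0)
        config = SimulationConfig(duration=300.0, dt=0.1)
        ss = steady_state(params, config)
        assert ss.to_array() == pytest.approx(np.zeros(8), abs=1e-3)

    def test_balanced_vector_reproduces_reference(self, balanced_params):
        ss = steady_state(balanced_params)
        assert mean_abs_percentage_error(ss, REFERENCE_STATE) < 3e-3

    @given(
        a4=st.floats(0.2, 5.0),
        tau=st.floats(0.5, 5.0),
        drn=st.floats(0.2, 10.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_serotonin_fixed_point_closed_form(self, a4, tau, drn):
        # with DRN frozen, steady 5-HT = a4DRN * DRN / tau5HT
        overrides = {**ZERO_COUPLINGS, "a4DRN": a4, "tau5HT": tau,
                     "a3Ex": 0.0, "tauDRN": 0.0}  # dDRN/dt = 0: DRN frozen
        params = DEFAULT_PARAMS.replace(**overrides)
        y0 = CircuitState(**{**{n: 0.0 for n in STATE_NAMES}, "DRN": drn})
        config = SimulationConfig(duration=120.0, dt=0.1, initial_state=y0)
        ss = steady_state(params, config)
        assert ss.fiveHT == pytest.approx(a4 * drn / tau, rel=1e-3)
        assert ss.DRN == pytest.approx(drn, rel=1e-12)

    def test_step_halving_leaves_steady_state(self, balanced_params):
        coarse = steady_state(
            balanced_params, SimulationConfig(duration=300.0, dt=0.1))
        fine = steady_state(
            balanced_params, SimulationConfig(duration=300.0, dt=0.05))
        rel = np.abs(coarse.to_array() - fine.to_array()) / fine.to_array()
        assert rel.max() < 1e-3

    def test_non_convergence_reports_last_mean(self, balanced_params):
        # a 3-s horizon cannot hold two 1-s windows that agree to 1e-6
        # while the transient from a displaced start is still decaying
        y0 = CircuitState(**{**REFERENCE_STATE.to_dict(), "M1": 40.0})
        config = SimulationConfig(duration=3.0, dt=0.01, initial_state=y0)
        with pytest.raises(SteadyStateError) as err:
            steady_state(balanced_params, config, window=1.0, tol=1e-6)
        assert err.value.last_mean is not None
        assert np.isfinite(err.value.last_mean.to_array()).all()


class TestOscillationClosedForm:
    def test_ip_oscillation_amplitude_and_mean(self):
        # with DA frozen (G = 0, tauDA = 0) the IP equation is a linear
        # ODE driven by (alphaIP/DA) sin(fIP t): mean a8Ex/tauIP,
        # amplitude (alphaIP/DA) / sqrt(tauIP^2 + fIP^2)
        da0 = 2.0
        overrides = {**ZERO_COUPLINGS, "G": 0.0, "tauDA": 0.0,
                     "a8Ex": 1.1229, "alphaIP": 7.3801}
        params = DEFAULT_PARAMS.replace(**overrides)
        y0 = CircuitState(**{**{n: 0.0 for n in STATE_NAMES},
                             "DA": da0, "IP": params.a8Ex / params.tauIP})
        config = SimulationConfig(duration=60.0, dt=0.01,
                                  initial_state=y0, method="rk4")
        traj = integrate_circuit(config, params)
        tail = traj.series("IP")[traj.time >= 40.0]
        expected_amp = (params.alphaIP / da0) / np.hypot(params.tauIP, params.fIP)
        expected_mean = params.a8Ex / params.tauIP
        assert (tail.max() - tail.min()) / 2 == pytest.approx(expected_amp, rel=0.01)
        assert tail.mean() == pytest.approx(expected_mean, rel=0.01)


class TestMeanAPE:
    def test_identical_states_give_zero(self, reference):
        assert mean_abs_percentage_error(reference, reference) == 0.0

    def test_known_relative_errors_average(self, reference):
        # perturb two variables by -50% and +25%: meanAPE = 0.75 / 8
        est = reference.to_dict()
        est["M1"] *= 0.5
        est["DA"] *= 1.25
        value = mean_abs_percentage_error(CircuitState(**est), reference)
        assert value == pytest.approx(0.75 / 8, rel=1e-12)

    def test_zero_reference_entry_rejected(self, reference):
        zero_ref = CircuitState(**{**reference.to_dict(), "DP": 0.0})
        with pytest.raises(ValueError, match="DP"):
            mean_abs_percentage_error(reference, zero_ref)
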