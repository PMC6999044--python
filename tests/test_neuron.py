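"""Single-neuron membrane model: gates, currents, EPSCs and protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moonjelly as mj
from moonjelly.errors import IntegrationError, ProtocolError
from moonjelly.neuron import GATE_NAMES, ap_inflection_voltage


class TestGateCurves:
    def test_steady_state_midpoint_and_saturation(self, neuron_params):
        for g in neuron_params.gates.values():
            assert mj.gate_steady_state(g.v_half, g) == pytest.approx(0.5)
            hi = mj.gate_steady_state(g.v_half + 1e3 * np.sign(g.rho), g)
            assert hi == pytest.approx(1.0, abs=1e-12)

    def test_steady_state_one_slope_above_midpoint(self, neuron_params):
        g = neuron_params.gates["a"]
        assert mj.gate_steady_state(g.v_half + g.rho, g) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)))

    def test_steady_state_monotone_for_positive_slope(self, neuron_params):
        g = neuron_params.gates["a"]  # rho > 0: activation gate
        v = np.linspace(-120.0, 120.0, 400)
        assert np.all(np.diff(mj.gate_steady_state(v, g)) > 0)

    def test_time_constant_peak_and_tails(self, neuron_params):
        for g in neuron_params.gates.values():
            assert mj.gate_time_constant(g.v_max, g) == pytest.approx(
                g.c_base + g.c_amp)
            assert mj.gate_time_constant(g.v_max + 1e4, g) == pytest.approx(
                g.c_base)
            v = np.linspace(-120, 120, 200)
            assert np.all(mj.gate_time_constant(v, g) >= g.c_base)

    def test_time_constant_one_sigma_from_peak(self, neuron_params):
        g = neuron_params.gates["a"]
        for v in (g.v_max - g.sigma, g.v_max + g.sigma):
            assert mj.gate_time_constant(v, g) == pytest.approx(
                g.c_base + g.c_amp / math.e)


class TestMembraneCurrents:
    def test_all_zero_at_leak_reversal_with_closed_gates(self, neuron_params):
        state = mj.NeuronState(v=neuron_params.e_l, gates=np.zeros(7))
        assert mj.membrane_currents(state, neuron_params) == pytest.approx(
            (0.0,) * 5)

    def test_outward_currents_vanish_at_their_reversal(self, neuron_params):
        state = mj.NeuronState(v=neuron_params.e_o, gates=np.full(7, 0.7))
        _, ift, ist, iss, _ = mj.membrane_currents(state, neuron_params)
        assert (ift, ist, iss) == pytest.approx((0.0, 0.0, 0.0))

    def test_fully_open_gates_at_zero_mv(self, neuron_params):
        p = neuron_params
        state = mj.NeuronState(v=0.0, gates=np.ones(7))
        ii, ift, ist, iss, il = mj.membrane_currents(state, p)
        assert ii == pytest.approx(345.0 * (0.0 - 76.7))
        assert ift == pytest.approx(39.8 * 84.6)
        assert ist == pytest.approx(27.2 * 84.6)
        assert iss == pytest.approx(10.8 * 84.6)
        assert il == pytest.approx(0.953 * 70.0)


class TestEpscCurrent:
    def test_zero_before_onset(self, syn_params):
        assert mj.epsc_current(-1.0, -70.0, syn_params) == 0.0

    def test_rectifier_blocks_above_reversal(self, syn_params):
        v = syn_params.e_syn + 10.0
        t = np.linspace(0.1, 50, 57)
        assert np.all(mj.epsc_current(t, v, syn_params) == 0.0)

    def test_closed_form_value(self, syn_params):
        s = syn_params
        t, v = 5.0, -70.0
        expected = (75.0 * (1 - math.exp(-t / 20.0))
                    * (0.957 * math.exp(-t / 3.0)
                       + 0.043 * math.exp(-t / 6.0)) * (4.32 - v))
        assert mj.epsc_current(t, v, s) == pytest.approx(expected, rel=1e-9)

    def test_nonnegative_driving_current(self, syn_params):
        t = np.linspace(-5, 100, 300)
        for v in (-90.0, -70.0, 0.0, 30.0):
            assert np.all(mj.epsc_current(t, v, syn_params) >= 0.0)


class TestActionPotential:
    def test_unstimulated_neuron_rests_near_minus_70(self, neuron_params,
                                                     syn_params):
        trace, spikes = mj.integrate_neuron(None, [], neuron_params,
                                            syn_params, T=100.0)
        assert spikes.size == 0
        assert trace.v == pytest.approx(-70.0, abs=2.0)
        assert np.ptp(trace.v) < 1e-6  # resting state is a fixed point

    def test_single_epsc_evokes_one_spike_peaking_near_2p5_ms(self, ap_run):
        trace, spikes = ap_run
        assert spikes.size == 1
        t_peak = trace.t[np.argmax(trace.v)]
        assert t_peak == pytest.approx(2.5, abs=0.5)
        assert trace.v.max() > 30.0

    def test_upstroke_inflection_below_release_threshold(self, ap_run):
        v_inf = ap_inflection_voltage(ap_run[0])
        assert np.isfinite(v_inf)
        assert -15.0 < v_inf < 20.0  # take-off between EPSP and spike phases

    def test_peak_time_converges_under_dt_halving(self, neuron_params,
                                                  syn_params):
        peaks = []
        for dt in (0.01, 0.005):
            trace, _ = mj.integrate_neuron(None, [0.0], neuron_params,
                                           syn_params, T=20.0, dt=dt)
            peaks.append(trace.t[np.argmax(trace.v)])
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.01

    def test_rectifier_disabled_reduces_spike_amplitude(self, neuron_params,
                                                        syn_params, ap_run):
        trace, _ = mj.integrate_neuron(
            None, [0.0], neuron_params.without("rectifier"), syn_params,
            T=30.0)
        assert trace.v.max() < ap_run[0].v.max()

    def test_current_decomposition_balances_capacitive_current(self, ap_run,
                                                               neuron_params):
        trace, _ = ap_run
        c = trace.currents
        resid = (c["II"] + c["IFT"] + c["IST"] + c["ISS"] + c["IL"]
                 - c["Isyn"]) + neuron_params.cm * np.gradient(trace.v, trace.t)
        scale = np.abs(c["II"]).max()
        assert np.abs(resid).max() < 0.02 * scale

    def test_divergent_state_raises_with_offending_time(self, syn_params):
        with pytest.raises(IntegrationError) as exc:
            mj.integrate_neuron(None, [0.0], mj.NeuronParams(cm=1e-7),
                                syn_params, T=10.0)
        assert exc.value.time_ms >= 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(v0=st.floats(-120.0, 120.0),
           v_gates=st.floats(-120.0, 120.0))
    def test_gating_variables_stay_in_unit_interval(self, v0, v_gates,
                                                    neuron_params, syn_params):
        gates = np.array([mj.gate_steady_state(v_gates, g)
                          for g in (neuron_params.gates[k]
                                    for k in GATE_NAMES)])
        state = mj.NeuronState(v=v0, gates=gates)
        trace, _ = mj.integrate_neuron(state, [0.0, 5.0], neuron_params,
                                       syn_params, T=30.0)
        assert np.all(trace.gates >= 0.0)
        assert np.all(trace.gates <= 1.0)


class TestRefractory:
    def test_lag_7_bump_only_lag_25_second_spike(self, neuron_params,
                                                 syn_params):
        res = mj.measure_refractory(neuron_params, syn_params,
                                    lags=[7.0, 25.0])
        assert res.max_post_spike_v[0] < syn_params.threshold
        assert res.max_post_spike_v[1] >= syn_params.threshold
        assert res.period == 25.0

    def test_protocol_failure_without_first_spike(self, neuron_params):
        weak = mj.SynapseParams(g_syn=0.1)
        with pytest.raises(ProtocolError):
            mj.measure_refractory(neuron_params, weak, lags=[10.0])


class TestVoltageClamp:
    def test_outward_currents_zero_when_clamped_at_their_reversal(
            self, neuron_params):
        tr = mj.simulate_voltage_clamp(-70.0, neuron_params.e_o,
                                       neuron_params, T=30.0)
        for key in ("IFT", "IST", "ISS"):
            assert np.all(tr.currents[key] == 0.0)

    def test_inward_current_zero_when_clamped_at_its_reversal(
            self, neuron_params):
        tr = mj.simulate_voltage_clamp(-70.0, neuron_params.e_i,
                                       neuron_params, T=30.0)
        assert np.all(tr.currents["II"] == 0.0)

    def test_step_to_plus_20_transient_inward_then_sustained_outward(
            self, neuron_params):
        tr = mj.simulate_voltage_clamp(-70.0, 20.0, neuron_params, T=50.0)
        total = tr.total
        early = total[tr.t < 5.0]
        assert early.min() < -100.0          # transient inward
        assert np.all(total[tr.t > 40.0] > 0)  # sustained outward


def test_parameter_yaml_round_trip(tmp_path, neuron_params, syn_params):
    path = tmp_path / "params.yaml"
    mj.save_params(path, neuron_params, syn_params)
    p2, s2 = mj.load_params(path)
    assert p2 == neuron_params
    assert s2 == syn_params


def test_trace_csv_and_hdf5_export(tmp_path, ap_run):
    import pandas as pd

    trace, _ = ap_run
    trace.save_csv(tmp_path / "trace.csv")
    df = pd.read_csv(tmp_path / "trace.csv")
    assert {"time_ms", "v_mV", "II_pA", "Isyn_pA"} <= set(df.columns)
    np.testing.assert_allclose(df.v_mV.to_numpy(), trace.v)
    trace.save_hdf5(tmp_path / "trace.h5")
    import h5py

    with h5py.File(tmp_path / "trace.h5") as f:
        np.testing.assert_array_equal(f["v_mV"][...], trace.v)
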