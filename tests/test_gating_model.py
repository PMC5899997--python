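import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navclamp.gating_model import (Epoch, GatingParams, InvalidParameterError,
                                   PopulationSpec, SimulationAccuracyError,
                                   SWEEP, VoltageProtocol, draw_biophysics,
                                   gate_time_constant, generate_cohort,
                                   simulate_sweep, steady_state_gate)


class TestSteadyStateGate:
    @pytest.mark.parametrize("V12,slope", [(-19.5, 6.4), (-65.3, 5.4), (0, 1)])
    def test_midpoint_is_half(self, V12, slope):
        assert steady_state_gate(V12, V12, slope, "increasing") == pytest.approx(0.5)
        assert steady_state_gate(V12, V12, slope, "decreasing") == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        # one slope-scaled log-unit of ln 9 above the midpoint leaves 10%
        V12, slope = -65.3, 5.4
        v = V12 + slope * math.log(9.0)
        assert steady_state_gate(v, V12, slope, "decreasing") == pytest.approx(0.1)

    def test_invalid_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            steady_state_gate(0.0, -20.0, 0.0, "increasing")

    @settings(derandomize=True, max_examples=30)
    @given(v1=st.floats(-120, 40), v2=st.floats(-120, 40))
    def test_strictly_monotone(self, v1, v2):
        if abs(v1 - v2) < 1e-6:
            return
        lo, hi = sorted((v1, v2))
        inc = steady_state_gate(np.array([lo, hi]), -20.0, 6.0, "increasing")
        dec = steady_state_gate(np.array([lo, hi]), -65.0, 5.0, "decreasing")
        assert inc[0] < inc[1]
        assert dec[0] > dec[1]


class TestGateTimeConstant:
    def test_inactivation_anchors(self, wt_params):
        # pinned to the measured open-state decay and recovery constants
        assert gate_time_constant(0.0, wt_params, "inactivation") == \
            pytest.approx(0.30)
        assert gate_time_constant(-80.0, wt_params, "inactivation") == \
            pytest.approx(5.63)

    def test_interpolation_bounded_between_anchors(self, wt_params):
        tau = gate_time_constant(-40.0, wt_params, "inactivation")
        assert 0.30 < tau < 5.63

    def test_clamped_outside_anchors(self, wt_params):
        assert gate_time_constant(-150.0, wt_params, "inactivation") == \
            pytest.approx(5.63)
        assert gate_time_constant(40.0, wt_params, "inactivation") == \
            pytest.approx(0.30)

    def test_activation_tau_at_0mV(self, wt_params):
        assert gate_time_constant(0.0, wt_params, "activation") == \
            pytest.approx(wt_params.tau_act_ms)

    def test_voltage_range_enforced(self, wt_params):
        with pytest.raises(InvalidParameterError):
            gate_time_constant(80.0, wt_params, "activation")


class TestSimulateSweep:
    def test_zero_conductance_is_silent(self, wt_params, protocols):
        p = replace(wt_params, gmax_density=0.0)
        trace = simulate_sweep(p, 15.0, protocols["activation"], 10)
        assert np.allclose(trace, 0.0)

    def test_instantaneous_gating_peak_matches_closed_form(self, wt_params):
        # with inactivation equilibrating much faster than activation (the
        # instantaneous-gating limit of the sampled trace), the peak equals
        # the equilibrium current gmax * C * m_inf^p * h_inf * (V - E_rev)
        V = -30.0
        proto = VoltageProtocol(
            name="act", holding_mV=-120.0,
            epochs=(Epoch("pre", -120.0, 1.0), Epoch("test", SWEEP, 3.0)),
            sweep_values=(V,), sample_interval_ms=0.002)
        p = replace(wt_params, tau_act_ms=0.2, tau_inact_0mV_ms=0.01,
                    tau_rec_m80mV_ms=0.01)
        cap = 15.0
        trace = simulate_sweep(p, cap, proto, 0)
        b_act = steady_state_gate(V, p.act_V12_mV, p.act_slope_mV,
                                  "increasing")
        h_inf = steady_state_gate(V, p.inact_V12_mV, p.inact_slope_mV,
                                  "decreasing")
        expected = p.gmax_density * cap * b_act * h_inf * (V - p.E_rev_mV)
        peak = trace[np.argmax(np.abs(trace))]
        assert peak == pytest.approx(expected, rel=1e-3)

    def test_hyperpolarizing_step_has_no_inward_transient(self, wt_params,
                                                          protocols):
        proto = protocols["activation"]
        i = proto.sweep_values.index(-100.0)
        trace = simulate_sweep(wt_params, 15.0, proto, i)
        assert trace.min() > -10.0  # no transient beyond the tiny holding current

    def test_peak_linear_in_gmax(self, wt_params, protocols):
        proto = protocols["activation"]
        i0 = proto.sweep_values.index(0.0)
        peaks = []
        for g in (5.0, 10.0):
            p = replace(wt_params, gmax_density=g)
            peaks.append(np.abs(simulate_sweep(p, 15.0, proto, i0)).max())
        assert peaks[1] == pytest.approx(2.0 * peaks[0], rel=1e-9)

    def test_availability_equals_boltzmann_at_fast_gating(self, wt_params):
        # tail peaks after long prepulses trace the decreasing Boltzmann when
        # gating is much faster than the epochs: a Boltzmann fit of the tail
        # peaks recovers the inactivation midpoint and slope
        from navclamp.trace_analysis import fit_boltzmann
        proto = VoltageProtocol(
            name="inact", holding_mV=-120.0,
            epochs=(Epoch("pre", -120.0, 1.0), Epoch("prepulse", SWEEP, 30.0),
                    Epoch("tail", -10.0, 2.0)),
            sweep_values=tuple(float(v) for v in range(-150, 10, 10)),
            sample_interval_ms=0.0005)
        p = replace(wt_params, tau_act_ms=0.005, tau_inact_0mV_ms=0.05,
                    tau_rec_m80mV_ms=0.05)
        tails = []
        for i in range(proto.n_sweeps):
            trace = simulate_sweep(p, 15.0, proto, i)
            tail = trace[int(31.0 / 0.0005):]
            tails.append(np.abs(tail).max())
        fit = fit_boltzmann(proto.sweep_values, tails, "decreasing")
        assert fit.V12_mV == pytest.approx(p.inact_V12_mV, abs=0.15)
        assert fit.Vslope_mV == pytest.approx(p.inact_slope_mV, abs=0.1)

    def test_refuses_coarse_sampling(self, wt_params):
        proto = VoltageProtocol(
            name="x", holding_mV=-80.0,
            epochs=(Epoch("pre", -80.0, 1.0), Epoch("test", SWEEP, 5.0)),
            sweep_values=(0.0,), sample_interval_ms=0.1)
        with pytest.raises(SimulationAccuracyError):
            simulate_sweep(wt_params, 15.0, proto, 0)

    def test_deterministic_given_rng_seed(self, wt_params, protocols):
        t1 = simulate_sweep(wt_params, 15.0, protocols["activation"], 8,
                            noise_sd_pA=10.0, rng=np.random.default_rng(5))
        t2 = simulate_sweep(wt_params, 15.0, protocols["activation"], 8,
                            noise_sd_pA=10.0, rng=np.random.default_rng(5))
        assert np.array_equal(t1, t2)


class TestStandardProtocols:
    def test_activation_sweeps(self, protocols):
        act = protocols["activation"]
        assert act.n_sweeps == 16
        assert act.sweep_values[0] == -100.0 and act.sweep_values[-1] == 50.0
        assert act.holding_mV == -80.0

    def test_inactivation_prepulse(self, protocols):
        inact = protocols["inactivation"]
        assert inact.n_sweeps == 16
        assert inact.sweep_values[0] == -150.0 and inact.sweep_values[-1] == 0.0
        pre = [e for e in inact.epochs if e.label == "prepulse"][0]
        assert pre.duration_ms == 150.0

    def test_recovery_zero_interval_degenerates(self, protocols):
        rec = protocols["recovery"]
        assert 0.0 in rec.sweep_values
        assert {1.0, 2.0, 5.0, 10.0, 20.0} <= set(rec.sweep_values)
        i0 = rec.sweep_values.index(0.0)
        samples = rec.epoch_samples(i0)
        labels = [s[0] for s in samples]
        assert samples[labels.index("interval")][2] == 0  # P2 follows P1

    def test_recovery_sweeps_padded_to_common_length(self, protocols):
        rec = protocols["recovery"]
        lengths = {rec.n_samples(i) for i in range(rec.n_sweeps)}
        assert len(lengths) == 1

    def test_protocol_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            VoltageProtocol("bad", -80.0,
                            (Epoch("a", -80.0, 0.0), Epoch("b", SWEEP, 5.0)),
                            (0.0,), 0.02)
        with pytest.raises(InvalidParameterError):  # two sweep epochs
            VoltageProtocol("bad", -80.0,
                            (Epoch("a", SWEEP, 1.0), Epoch("b", SWEEP, 5.0)),
                            (0.0,), 0.02)
        with pytest.raises(InvalidParameterError):  # no sweep epoch
            VoltageProtocol("bad", -80.0, (Epoch("a", -80.0, 1.0),),
                            (0.0,), 0.02)


class TestGenerateCohort:
    def _spec(self, **kw):
        defaults = dict(variant_id="wt", n_cells=2,
                        param_means=GatingParams(),
                        param_cv={"act_V12_mV": 0.05, "gmax_density": 0.2},
                        noise_sd_pA=5.0, seed=3)
        defaults.update(kw)
        return PopulationSpec(**defaults)

    def test_empty_cohort(self):
        cells, truth = generate_cohort(self._spec(n_cells=0))
        assert cells == [] and truth.empty

    def test_cv_zero_shares_means(self):
        spec = self._spec(param_cv={"act_V12_mV": 0.0, "gmax_density": 0.0},
                          noise_sd_pA=0.0)
        _, truth = generate_cohort(spec)
        assert truth["act_V12_mV"].nunique() == 1
        assert truth["gmax_density"].nunique() == 1

    def test_seed_reproducibility(self, protocols):
        c1, t1 = generate_cohort(self._spec(), protocols)
        c2, t2 = generate_cohort(self._spec(), protocols)
        assert t1.equals(t2)
        assert np.array_equal(c1[0].recordings["activation"].data,
                              c2[0].recordings["activation"].data)
        c3, _ = generate_cohort(self._spec(seed=4), protocols)
        assert not np.array_equal(c1[0].recordings["activation"].data,
                                  c3[0].recordings["activation"].data)

    def test_recovery_protocol_limited_to_subset(self, protocols):
        cells, truth = generate_cohort(self._spec(n_cells=3, n_recovery=1),
                                       protocols)
        assert "recovery" in cells[0].recordings
        assert "recovery" not in cells[2].recordings
        assert truth["has_recovery"].tolist() == [True, False, False]


class TestDrawBiophysics:
    def test_moments_match_spec(self, summary):
        from conftest import spec_from_row
        row = summary.iloc[0]
        spec = spec_from_row(row, seed=9, n_cells=4000, n_recovery=4000)
        df = draw_biophysics(spec)
        assert df["act_V12_mV"].mean() == pytest.approx(-19.5, abs=0.15)
        sd = df["act_V12_mV"].std()
        assert sd == pytest.approx(0.2 * math.sqrt(146), rel=0.1)
        assert df["tau_rec_ms"].min() > 0

    def test_recovery_subset_is_nan(self, summary):
        from conftest import spec_from_row
        spec = spec_from_row(summary.iloc[0], n_cells=10, n_recovery=4)
        df = draw_biophysics(spec)
        assert df["tau_rec_ms"].notna().sum() == 4
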