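import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navclamp.calibration import calibrate_gating_params
from navclamp.gating_model import (GatingParams, build_standard_protocols,
                                   simulate_cell)
from navclamp.trace_analysis import (AnalysisConfig, BoltzmannFit,
                                     CellBiophysics, analyze_cell,
                                     conductance_curve, estimate_reversal,
                                     fit_boltzmann, fit_exponential,
                                     normalize_to_fit, peak_current,
                                     qc_filter, summarize_variant)

WT_TARGETS = {
    "Ipeak_density_pA_per_pF": -127.5, "act_V12_mV": -19.5,
    "act_Vslope_mV": 6.4, "inact_V12_mV": -65.3, "inact_Vslope_mV": 5.4,
    "tau_inact_0mV_ms": 0.30, "tau_rec_ms": 5.63,
}


def boltzmann(V, lo, hi, V12, slope, direction="increasing"):
    z = (V12 - V) / slope if direction == "increasing" else (V - V12) / slope
    return lo + (hi - lo) / (1.0 + np.exp(z))


class TestPeakCurrent:
    def test_flat_trace_peaks_at_zero(self):
        t = np.arange(100) * 0.1
        assert peak_current(np.zeros(100), t, (2.0, 8.0), (0.0, 2.0)) == 0.0

    def test_single_negative_deflection(self):
        t = np.arange(100) * 0.1
        trace = np.zeros(100)
        trace[40:45] = -1200.0
        assert peak_current(trace, t, (2.0, 8.0), (0.0, 2.0)) == -1200.0

    def test_baseline_subtracted(self):
        t = np.arange(100) * 0.1
        trace = np.full(100, -50.0)
        trace[40] = -1250.0
        assert peak_current(trace, t, (2.0, 8.0), (0.0, 2.0)) == \
            pytest.approx(-1200.0)

    def test_empty_window_rejected(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ValueError):
            peak_current(np.zeros(10), t, (5.0, 5.0))


class TestEstimateReversal:
    def test_linear_limb_extrapolates_to_true_reversal(self):
        V = np.arange(-40, 60, 10, dtype=float)
        I = 20.0 * (V - 65.0) * boltzmann(V, 0, 1, -19.5, 6.4)
        erev, ok = estimate_reversal(list(zip(V, I)))
        assert ok and erev == pytest.approx(65.0, abs=1.0)

    def test_scale_invariance(self):
        V = np.arange(-40, 60, 10, dtype=float)
        I = 20.0 * (V - 65.0) * boltzmann(V, 0, 1, -19.5, 6.4)
        e1, _ = estimate_reversal(list(zip(V, I)))
        e2, _ = estimate_reversal(list(zip(V, 7.3 * I)))
        assert e1 == pytest.approx(e2)

    def test_degenerate_iv_falls_back_with_warning(self):
        V = np.arange(-40, 60, 10, dtype=float)
        with pytest.warns(UserWarning):
            erev, ok = estimate_reversal([(v, 0.0) for v in V])
        assert not ok and erev == 65.0


class TestConductanceCurve:
    def test_chord_conductance_arithmetic(self):
        # -1000 pA at 0 mV with reversal at +65 mV is 15.38 nS
        (v, g), = conductance_curve([(0.0, -1000.0)], 65.0)
        assert g == pytest.approx(15.384615, rel=1e-6)

    def test_zero_current_zero_conductance(self):
        gv = conductance_curve([(v, 0.0) for v in (-40.0, -20.0, 0.0)], 65.0)
        assert all(g == 0.0 for _, g in gv)

    def test_points_near_reversal_excluded(self):
        gv = conductance_curve([(62.0, 10.0), (40.0, -100.0)], 65.0)
        assert [v for v, _ in gv] == [40.0]


class TestFitBoltzmann:
    def test_exact_recovery_on_noiseless_data(self):
        V = np.arange(-80, 60, 10, dtype=float)
        y = boltzmann(V, 0.0, 1.0, -19.5, 6.4)
        fit = fit_boltzmann(V, y, "increasing")
        assert fit.converged
        assert fit.V12_mV == pytest.approx(-19.5, abs=1e-6)
        assert fit.Vslope_mV == pytest.approx(6.4, abs=1e-6)

    def test_fitted_curve_at_midpoint_is_half_span(self):
        V = np.arange(-120, 0, 10, dtype=float)
        y = boltzmann(V, 0.2, 1.7, -65.3, 5.4, "decreasing")
        fit = fit_boltzmann(V, y, "decreasing")
        assert fit.predict(fit.V12_mV) == pytest.approx((fit.A + fit.B) / 2)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        V = np.arange(-80, 60, 10, dtype=float)
        y = boltzmann(V, 0.0, 1.0, -22.0, 7.0) + rng.normal(0, 0.02, V.size)
        fit = fit_boltzmann(V, y, "increasing", fix_amplitudes=(0.0, 1.0))
        # independent dense grid search over (V12, slope)
        v12s = np.linspace(-35, -10, 301)
        slopes = np.linspace(4.0, 10.0, 241)
        grid_rss, best = math.inf, None
        for v12 in v12s:
            preds = boltzmann(V[None, :], 0.0, 1.0, v12, slopes[:, None])
            rss = ((preds - y[None, :]) ** 2).sum(axis=1)
            k = int(np.argmin(rss))
            if rss[k] < grid_rss:
                grid_rss, best = rss[k], (v12, slopes[k])
        assert fit.V12_mV == pytest.approx(best[0], abs=0.1)
        assert fit.Vslope_mV == pytest.approx(best[1], abs=0.05)

    @settings(derandomize=True, max_examples=20)
    @given(shift=st.floats(-40, 40))
    def test_shift_equivariance(self, shift):
        V = np.arange(-80, 60, 10, dtype=float)
        y = boltzmann(V, 0.0, 1.0, -19.5, 6.4)
        f0 = fit_boltzmann(V, y, "increasing")
        f1 = fit_boltzmann(V + shift, y, "increasing")
        assert f1.V12_mV - f0.V12_mV == pytest.approx(shift, abs=1e-4)
        assert f1.Vslope_mV == pytest.approx(f0.Vslope_mV, abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0, 1, 2, 3], [0, 0.1, 0.9, 1], "increasing")


class TestNormalizeToFit:
    def _fit(self):
        return BoltzmannFit(A=2.0, B=0.5, V12_mV=-20.0, Vslope_mV=6.0,
                            rss=0.0, converged=True)

    def test_asymptotes_map_to_unit_interval(self):
        fit = self._fit()
        out = normalize_to_fit([0.5, 1.25, 2.0], fit)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_degenerate_fit_rejected(self):
        fit = BoltzmannFit(A=1.0, B=1.0, V12_mV=0, Vslope_mV=6, rss=0.0,
                           converged=True)
        with pytest.raises(ValueError):
            normalize_to_fit([1.0], fit)

    def test_refit_after_normalization_preserves_shape(self):
        V = np.arange(-120, 0, 10, dtype=float)
        y = boltzmann(V, 0.3, 1.8, -65.3, 5.4, "decreasing")
        fit = fit_boltzmann(V, y, "decreasing")
        norm = normalize_to_fit(y, fit)
        refit = fit_boltzmann(V, norm, "decreasing", fix_amplitudes=(0.0, 1.0))
        assert refit.V12_mV == pytest.approx(fit.V12_mV, abs=1e-6)
        assert refit.Vslope_mV == pytest.approx(fit.Vslope_mV, abs=1e-6)


class TestFitExponential:
    def test_exact_single_exponential(self):
        t = np.linspace(0, 30, 120)
        y = 1.5 - 0.8 * np.exp(-t / 5.63)
        fit = fit_exponential(t, y, 1)
        assert fit.components[0][1] == pytest.approx(5.63, abs=1e-6)
        assert fit.offset == pytest.approx(1.5, abs=1e-6)

    def test_double_exponential_fast_component(self):
        t = np.linspace(0, 12, 400)
        y = 0.95 * np.exp(-t / 0.3) + 0.05 * np.exp(-t / 3.0)
        fit = fit_exponential(t, y, 2)
        assert fit.components[0][1] == pytest.approx(0.3, abs=1e-4)
        assert fit.fast_fraction == pytest.approx(0.95, abs=1e-3)
        assert not fit.warnings

    def test_minor_fast_component_recorded_as_warning(self):
        t = np.linspace(0, 12, 400)
        y = 0.5 * np.exp(-t / 0.3) + 0.5 * np.exp(-t / 3.0)
        fit = fit_exponential(t, y, 2)
        assert any("0.95" in w for w in fit.warnings)

    def test_constant_input_flagged_degenerate(self):
        t = np.linspace(0, 10, 50)
        fit = fit_exponential(t, np.full(50, 3.0), 1)
        assert fit.components[0][0] == 0.0
        assert any("degenerate" in w for w in fit.warnings)

    def test_time_rescaling_rescales_tau(self):
        t = np.linspace(0, 20, 100)
        y = np.exp(-t / 2.5)
        tau1 = fit_exponential(t, y, 1).components[0][1]
        tau2 = fit_exponential(3.0 * t, y, 1).components[0][1]
        assert tau2 == pytest.approx(3.0 * tau1, rel=1e-9)

    def test_unsorted_time_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 2, 1, 3, 4, 5], [1, 2, 3, 4, 5, 6], 1)


class TestQcTiers:
    def _cell(self, ipk_pa, rs_mohm=1.0):
        c = CellBiophysics(cell_id="c", variant_id="v", Ipeak_0mV_pA=ipk_pa)
        c.Rs_error_mV = abs(ipk_pa) * rs_mohm * 1e-3
        return c

    def test_intermediate_current_density_tier_only(self):
        df = qc_filter([self._cell(-400.0)])
        assert df["qc_density_pass"].item()
        assert not df["qc_biophysics_pass"].item()

    def test_series_resistance_error_excludes_from_biophysics(self):
        # 2 nA through 3 MOhm is a 6 mV command error
        df = qc_filter([self._cell(-2000.0, rs_mohm=3.0)])
        assert df["qc_density_pass"].item()
        assert not df["qc_biophysics_pass"].item()

    def test_small_current_excluded_everywhere(self):
        df = qc_filter([self._cell(-50.0)])
        assert not df["qc_density_pass"].item()
        assert not df["qc_biophysics_pass"].item()

    def test_tiers_nested(self):
        rng = np.random.default_rng(0)
        cells = [self._cell(float(i), rs_mohm=r) for i, r in
                 zip(rng.uniform(-3000, 0, 50), rng.uniform(0.3, 4.0, 50))]
        df = qc_filter(cells)
        assert (df["qc_biophysics_pass"] <= df["qc_density_pass"]).all()


class TestSummarizeVariant:
    def _frame(self, values, variant="v"):
        cells = []
        for i, val in enumerate(values):
            c = CellBiophysics(cell_id=f"c{i}", variant_id=variant,
                               Ipeak_0mV_pA=-1000.0,
                               Ipeak_density_pA_per_pF=-100.0,
                               act_V12_mV=val, Rs_error_mV=1.0)
            cells.append(c)
        return qc_filter(cells)

    def test_single_cell_se_zero_with_note(self):
        out = summarize_variant(self._frame([-19.0]))
        row = out[out["parameter"] == "act_V12_mV"].iloc[0]
        assert row["N"] == 1 and row["se"] == 0.0 and "single" in row["note"]

    def test_duplicate_cells_have_zero_se(self):
        out = summarize_variant(self._frame([-19.0, -19.0, -19.0]))
        row = out[out["parameter"] == "act_V12_mV"].iloc[0]
        assert row["N"] == 3 and row["se"] == 0.0

    def test_se_is_sd_over_sqrt_n(self):
        vals = [-18.0, -19.0, -20.0, -21.0]
        out = summarize_variant(self._frame(vals))
        row = out[out["parameter"] == "act_V12_mV"].iloc[0]
        assert row["se"] == pytest.approx(np.std(vals, ddof=1) / 2.0)


@pytest.fixture(scope="module")
def wt_cell_bio(protocols):
    latent = calibrate_gating_params(WT_TARGETS, protocols=protocols)
    cell = simulate_cell(latent, 15.0, 0.8, protocols,
                         cell_id="rt", variant_id="rt")
    return analyze_cell(cell, AnalysisConfig())


class TestCellRoundTrip:
    """Simulate a calibrated cell without variability and re-measure it."""

    def test_midpoints_within_fit_tolerance(self, wt_cell_bio):
        assert wt_cell_bio.act_V12_mV == pytest.approx(-19.5, abs=0.2)
        assert wt_cell_bio.inact_V12_mV == pytest.approx(-65.3, abs=0.2)

    def test_slopes_and_density(self, wt_cell_bio):
        assert wt_cell_bio.act_Vslope_mV == pytest.approx(6.4, abs=0.2)
        assert wt_cell_bio.inact_Vslope_mV == pytest.approx(5.4, abs=0.2)
        assert wt_cell_bio.Ipeak_density_pA_per_pF == \
            pytest.approx(-127.5, rel=0.02)

    def test_time_constants_within_two_percent(self, wt_cell_bio):
        assert wt_cell_bio.tau_inact_0mV_ms == pytest.approx(0.30, rel=0.02)
        assert wt_cell_bio.tau_rec_ms == pytest.approx(5.63, rel=0.02)

    def test_density_invariant_under_capacitance(self, protocols):
        latent = calibrate_gating_params(WT_TARGETS, protocols=protocols)
        dens = []
        for cap in (10.0, 20.0):
            cell = simulate_cell(latent, cap, 0.8, protocols,
                                 cell_id="c", variant_id="c")
            dens.append(analyze_cell(cell).Ipeak_density_pA_per_pF)
        assert dens[0] == pytest.approx(dens[1], rel=1e-6)

    def test_averaged_availability_monotone_decreasing(self, protocols):
        # per-cell normalised availability curves, averaged over a noisy
        # cohort, decrease with prepulse depolarisation (up to noise)
        from navclamp.calibration import population_from_summary
        from navclamp.gating_model import generate_cohort
        from navclamp.reference_data import biophysics_summary
        from navclamp.trace_analysis import normalized_availability
        spec = population_from_summary(biophysics_summary().iloc[0], seed=6,
                                       n_cells=4, n_recovery=0)
        cells, _ = generate_cohort(spec, protocols)
        curves = [normalized_availability(c)[1] for c in cells]
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) < 0.02)
        assert mean_curve[0] > 0.97 and mean_curve[-1] < 0.03

    def test_halving_tau_h_halves_fitted_onset_tau(self):
        # scaling oracle needs activation much faster than the decay, else
        # the fitted decay constant is kinetically confounded
        fast = build_standard_protocols(sample_interval_ms=0.005)
        taus = []
        for tau_h in (0.30, 0.15):
            p = GatingParams(tau_act_ms=0.05, tau_inact_0mV_ms=tau_h)
            cell = simulate_cell(p, 15.0, 0.8,
                                 {"activation": fast["activation"]},
                                 cell_id="h", variant_id="h")
            taus.append(analyze_cell(cell).tau_inact_0mV_ms)
        assert taus[1] / taus[0] == pytest.approx(0.5, rel=0.03)
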