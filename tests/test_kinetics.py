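"""Current-kinetics extraction: detection, exponential fits, classification."""

import numpy as np
import pytest

from pilarray import synth
from pilarray.kinetics import (CurrentKinetics, CurrentKineticsModel,
                               CurrentTrace, classify_rapid, detect_event,
                               fit_activation, fit_decay, rectification_summary,
                               summarize_kinetics)
from pilarray.synth import TraceSpec, generate_current_trace
from tests.conftest import fixed_phenotype


def run_model(spec, phen, deflection=500.0, **kw):
    trace, truth = generate_current_trace(spec, phen, deflection, **kw)
    return CurrentKineticsModel(trace).fit(), truth


class TestDetection:
    def test_pure_noise_trace_not_a_response(self):
        rng = np.random.default_rng(0)
        trace = CurrentTrace(rng.normal(0, 2, 2000), 10_000.0, stimulus_onset=50.0)
        det = detect_event(trace)
        assert not det.responded

    def test_noiseless_latency_within_one_sample(self, clean_trace_spec):
        kin, truth = run_model(clean_trace_spec, fixed_phenotype(latency=3.6))
        assert kin.responded
        assert kin.latency_ms == pytest.approx(3.6, abs=0.1)

    def test_threshold_monotonicity_flips_response(self):
        spec = TraceSpec(baseline_noise_sd_pA=5.0, seed=1)
        trace, truth = generate_current_trace(spec, fixed_phenotype(amp=150.0), 500.0)
        assert detect_event(trace, k_sd=5.0).responded
        assert not detect_event(trace, k_sd=1e6).responded

    def test_short_baseline_rejected(self, clean_trace_spec):
        trace, _ = generate_current_trace(clean_trace_spec, fixed_phenotype(), 500.0)
        with pytest.raises(ValueError):
            detect_event(trace, baseline_window_ms=0.5)


class TestActivationFit:
    @pytest.mark.parametrize("tau1", [1.7, 0.5])
    def test_noiseless_recovery_within_one_percent(self, clean_trace_spec, tau1):
        kin, truth = run_model(clean_trace_spec, fixed_phenotype(tau1=tau1, latency=3.0))
        assert kin.tau1_ms == pytest.approx(tau1, rel=0.01)

    def test_time_axis_rescaling_doubles_tau(self, unfiltered_trace_spec):
        """Halving the sampling rate (same samples) doubles the fitted τ1."""
        trace, truth = generate_current_trace(unfiltered_trace_spec,
                                              fixed_phenotype(), 500.0)
        slow = CurrentTrace(trace.samples, trace.sampling_rate / 2,
                            trace.stimulus_onset * 2, trace.holding_potential)
        fast_fit = CurrentKineticsModel(trace).fit()
        slow_fit = CurrentKineticsModel(slow, baseline_window_ms=20.0).fit()
        assert slow_fit.tau1_ms == pytest.approx(2 * fast_fit.tau1_ms, rel=1e-3)

    def test_too_few_samples_flagged_unfittable(self):
        t = np.zeros(2000)
        t[600:] = -50.0  # instantaneous step: no rising phase to fit
        trace = CurrentTrace(t, 10_000.0, stimulus_onset=50.0)
        fit = fit_activation(trace, 60.0, 60.2)
        assert fit.tau1_ms is None


class TestDecayFit:
    def test_noiseless_recovery_within_one_percent(self, clean_trace_spec):
        kin, truth = run_model(clean_trace_spec, fixed_phenotype(tau2=12.2))
        assert kin.tau2_ms == pytest.approx(12.2, rel=0.01)

    def test_offset_invariance(self, unfiltered_trace_spec):
        trace, _ = generate_current_trace(unfiltered_trace_spec, fixed_phenotype(), 500.0)
        kin0 = CurrentKineticsModel(trace).fit()
        shifted = CurrentTrace(trace.samples - 30.0, trace.sampling_rate,
                               trace.stimulus_onset, trace.holding_potential)
        kin1 = CurrentKineticsModel(shifted).fit()
        assert kin1.tau2_ms == pytest.approx(kin0.tau2_ms, rel=1e-6)

    def test_grid_search_oracle_agreement(self):
        """Brute-force (A, τ2, C) grid on a 50-sample decay agrees with the
        least-squares fitter within 2%."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            tau = rng.uniform(2.0, 8.0)  # resolvable within the 5 ms window
            a = rng.uniform(50.0, 200.0)
            c = rng.uniform(-5.0, 5.0)
            t = np.arange(50) * 0.1
            y = a * np.exp(-t / tau) + c + rng.normal(0, 1.0, 50)
            samples = np.concatenate([np.zeros(100), y])
            trace = CurrentTrace(samples, 10_000.0, stimulus_onset=5.0)
            tau_fit, _ = fit_decay(trace, peak_time_ms=10.0, window_end_ms=14.9)
            # grid over tau; (A, C) solved exactly by linear least squares
            best, best_tau = np.inf, None
            for tg in np.linspace(0.5, 20.0, 2000):
                basis = np.column_stack([np.exp(-t / tg), np.ones_like(t)])
                coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
                sse = float(res[0]) if len(res) else np.sum((basis @ coef - y) ** 2)
                if sse < best:
                    best, best_tau = sse, tg
            assert tau_fit == pytest.approx(best_tau, rel=0.02)


class TestClassification:
    @pytest.mark.parametrize("latency,rapid", [(3.6, True), (7.8, False), (5.0, False)])
    def test_latency_boundary_strict(self, latency, rapid):
        kin = CurrentKinetics(responded=True, latency_ms=latency, tau1_ms=1.7,
                              tau2_ms=12.0, peak_amplitude_pA=100.0)
        assert classify_rapid(kin).rapid_gating is rapid

    def test_direct_gating_needs_fast_activation(self):
        slow = CurrentKinetics(responded=True, latency_ms=3.6, tau1_ms=1.7,
                               tau2_ms=12.0, peak_amplitude_pA=100.0)
        fast = CurrentKinetics(responded=True, latency_ms=3.6, tau1_ms=0.5,
                               tau2_ms=12.0, peak_amplitude_pA=100.0)
        assert not classify_rapid(slow).direct_gating
        assert classify_rapid(fast).direct_gating

    def test_nonresponder_rejected(self):
        with pytest.raises(ValueError):
            classify_rapid(CurrentKinetics(responded=False))


class TestPolaritySymmetry:
    def test_magnitudes_invariant_under_polarity_flip(self, clean_trace_spec):
        """Outward events at +60 mV report the same magnitudes as inward
        events at −60 mV."""
        phen = fixed_phenotype()
        spec_neg = TraceSpec(baseline_noise_sd_pA=0.0, holding_potential_mV=-60.0, seed=7)
        spec_pos = TraceSpec(baseline_noise_sd_pA=0.0, holding_potential_mV=60.0, seed=7)
        kn, _ = run_model(spec_neg, phen)
        kp, _ = run_model(spec_pos, phen)
        assert kn.amplitude_sign == -1 and kp.amplitude_sign == 1
        assert kn.peak_amplitude_pA == pytest.approx(kp.peak_amplitude_pA, rel=1e-9)
        assert kn.tau2_ms == pytest.approx(kp.tau2_ms, rel=1e-9)


class TestRectification:
    def _events(self, phen_name, potential, n, rng):
        phen = synth.PHENOTYPES[phen_name]
        out = []
        for _ in range(n):
            spec = TraceSpec(baseline_noise_sd_pA=3.0,
                             holding_potential_mV=potential, seed=0)
            trace, _ = generate_current_trace(spec, phen, 900.0, rng=rng,
                                              responder=True, threshold_nm=0.0)
            out.append(CurrentKineticsModel(trace).fit())
        return out

    def test_voltage_independent_channel_shows_no_contrast(self, rng):
        """TRPV4-like cohorts at realistic sizes: amplitude and τ2 do not
        differ between −60 and +60 mV."""
        neg = self._events("TRPV4-like", -60.0, 30, rng)
        pos = self._events("TRPV4-like", 60.0, 20, rng)
        table = rectification_summary(neg, pos)
        assert (table["p_value"] > 0.05).all()

    def test_identical_event_lists_give_zero_contrast(self, rng):
        events = self._events("TRPV4-like", -60.0, 5, rng)
        table = rectification_summary(events, events)
        assert (table["contrast"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()

    def test_rectifying_channel_shows_larger_tau2_at_positive(self, rng):
        neg = self._events("PIEZO1-like", -60.0, 25, rng)
        pos = self._events("PIEZO1-like", 60.0, 25, rng)
        table = rectification_summary(neg, pos).set_index("parameter")
        assert (table.loc["tau2_ms", "mean +60 mV"]
                > table.loc["tau2_ms", "mean -60 mV"])

    def test_insufficient_events_rejected(self, rng):
        events = self._events("TRPV4-like", -60.0, 4, rng)
        with pytest.raises(ValueError):
            rectification_summary(events[:2], events)


class TestSummaries:
    def test_summary_table_counts_fittable_events(self, clean_trace_spec, rng):
        phen = synth.PHENOTYPES["chondrocyte-WT"]
        results = []
        for _ in range(10):
            spec = TraceSpec(baseline_noise_sd_pA=4.0, seed=0)
            trace, _ = generate_current_trace(spec, phen, 1000.0, rng=rng,
                                              responder=True, threshold_nm=0.0)
            results.append(CurrentKineticsModel(trace).fit())
        table = summarize_kinetics(results).set_index("parameter")
        assert table.loc["latency_ms", "n"] == sum(k.responded for k in results)
        assert np.isfinite(table.loc["peak_amplitude_pA", "mean"])

    def test_results_summary_prints_key_fields(self, clean_trace_spec):
        kin, _ = run_model(clean_trace_spec, fixed_phenotype())
        text = kin.summary()
        assert "latency" in text and "tau1" in text and "rapid gating" in text
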