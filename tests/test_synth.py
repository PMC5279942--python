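"""Synthetic-data generators: determinism, identity cases, convergence."""

import numpy as np
import pytest
from scipy import stats as sps

from pilarray import synth
from pilarray.response import summarize_cells
from pilarray.synth import (ChannelPhenotype, ImageSceneSpec, TraceSpec,
                            generate_current_trace, generate_fluorescence_trace,
                            generate_pillar_scene, generate_population,
                            generate_pressure_family)
from tests.conftest import fixed_phenotype


class TestSceneGenerator:
    def test_zero_deflection_noiseless_frames_identical(self):
        spec = ImageSceneSpec(true_deflection_nm=(0.0, 0.0), read_noise_sd=0.0, seed=0)
        scene = generate_pillar_scene(spec)
        np.testing.assert_array_equal(scene.frames["before"], scene.frames["during"])
        np.testing.assert_array_equal(scene.frames["before"], scene.frames["after"])

    def test_truth_reports_constructed_shift(self):
        spec = ImageSceneSpec(true_deflection_nm=(100.0, 0.0), seed=0)
        scene = generate_pillar_scene(spec)
        pid = scene.truth["designated_pilus"]
        before = np.array(scene.truth["centers_px"]["before"][pid])
        during = np.array(scene.truth["centers_px"]["during"][pid])
        np.testing.assert_allclose(during - before, [100.0 / 161.0, 0.0])
        assert scene.truth["true_deflection_magnitude_nm"] == 100.0

    def test_seeded_determinism_bit_identical(self):
        a = generate_pillar_scene(ImageSceneSpec(true_deflection_nm=(50.0, 20.0), seed=11))
        b = generate_pillar_scene(ImageSceneSpec(true_deflection_nm=(50.0, 20.0), seed=11))
        for role in synth.FRAME_ROLES:
            np.testing.assert_array_equal(a.frames[role], b.frames[role])

    def test_collision_deflection_rejected(self):
        with pytest.raises(ValueError, match="collision"):
            ImageSceneSpec(true_deflection_nm=(3000.0, 0.0))

    def test_unresolvable_spot_rejected(self):
        with pytest.raises(ValueError):
            ImageSceneSpec(spot_sigma_nm=50.0, pixel_size_nm=161.0)

    def test_tiff_roundtrip(self, tmp_path):
        scene = generate_pillar_scene(ImageSceneSpec(seed=3))
        path = tmp_path / "scene.tiff"
        synth.write_scene(scene, path)
        back = synth.read_scene(path)
        assert back.truth["designated_pilus"] == scene.truth["designated_pilus"]
        np.testing.assert_allclose(back.frames["during"], scene.frames["during"],
                                   rtol=1e-6)


class TestTraceGenerator:
    def test_nonresponder_yields_baseline_only(self, clean_trace_spec):
        phen = fixed_phenotype(responder_prob=0.0)
        trace, truth = generate_current_trace(clean_trace_spec, phen, 500.0)
        assert not truth["responded"]
        np.testing.assert_array_equal(trace.samples, 0.0)

    def test_below_threshold_deflection_gives_no_event(self, clean_trace_spec):
        phen = fixed_phenotype(threshold_mean_nm=400.0)
        _, truth = generate_current_trace(clean_trace_spec, phen, 100.0)
        assert not truth["responded"]

    def test_inward_current_negative_at_negative_holding(self, clean_trace_spec):
        phen = fixed_phenotype()
        trace, truth = generate_current_trace(clean_trace_spec, phen, 500.0)
        assert truth["responded"]
        assert trace.samples.min() < -100.0  # inward = negative deflection

    def test_seeded_determinism(self):
        spec = TraceSpec(baseline_noise_sd_pA=5.0, seed=42)
        phen = synth.PHENOTYPES["chondrocyte-WT"]
        t1, _ = generate_current_trace(spec, phen, 800.0)
        t2, _ = generate_current_trace(spec, phen, 800.0)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_nonrectifying_amplitudes_voltage_symmetric(self, rng):
        """A voltage-independent channel gives equal-magnitude amplitude
        distributions at −60 and +60 mV."""
        phen = synth.PHENOTYPES["TRPV4-like"]
        amps = {}
        for v in (-60.0, 60.0):
            draws = []
            for i in range(60):
                spec = TraceSpec(holding_potential_mV=v, seed=0)
                _, truth = generate_current_trace(spec, phen, 900.0, rng=rng,
                                                  responder=True, threshold_nm=0.0)
                draws.append(truth["amplitude_pA"])
            amps[v] = np.asarray(draws)
        assert np.sign(amps[-60.0]).all() == np.sign(amps[60.0]).all()
        assert sps.mannwhitneyu(amps[-60.0], amps[60.0]).pvalue > 0.05

    def test_rectifying_tau2_slows_at_positive_potential(self, rng):
        phen = synth.PHENOTYPES["PIEZO1-like"]
        taus = {}
        for v in (-60.0, 60.0):
            draws = []
            for i in range(40):
                spec = TraceSpec(holding_potential_mV=v, seed=0)
                _, truth = generate_current_trace(spec, phen, 900.0, rng=rng,
                                                  responder=True, threshold_nm=0.0)
                draws.append(truth["tau2_ms"])
            taus[v] = np.mean(draws)
        assert taus[60.0] > taus[-60.0]


class TestPressureGenerator:
    def test_midpoint_is_half_imax(self):
        fam, _ = generate_pressure_family(70.0, 12.0, 80.0,
                                          steps_mmHg=[10, 40, 70, 100, 130],
                                          noise_sd_pA=0.0)
        assert fam.peak_currents_pA[2] == pytest.approx(40.0)

    def test_saturation_approaches_imax(self):
        fam, _ = generate_pressure_family(50.0, 5.0, 60.0,
                                          steps_mmHg=[10, 50, 500, 1000],
                                          noise_sd_pA=0.0)
        assert fam.peak_currents_pA[-1] == pytest.approx(60.0, rel=1e-8)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            generate_pressure_family(87.1, 0.0, 45.2)

    def test_default_protocol_is_8_steps_to_150(self):
        fam, _ = generate_pressure_family(87.1, 10.0, 45.2, noise_sd_pA=0.0)
        np.testing.assert_allclose(fam.pressures_mmHg, np.arange(10, 151, 20))


class TestPopulationGenerator:
    def test_identical_seed_gives_identical_tables(self):
        phens = {"wt": synth.PHENOTYPES["chondrocyte-WT"]}
        m1, c1 = generate_population(phens, {"wt": 20}, seed=3)
        m2, c2 = generate_population(phens, {"wt": 20}, seed=3)
        assert m1.equals(m2) and c1.equals(c2)

    def test_zero_threshold_sd_collapses_to_mean(self):
        phen = fixed_phenotype(threshold_mean_nm=200.0, peak_amp_sd_pA=0.0)
        _, cells = generate_population({"g": phen}, {"g": 30}, seed=1)
        assert (cells["threshold_nm"] == 200.0).all()

    def test_responder_fraction_converges(self):
        """Observed responder fraction at n = 2700 lies within 3 s.e. of the
        24/27 generator probability."""
        phens = {"wt": synth.PHENOTYPES["chondrocyte-WT"]}
        meas, _ = generate_population(phens, {"wt": 2700}, seed=5)
        summaries = summarize_cells(meas)
        frac = np.mean([c.responder for c in summaries])
        p = 24 / 27
        se = np.sqrt(p * (1 - p) / 2700)
        assert abs(frac - p) < 3 * se

    def test_drawn_thresholds_converge_to_truncated_lognormal_mean(self):
        """LLN at n = 10000: the drawn per-cell thresholds match the
        analytic mean of the truncated log-normal the generator samples."""
        phen = synth.PHENOTYPES["chondrocyte-WT"]
        _, cells = generate_population({"wt": phen}, {"wt": 10_000}, seed=8)
        drawn = cells["threshold_nm"].dropna().to_numpy()
        mean, sd, upper = phen.threshold_mean_nm, phen.threshold_sd_nm, 1000.0
        sigma2 = np.log1p((sd / mean) ** 2)
        sigma, mu = np.sqrt(sigma2), np.log(mean) - sigma2 / 2
        # E[X | X <= upper] for lognormal(mu, sigma)
        z = (np.log(upper) - mu) / sigma
        trunc_mean = mean * sps.norm.cdf(z - sigma) / sps.norm.cdf(z)
        assert np.mean(drawn) == pytest.approx(trunc_mean, rel=0.03)
        assert drawn.max() <= upper

    def test_mismatched_groups_rejected(self):
        with pytest.raises(ValueError):
            generate_population({"a": fixed_phenotype()}, {"b": 5}, seed=0)


class TestFluorescenceGenerator:
    def test_zero_amplitudes_fluctuate_around_zero(self):
        from pilarray.calcium import Epoch, delta_f_over_f

        trace, _ = generate_fluorescence_trace(
            1000.0, [(Epoch("ATP", 60.0, 60.0), 0.0)], noise_sd=10.0, seed=2)
        dff = delta_f_over_f(trace)
        assert abs(np.mean(dff)) < 0.01
        assert np.std(dff) == pytest.approx(10.0 / 1000.0, rel=0.3)

    def test_noiseless_peak_dff_equals_amplitude_over_baseline(self):
        from pilarray.calcium import Epoch, delta_f_over_f

        trace, truth = generate_fluorescence_trace(
            500.0, [(Epoch("Yoda1", 100.0, 90.0), 500.0)], noise_sd=0.0)
        assert np.max(delta_f_over_f(trace)) == pytest.approx(1.0)
        assert truth["peak_dff"]["Yoda1"] == 1.0

    def test_default_schedule_durations(self):
        epochs = synth.default_calcium_epochs(100.0, 100.0, 100.0)
        durations = {ep.label: ep.duration_s for ep, _ in epochs}
        assert durations == {"ATP": 60.0, "Yoda1": 90.0, "GSK101": 15.0}

    def test_child_seed_stable_and_bounded(self):
        s1 = synth.child_seed(1, "tracking")
        assert s1 == synth.child_seed(1, "tracking")
        assert s1 != synth.child_seed(1, "kinetics")
        assert 0 <= s1 < 2**31
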