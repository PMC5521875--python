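import warnings

import numpy as np
import pytest
from scipy import stats

from pdmcircuit import filter_spectrum, make_ground_truth_filters, \
    make_theta_inputs, simulate_ca1
from pdmcircuit.errors import ParameterError
from pdmcircuit.synthetic import (EffectScenario, FilterShapeSpec,
                                  control_scenario, make_circuit, make_study,
                                  thc_scenario)


class TestGroundTruthFilters:
    def test_default_feedback_negative_through_refractory_lags(self):
        _, fb = make_ground_truth_filters()
        assert (fb.values[:10] < 0).all()  # lags 1..10 = 4..40 ms

    def test_feedback_resonance_tracks_requested_frequency(self):
        spec = FilterShapeSpec(fb_resonance_hz=3.5)
        _, fb = make_ground_truth_filters(spec=spec)
        assert abs(filter_spectrum(fb).peak_freq - 3.5) <= 0.5

    def test_feedforward_peak_in_high_theta(self):
        spec = FilterShapeSpec(ff_resonance_hz=8.5)
        ff, _ = make_ground_truth_filters(spec=spec)
        assert 8.0 <= filter_spectrum(ff).peak_freq <= 9.0

    def test_filters_live_in_basis_span(self, basis):
        ff, fb = make_ground_truth_filters()
        for filt in (ff, fb):
            proj = basis.B @ basis.project(filt.values)
            assert np.abs(proj - filt.values).max() < 1e-9

    def test_off_basis_component_leaves_span(self, basis):
        spec = FilterShapeSpec(off_basis_component=0.2)
        ff, _ = make_ground_truth_filters(spec=spec)
        proj = basis.B @ basis.project(ff.values)
        assert np.abs(proj - ff.values).max() > 1e-6

    def test_super_nyquist_resonance_rejected(self):
        with pytest.raises(ParameterError):
            make_ground_truth_filters(spec=FilterShapeSpec(fb_resonance_hz=130.0))


class TestThetaInputs:
    def test_zero_depth_rate_matches_target(self):
        tr = make_theta_inputs(1, 600.0, rate=8.0, theta_depth=0.0, seed=1)[0]
        se = np.sqrt(8.0 / 600.0)
        assert abs(tr.values.sum() / 600.0 - 8.0) < 3 * se

    def test_periodogram_peak_at_theta_frequency(self):
        tr = make_theta_inputs(1, 600.0, theta_freq=6.0, theta_depth=0.8,
                               seed=2)[0]
        x = tr.values - tr.values.mean()
        power = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 0.004)
        band = (freqs > 0.5) & (freqs < 50.0)
        peak = freqs[band][np.argmax(power[band])]
        assert abs(peak - 6.0) <= 0.5

    def test_same_seed_reproduces_trains(self):
        a = make_theta_inputs(3, 60.0, seed=3)
        b = make_theta_inputs(3, 60.0, seed=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.values, tb.values)

    def test_excess_probability_warns(self):
        with pytest.warns(UserWarning, match="exceeded 1"):
            make_theta_inputs(1, 10.0, rate=100.0, theta_depth=1.0, seed=4,
                              events=np.array([2.0, 5.0]), event_gain=3.0)

    def test_rate_too_high_rejected(self):
        with pytest.raises(ParameterError):
            make_theta_inputs(1, 10.0, rate=200.0)


class TestSimulateCa1:
    def test_degenerate_circuit_is_bernoulli_offset(self):
        c = make_circuit(n_ca3=2, n_ca1=1, connect_prob=0.0, seed=5)
        c.offsets[:] = 0.02
        c.fb_trough[0][:] = 0.0
        c.fb_osc[0][:] = 0.0
        inputs = make_theta_inputs(2, 600.0, seed=6)
        out = simulate_ca1(inputs, c, seed=7)[0]
        rate = out.values.sum() / 600.0
        se = np.sqrt(5.0 / 600.0)
        assert abs(rate - 5.0) < 3 * se

    def test_lag_zero_filter_peaks_crosscorrelation_at_zero(self, basis):
        c = make_circuit(n_ca3=1, n_ca1=1, connect_prob=1.0, seed=8)
        delta = np.zeros(basis.M + 1)
        delta[0] = 1.0
        c.ff_coeffs[(0, 0)] = basis.project(delta) * 0.4
        inputs = make_theta_inputs(1, 300.0, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = simulate_ca1(inputs, c, seed=10)[0]
        x = inputs[0].values - inputs[0].values.mean()
        y = out.values - out.values.mean()
        lags = range(-10, 11)
        cc = [np.dot(x[max(0, -k):len(x) - max(0, k)],
                     y[max(0, k):len(y) - max(0, -k)]) for k in lags]
        assert list(lags)[int(np.argmax(cc))] == 0

    def test_deep_trough_enforces_refractory_period(self, basis):
        c = make_circuit(n_ca3=1, n_ca1=1, connect_prob=0.0, seed=11)
        tau = np.arange(basis.M + 1) + 1.0
        c.fb_trough[0] = basis.project(-5.0 * np.exp(-tau / 8.0))
        c.fb_osc[0][:] = 0.0
        c.offsets[:] = 0.3
        inputs = make_theta_inputs(1, 60.0, seed=12)
        out = simulate_ca1(inputs, c, seed=13)[0]
        isi = np.diff(np.flatnonzero(out.values))
        assert out.values.sum() > 50
        assert isi.min() > 10

    def test_rate_monotone_in_offset(self):
        rates = []
        for offset in (0.005, 0.015, 0.03):
            c = make_circuit(n_ca3=1, n_ca1=1, connect_prob=0.0, seed=14)
            c.offsets[:] = offset
            inputs = make_theta_inputs(1, 300.0, seed=15)
            out = simulate_ca1(inputs, c, seed=16)[0]
            rates.append(out.values.sum())
        assert rates[0] < rates[1] < rates[2]

    def test_mismatched_extents_rejected(self):
        c = make_circuit(n_ca3=2, n_ca1=1, seed=17)
        a = make_theta_inputs(1, 60.0, seed=18)
        b = make_theta_inputs(1, 50.0, seed=19)
        with pytest.raises(ParameterError):
            simulate_ca1(a + b, c, seed=20)


class TestMakeStudy:
    def test_study_is_pure_function_of_seed(self):
        s1 = make_study(n_animals=1, sessions_per_condition=1, duration=20.0,
                        seed=21)
        s2 = make_study(n_animals=1, sessions_per_condition=1, duration=20.0,
                        seed=21)
        assert s1.spikes.equals(s2.spikes)
        assert s1.meta.equals(s2.meta)
        assert s1.ground_truth == s2.ground_truth

    def test_noiseless_behavior_is_exact_line_in_magnitude(self):
        drug = EffectScenario(condition="THC", behavior_slope=15.0,
                              behavior_noise_sd=0.0)
        ctrl = EffectScenario(condition="control", behavior_noise_sd=0.0)
        study = make_study(n_animals=1, sessions_per_condition=4,
                           duration=10.0, scenarios=(ctrl, drug), seed=22)
        sess = study.ground_truth["sessions"]
        thc = [s for s in sess.values() if s["condition"] == "THC"]
        g = np.array([s["magnitude"] for s in thc])
        perf = np.array([s["performance"] for s in thc])
        res = stats.linregress(g, perf)
        assert res.rvalue ** 2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-15.0, abs=1e-9)

    def test_zero_slope_scenario_decouples_behavior(self):
        drug = EffectScenario(condition="THC", behavior_slope=0.0,
                              behavior_noise_sd=3.0)
        study = make_study(n_animals=3, sessions_per_condition=4,
                           duration=10.0,
                           scenarios=(control_scenario(), drug), seed=23)
        sess = study.ground_truth["sessions"]
        thc = [s for s in sess.values() if s["condition"] == "THC"]
        g = np.array([s["magnitude"] for s in thc])
        perf = np.array([s["performance"] for s in thc])
        assert stats.linregress(g, perf).pvalue > 0.05

    def test_dropped_connections_are_bookkept(self):
        study = make_study(n_animals=2, sessions_per_condition=2,
                           duration=10.0, seed=24)
        gt = study.ground_truth
        for sid, rec in gt["sessions"].items():
            animal_edges = {
                (f"{rec['animal_id']}_ca3_{i}", f"{rec['animal_id']}_ca1_{j}")
                for (i, j) in gt["animals"][rec["animal_id"]]["edges"]}
            dropped = {
                (f"{rec['animal_id']}_ca3_{i}", f"{rec['animal_id']}_ca1_{j}")
                for (i, j) in rec["dropped_edges"]}
            kept = set(map(tuple, rec["true_edges"]))
            if rec["condition"] == "control":
                assert dropped == set()
            assert kept | dropped == animal_edges
            assert kept & dropped == set()

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ParameterError):
            EffectScenario(connection_drop=1.5)
        with pytest.raises(ParameterError):
            EffectScenario(ff_gain=-0.1)

    def test_thc_scenario_directions_on_ground_truth(self):
        from pdmcircuit import band_power, excitatory_index
        from pdmcircuit.synthetic import apply_scenario
        rng = np.random.default_rng(25)
        c = make_circuit(seed=26)
        base_fb = c.feedback_filter(0)
        mod, _ = apply_scenario(c, thc_scenario(), 0.8, rng)
        mod_fb = mod.feedback_filter(0)
        assert band_power(filter_spectrum(mod_fb), 4, 9) \
            < band_power(filter_spectrum(base_fb), 4, 9)
        assert excitatory_index(mod_fb) > excitatory_index(base_fb)
        for key in mod.ff_coeffs:
            assert np.abs(mod.ff_coeffs[key]).max() \
                < np.abs(c.ff_coeffs[key]).max()
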