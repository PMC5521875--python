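import numpy as np
import pandas as pd
import pytest

from pdmcircuit import (behavior_correlation, group_difference,
                        range_relative_impairment, relative_reduction,
                        summarize_study)
from pdmcircuit.errors import InsufficientDataError, UndefinedMetricError
from pdmcircuit.population_stats import CONTRAST_METRICS


class TestRelativeReduction:
    def test_basic_arithmetic(self):
        assert relative_reduction(8.0, 10.0) == pytest.approx(0.20)
        assert relative_reduction(10.0, 10.0) == 0.0

    def test_increase_is_negative_reduction(self):
        assert relative_reduction(12.0, 10.0) == pytest.approx(-0.20)

    def test_invariant_to_common_rescaling(self):
        r = relative_reduction(8.0, 10.0)
        assert relative_reduction(8.0e3, 10.0e3) == pytest.approx(r)

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedMetricError):
            relative_reduction(1.0, 0.0)

    def test_chance_relative_impairment_worked_example(self):
        # a 12.2-point drop from 74.4% correct is 24.4% of the 50-point
        # range above the 50% chance level
        assert range_relative_impairment(74.4, 62.2) == pytest.approx(24.4)


def _features(deltas, noise_sd=0.0, seed=0, n_animals=3, metric="fb_ei"):
    """Synthetic feature table: per-animal control baseline plus THC sessions
    displaced by `deltas` with behavior following the same latent values."""
    rng = np.random.default_rng(seed)
    rows = []
    deltas = np.asarray(deltas, float)
    per_animal = np.array_split(np.arange(deltas.size), n_animals)
    for a, idx in enumerate(per_animal):
        rows.append({"session_id": f"a{a}c", "animal_id": f"a{a}",
                     "condition": "control", metric: 1.0, "performance": 80.0})
        for k in idx:
            rows.append({
                "session_id": f"a{a}t{k}", "animal_id": f"a{a}",
                "condition": "THC",
                metric: 1.0 - deltas[k] + rng.normal(0, noise_sd),
                "performance": 80.0 * (1.0 - deltas[k]),
            })
    return pd.DataFrame(rows)


class TestBehaviorCorrelation:
    def test_noiseless_line_gives_unit_r_squared(self):
        feats = _features(np.linspace(0.05, 0.4, 9))
        ec = behavior_correlation(feats, "fb_ei")
        assert ec.r_squared == pytest.approx(1.0, abs=1e-12)
        assert ec.slope == pytest.approx(1.0, abs=1e-9)

    def test_r_squared_matches_squared_pearson_of_pairs(self):
        feats = _features(np.linspace(0.05, 0.4, 9), noise_sd=0.05, seed=1)
        ec = behavior_correlation(feats, "fb_ei")
        r = np.corrcoef(ec.pairs["delta_metric"],
                        ec.pairs["delta_behavior"])[0, 1]
        assert ec.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_invariant_to_affine_metric_transform(self):
        feats = _features(np.linspace(0.05, 0.4, 9), noise_sd=0.05, seed=2)
        r2 = behavior_correlation(feats, "fb_ei").r_squared
        feats2 = feats.copy()
        feats2["fb_ei"] = 5.0 * feats2["fb_ei"]
        assert behavior_correlation(feats2, "fb_ei").r_squared \
            == pytest.approx(r2, abs=1e-9)

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(3)
        sig = 0
        n_rep = 200
        for rep in range(n_rep):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            rows = [{"session_id": "c", "animal_id": "a0",
                     "condition": "control", "m": 1.0, "performance": 80.0}]
            rows += [{"session_id": f"t{k}", "animal_id": "a0",
                      "condition": "THC", "m": 1.0 + x[k],
                      "performance": 80.0 + y[k]} for k in range(12)]
            ec = behavior_correlation(pd.DataFrame(rows), "m")
            sig += ec.p_value < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(sig / n_rep - 0.05) < band + 1e-9

    def test_too_few_sessions_rejected(self):
        feats = _features(np.array([0.1, 0.2]))
        with pytest.raises(InsufficientDataError):
            behavior_correlation(feats, "fb_ei")


class TestGroupDifference:
    def test_identical_groups_null(self):
        x = np.arange(10.0)
        gd = group_difference(x, x, seed=0)
        assert gd.delta == 0.0
        assert gd.ci[0] <= 0.0 <= gd.ci[1]
        assert gd.p_value > 0.5

    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(12)
        gd = group_difference(x + 0.7, x, seed=1)
        assert gd.delta == pytest.approx(0.7, abs=1e-12)
        gd_paired = group_difference(x + 0.7, x, paired=True, seed=2)
        assert gd_paired.delta == pytest.approx(0.7, abs=1e-12)
        assert gd_paired.p_value <= 2.0 / 10000 * 10  # sign-flip null is tight

    def test_bootstrap_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(5)
        true_delta = 0.5
        cover = 0
        n_rep = 200
        for rep in range(n_rep):
            a = rng.standard_normal(50) + true_delta
            b = rng.standard_normal(50)
            gd = group_difference(a, b, n_boot=400, n_perm=10,
                                  coverage=0.95, seed=rep)
            cover += gd.ci[0] <= true_delta <= gd.ci[1]
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(cover / n_rep - 0.95) < 3 * se + 1e-9

    def test_paired_mismatched_lengths_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_difference(np.ones(3), np.ones(4), paired=True)


class TestSummarizeStudy:
    def _study_features(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(3):
            for cond in ("control", "THC"):
                for s in range(2):
                    row = {"session_id": f"a{a}{cond}{s}",
                           "animal_id": f"a{a}", "condition": cond,
                           "performance": rng.uniform(60, 80)}
                    for m in CONTRAST_METRICS:
                        row[m] = rng.uniform(0.5, 1.5)
                    for m in ("gpdm_ff_m1", "gpdm_ff_m3", "gpdm_fb_m1",
                              "gpdm_fb_m2"):
                        row[m] = rng.uniform(0.5, 1.5)
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_one_contrast_row_per_metric(self):
        report = summarize_study(self._study_features(), seed=1)
        assert len(report.contrasts) == 12
        assert set(report.contrasts["metric"]) == set(CONTRAST_METRICS)
        assert report.n_tests == len(report.contrasts) + len(report.correlations)

    def test_missing_metric_listed_as_gap(self):
        feats = self._study_features().drop(columns=["fb_theta"])
        report = summarize_study(feats, seed=2)
        assert len(report.contrasts) == 11
        assert any("fb_theta" in g for g in report.gaps)

    def test_correlations_cover_excitation_and_modes(self):
        report = summarize_study(self._study_features(), seed=3)
        assert set(report.correlations["metric"]) == {
            "ff_ei", "fb_ei", "gpdm_ff_m1", "gpdm_ff_m2", "gpdm_ff_m3",
            "gpdm_fb_m1", "gpdm_fb_m2", "gpdm_fb_m3"}
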