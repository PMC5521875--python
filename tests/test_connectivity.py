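import warnings

import numpy as np
import pytest

from pdmcircuit import (default_config, predict, roc_auc, stepwise_select,
                        surrogate_significance)
from pdmcircuit.connectivity import build_graph
from pdmcircuit.errors import (InsufficientDataError, ParameterError,
                               UndefinedMetricError)
from pdmcircuit.io import Session
from pdmcircuit.mvar import Prediction
from pdmcircuit.synthetic import (FilterShapeSpec, _ff_coeffs, make_circuit,
                                  make_theta_inputs, simulate_ca1)


def _two_input_circuit(seed=21):
    """6 candidate inputs, exactly two truly connected to the CA1 unit."""
    circuit = make_circuit(n_ca3=6, n_ca1=1, connect_prob=0.0, seed=seed)
    base = _ff_coeffs(FilterShapeSpec(), circuit.basis, 0.004)
    circuit.connectivity[1, 0] = 1
    circuit.connectivity[4, 0] = 1
    circuit.ff_coeffs = {(1, 0): base, (4, 0): base * 0.9}
    return circuit


@pytest.fixture(scope="module")
def selected_model():
    circuit = _two_input_circuit()
    inputs = make_theta_inputs(6, 600.0, seed=22)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        output = simulate_ca1(inputs, circuit, seed=23)[0]
    model = stepwise_select(output, inputs, circuit.basis)
    return circuit, inputs, output, model


class TestStepwiseSelect:
    def test_recovers_true_input_set(self, selected_model):
        _, _, _, model = selected_model
        assert set(model.input_units) == {"ca31", "ca34"}

    def test_recovery_across_replicates(self):
        circuit = _two_input_circuit()
        hits = 0
        for rep in range(5):
            inputs = make_theta_inputs(6, 600.0, seed=500 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                output = simulate_ca1(inputs, circuit, seed=600 + rep)[0]
            model = stepwise_select(output, inputs, circuit.basis)
            hits += set(model.input_units) == {"ca31", "ca34"}
        assert hits >= 4

    def test_infinite_threshold_returns_feedback_only(self, selected_model):
        circuit, inputs, output, _ = selected_model
        cfg = default_config()
        cfg.select.epsilon = np.inf
        model = stepwise_select(output, inputs, circuit.basis, cfg)
        assert model.n_inputs == 0

    def test_invariant_to_candidate_ordering(self, selected_model):
        circuit, inputs, output, model = selected_model
        reordered = list(reversed(inputs))
        model2 = stepwise_select(output, reordered, circuit.basis)
        assert model2.input_units == model.input_units
        assert np.allclose(model2.ff_coeffs, model.ff_coeffs)

    def test_empty_candidates_rejected(self, selected_model):
        circuit, _, output, _ = selected_model
        with pytest.raises(ParameterError):
            stepwise_select(output, [], circuit.basis)


class TestSurrogateSignificance:
    def test_connected_model_significant_with_40_surrogates(self, selected_model):
        circuit, inputs, output, model = selected_model
        sel = [t for t in inputs if t.unit_id in model.input_units]
        sig = surrogate_significance(model, (output, sel), seed=1)
        assert sig.surrogate_z.size == 40
        assert sig.threshold == 1e-4
        assert sig.p_value < 1e-4 and sig.significant

    def test_fisher_z_consistent_with_rho(self, selected_model):
        circuit, inputs, output, model = selected_model
        sel = [t for t in inputs if t.unit_id in model.input_units]
        sig = surrogate_significance(model, (output, sel), seed=2)
        assert sig.z_true == pytest.approx(np.arctanh(sig.rho_true), abs=1e-9)

    def test_zero_input_model_rejected(self, selected_model):
        circuit, inputs, output, _ = selected_model
        cfg = default_config()
        cfg.select.epsilon = np.inf
        fb_only = stepwise_select(output, inputs, circuit.basis, cfg)
        with pytest.raises(ParameterError):
            surrogate_significance(fb_only, (output, []))

    def test_too_few_surrogates_rejected(self, selected_model):
        _, inputs, output, model = selected_model
        sel = [t for t in inputs if t.unit_id in model.input_units]
        with pytest.raises(ParameterError):
            surrogate_significance(model, (output, sel), n_surrogates=10)


class TestRocAuc:
    def _pred(self, values, n=None):
        values = np.asarray(values, dtype=float)
        return Prediction(values=values, valid_mask=np.ones(values.size, bool))

    def test_constant_prediction_gives_half(self):
        rng = np.random.default_rng(7)
        y = (rng.random(500) < 0.3).astype(np.int8)
        roc = roc_auc(self._pred(np.ones(500)), y)
        assert roc.auc == pytest.approx(0.5, abs=1e-12)

    def test_perfect_prediction_gives_one(self):
        rng = np.random.default_rng(8)
        y = (rng.random(500) < 0.3).astype(np.int8)
        roc = roc_auc(self._pred(y.astype(float)), y)
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_mann_whitney(self):
        rng = np.random.default_rng(9)
        y = (rng.random(500) < 0.3).astype(np.int8)
        p = rng.standard_normal(500) + 0.8 * y
        roc = roc_auc(self._pred(p), y)
        pos, neg = p[y == 1], p[y == 0]
        greater = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        mw = (greater + 0.5 * ties) / (pos.size * neg.size)
        assert roc.auc == pytest.approx(mw, abs=1e-9)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-9)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: 3.0 * v - 1.0])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(10)
        y = (rng.random(400) < 0.25).astype(np.int8)
        p = rng.standard_normal(400) + y
        base = roc_auc(self._pred(p), y)
        mapped = roc_auc(self._pred(transform(p)), y)
        assert mapped.auc == pytest.approx(base.auc, abs=1e-12)
        assert np.allclose(mapped.tpr, base.tpr)
        assert np.allclose(mapped.fpr, base.fpr)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(self._pred(np.random.default_rng(0).random(200)),
                    np.zeros(200, dtype=np.int8))

    def test_too_few_bins_rejected(self):
        y = np.array([0, 1] * 20, dtype=np.int8)
        with pytest.raises(InsufficientDataError):
            roc_auc(self._pred(np.arange(40.0)), y)

    def test_curve_monotone(self, selected_model):
        circuit, inputs, output, model = selected_model
        sel = [t for t in inputs if t.unit_id in model.input_units]
        pred = predict(model, sel, output)
        roc = roc_auc(pred, output)
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
        assert 0.5 < roc.auc <= 1.0


class TestBuildGraph:
    def test_empty_ca1_yields_empty_graph(self):
        sess = Session(session_id="s", animal_id="a", condition="control",
                       performance=75.0, ca3=[], ca1=[])
        graphs = build_graph({"s": sess})
        assert graphs["s"].n_models == 0
        assert graphs["s"].n_edges == 0

    def test_shuffled_inputs_yield_no_significant_models(self):
        circuit = make_circuit(n_ca3=3, n_ca1=2, connect_prob=0.8, seed=31)
        inputs = make_theta_inputs(3, 300.0, seed=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            outputs = simulate_ca1(inputs, circuit, seed=33)
        rng = np.random.default_rng(34)
        for tr in inputs:
            tr.values = rng.permutation(tr.values)
        sess = Session(session_id="s", animal_id="a", condition="control",
                       performance=75.0, ca3=inputs, ca1=outputs)
        graphs = build_graph({"s": sess}, seed=35)
        assert graphs["s"].n_significant == 0

    def test_edges_only_from_significant_models(self, selected_model):
        circuit, inputs, output, _ = selected_model
        sess = Session(session_id="s", animal_id="a", condition="control",
                       performance=75.0, ca3=inputs, ca1=[output])
        graphs = build_graph({"s": sess}, seed=36)
        g = graphs["s"]
        assert g.n_models == 1
        for (src, dst, filt) in g.edges:
            assert dst in g.fb_filters
            assert filt.kind == "feedforward"
        assert {(s, d) for s, d, _ in g.edges} == {("ca31", "ca10"),
                                                   ("ca34", "ca10")}
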