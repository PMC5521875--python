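"""A small control-versus-drug study, analysed end to end.

Generates 2 animals x (1 control + 1 drug) sessions of 200 s with the
default drug scenario (weakened/sparser feedforward coupling, reduced
feedback theta, feedback excitation shift, dose-linked behavior), runs the
full pipeline and prints the per-session features and condition contrasts.
With so few sessions the permutation p-values are necessarily coarse; the
*signs* of the programmed effects are the thing to look at.  The default
study used by scripts/acceptance.py is 6 animals x (2 + 2) x 600 s.
"""

import warnings

from pdmcircuit.pipeline import analyze_study, score_edge_recovery
from pdmcircuit.synthetic import make_study

study = make_study(n_animals=2, sessions_per_condition=1, duration=200.0,
                   seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = analyze_study(study.spikes, study.meta, study.events, seed=1,
                           duration=200.0, ground_truth=study.ground_truth)

cols = ["session_id", "condition", "mfr_mean", "fb_theta", "fb_ei",
        "n_significant", "n_edges", "performance"]
print(result.features[cols].round(3).to_string(index=False))

print("\nedge recovery vs ground truth:",
      score_edge_recovery(result.graphs, study.ground_truth))

print("\ncondition contrasts (drug minus control):")
cols = ["metric", "control_mean", "drug_mean", "delta_drug_minus_control",
        "p_perm"]
print(result.report.contrasts[cols].round(4).to_string(index=False))
print("\nExpected directions under the drug scenario: fb_theta down, "
      "fb_ei up, n_edges down.")
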