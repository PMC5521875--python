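"""End-to-end study analysis: tables -> connectivity -> modes -> report.

Glue over the stage modules.  Given the three study tables this runs, per
session: binning, stepwise model selection with surrogate significance, and
filter harvesting; then pools all harvested filters (both conditions) into
one feedforward and one feedback gPDM set, assembles the per-session feature
table and hands it to the population-statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, default_config
from .connectivity import ConnectivityGraph, build_graph
from .filter_metrics import band_power, excitatory_index, filter_spectrum
from .gpdm import GpdmSet, compute_gpdms, stack_filters
from .io import Session, sessions_from_tables
from .population_stats import StudyReport, summarize_study
from .signal_metrics import mean_firing_rate, signal_band_power, spiketrain_spectrum


@dataclass
class StudyResult:
    sessions: dict[str, Session]
    graphs: dict[str, ConnectivityGraph]
    gpdm_ff: GpdmSet | None
    gpdm_fb: GpdmSet | None
    features: pd.DataFrame
    report: StudyReport


def pooled_gpdms(graphs: dict[str, ConnectivityGraph],
                 config: AnalysisConfig) -> tuple[GpdmSet | None, GpdmSet | None]:
    """One mode set per family from all sessions' harvested filters, pooled
    across conditions (never estimated per condition)."""
    ff = [f for g in graphs.values() for (_, _, f) in g.edges]
    fb = [f for g in graphs.values() for f in g.fb_filters.values()]
    n = config.gpdm.n_modes
    gp_ff = (compute_gpdms(stack_filters(ff), n, "feedforward",
                           config.gpdm.center)
             if len(ff) >= n else None)
    gp_fb = (compute_gpdms(stack_filters(fb), n, "feedback",
                           config.gpdm.center)
             if len(fb) >= n else None)
    return gp_ff, gp_fb


def compute_session_features(
    sessions: dict[str, Session],
    graphs: dict[str, ConnectivityGraph],
    gpdm_ff: GpdmSet | None,
    gpdm_fb: GpdmSet | None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-session averaged metrics: CA1 rate and theta, filter theta and EI
    by family, per-mode gPDM strengths, model/edge counts, AUC, behavior."""
    config = config or default_config()
    f_lo, f_hi = config.bands.filter_theta
    s_lo, s_hi = config.bands.signal_theta
    rows = []
    for sid, sess in sessions.items():
        g = graphs.get(sid)
        row = {"session_id": sid, "animal_id": sess.animal_id,
               "condition": sess.condition, "performance": sess.performance}
        ca1 = [tr for tr in sess.ca1 if tr.values.sum() > 0]
        row["mfr_mean"] = (float(np.mean([mean_firing_rate(t) for t in ca1]))
                           if ca1 else np.nan)
        theta = [signal_band_power(spiketrain_spectrum(t, config), s_lo, s_hi)
                 for t in ca1]
        row["signal_theta"] = float(np.mean(theta)) if theta else np.nan

        ff_filters = [f for (_, _, f) in g.edges] if g else []
        fb_filters = list(g.fb_filters.values()) if g else []
        for name, filters in (("ff", ff_filters), ("fb", fb_filters)):
            if filters:
                row[f"{name}_theta"] = float(np.mean(
                    [band_power(filter_spectrum(f), f_lo, f_hi)
                     for f in filters]))
                row[f"{name}_ei"] = float(np.mean(
                    [excitatory_index(f) for f in filters]))
            else:
                row[f"{name}_theta"] = np.nan
                row[f"{name}_ei"] = np.nan
        for name, filters, modes in (("ff", ff_filters, gpdm_ff),
                                     ("fb", fb_filters, gpdm_fb)):
            for m in range(modes.n_modes if modes else 3):
                key = f"gpdm_{name}_m{m + 1}"
                if filters and modes is not None:
                    row[key] = float(np.mean(
                        stack_filters(filters) @ modes.modes[:, m]))
                else:
                    row[key] = np.nan
        row["n_models"] = g.n_models if g else 0
        row["n_significant"] = g.n_significant if g else 0
        row["n_edges"] = g.n_edges if g else 0
        row["mean_auc"] = g.mean_auc if g else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def score_edge_recovery(graphs: dict[str, ConnectivityGraph],
                        ground_truth: dict) -> dict:
    """Edge sensitivity and false-discovery proportion against ground truth."""
    n_true = n_detected = n_hit = n_false = 0
    for sid, g in graphs.items():
        truth = set(map(tuple, ground_truth["sessions"][sid]["true_edges"]))
        found = {(src, dst) for (src, dst, _) in g.edges}
        n_true += len(truth)
        n_detected += len(found)
        n_hit += len(truth & found)
        n_false += len(found - truth)
    return {
        "n_true_edges": n_true,
        "n_detected_edges": n_detected,
        "sensitivity": n_hit / n_true if n_true else float("nan"),
        "false_discovery_proportion": n_false / n_detected if n_detected else 0.0,
    }


def analyze_study(
    spikes: pd.DataFrame,
    meta: pd.DataFrame,
    events: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    duration: float | None = None,
    ground_truth: dict | None = None,
) -> StudyResult:
    """Run the whole pipeline on a study's tables and summarise it."""
    config = config or default_config()
    sessions = sessions_from_tables(spikes, meta, events,
                                    bin_width=config.bin_width,
                                    duration=duration)
    graphs = build_graph(sessions, config, seed)
    gp_ff, gp_fb = pooled_gpdms(graphs, config)
    features = compute_session_features(sessions, graphs, gp_ff, gp_fb, config)
    recovery = (score_edge_recovery(graphs, ground_truth)
                if ground_truth else None)
    report = summarize_study(features, seed=seed, recovery=recovery)
    return StudyResult(sessions=sessions, graphs=graphs, gpdm_ff=gp_ff,
                       gpdm_fb=gp_fb, features=features, report=report)
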