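"""Condition contrasts, relative reductions and behavior correlations.

Sessions are the unit of analysis: each session contributes one value per
metric, drug-session reductions are taken relative to the *same animal's*
control-session mean, and scatter relationships with behavior treat sessions
as independent points (as the source scatter plots do).  Group p-values come
from label-permutation tests with parametric t-tests emitted alongside;
confidence intervals are percentile bootstrap.  No multiple-comparison
correction is applied across the contrast family — the number of tests is
reported so users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedMetricError

#: metrics contrasted between conditions, one row each in the study report
CONTRAST_METRICS = [
    "mfr_mean", "signal_theta", "ff_theta", "fb_theta", "ff_ei", "fb_ei",
    "n_models", "n_significant", "n_edges", "mean_auc",
    "gpdm_ff_m2", "gpdm_fb_m3",
]

#: metrics correlated with behavioral deficits across drug sessions
CORRELATION_METRICS = [
    "ff_ei", "fb_ei",
    "gpdm_ff_m1", "gpdm_ff_m2", "gpdm_ff_m3",
    "gpdm_fb_m1", "gpdm_fb_m2", "gpdm_fb_m3",
]


def relative_reduction(value: float, control_baseline: float) -> float:
    """(baseline - value) / baseline; positive means a reduction.

    The baseline is the mean of the metric over the same animal's control
    sessions.  Increases come out negative.
    """
    if control_baseline == 0:
        raise UndefinedMetricError("relative reduction undefined at zero baseline")
    return float((control_baseline - value) / control_baseline)


def range_relative_impairment(control_mean: float, value: float,
                              chance: float = 50.0) -> float:
    """Behavioral impairment as a percent of the range above chance.

    A drop from 74.4% to 62.2% correct is 12.2 points, i.e. 24.4% of the
    50-point range above the 50% chance level.
    """
    return float((control_mean - value) / (100.0 - chance) * 100.0)


@dataclass
class EffectCorrelation:
    """Across drug sessions: metric reduction versus behavioral reduction."""

    metric: str
    pairs: pd.DataFrame           # animal_id, session_id, delta_metric, delta_behavior
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def behavior_correlation(
    features: pd.DataFrame,
    metric: str,
    behavior_metric: str = "performance",
    drug_condition: str = "THC",
) -> EffectCorrelation:
    """OLS of behavioral reduction on metric reduction over drug sessions.

    Reductions are relative to the session's animal's control mean; every
    drug session is one point, pooled over animals.  p is the standard
    regression F-test.
    """
    needed = {metric, behavior_metric, "condition", "animal_id", "session_id"}
    missing = needed - set(features.columns)
    if missing:
        raise InsufficientDataError(f"features table lacks columns {sorted(missing)}")
    ctrl = features[features["condition"] == "control"]
    drug = features[features["condition"] == drug_condition]
    base_m = ctrl.groupby("animal_id")[metric].mean()
    base_b = ctrl.groupby("animal_id")[behavior_metric].mean()
    rows = []
    for _, r in drug.iterrows():
        a = r["animal_id"]
        if a not in base_m.index or not np.isfinite(r[metric]):
            continue
        bm, bb = base_m[a], base_b[a]
        if bm == 0 or bb == 0:
            continue
        rows.append({
            "animal_id": a, "session_id": r["session_id"],
            "delta_metric": relative_reduction(r[metric], bm),
            "delta_behavior": relative_reduction(r[behavior_metric], bb),
        })
    pairs = pd.DataFrame(rows)
    if len(pairs) < 4:
        raise InsufficientDataError(
            f"need >= 4 drug sessions with defined deltas for {metric!r}")
    x = pairs["delta_metric"].to_numpy()
    y = pairs["delta_behavior"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("zero variance in a delta; correlation undefined")
    res = stats.linregress(x, y)
    return EffectCorrelation(metric=metric, pairs=pairs, slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             p_value=float(res.pvalue))


@dataclass
class GroupDifference:
    delta: float
    ci: tuple[float, float]
    p_value: float          # label-permutation p (two-sided)
    p_t: float              # parametric t-test p, for comparison
    coverage: float
    n_a: int
    n_b: int
    paired: bool


def group_difference(
    values_a,
    values_b,
    paired: bool = False,
    n_boot: int = 2000,
    coverage: float = 0.95,
    seed: int | None = None,
    n_perm: int = 10000,
) -> GroupDifference:
    """mean(A) - mean(B) with a percentile-bootstrap CI and permutation p.

    In paired mode the statistic is the mean of within-pair differences and
    permutation randomly flips pair signs; otherwise condition labels are
    reshuffled.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if not paired:
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if paired and a.size != b.size:
        raise InsufficientDataError("paired mode requires matched lengths")
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - coverage) / 2.0
    if paired:
        d = a - b
        delta = float(d.mean())
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        boot = d[idx].mean(axis=1)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
        null = (signs * d).mean(axis=1)
        p_t = float(stats.ttest_rel(a, b).pvalue) if d.size > 1 else 1.0
    else:
        delta = float(a.mean() - b.mean())
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        pooled = np.concatenate([a, b])
        n = pooled.size
        keys = rng.random((n_perm, n)).argsort(axis=1)
        perm = pooled[keys]
        null = perm[:, :a.size].mean(axis=1) - perm[:, a.size:].mean(axis=1)
        p_t = float(stats.ttest_ind(a, b).pvalue) if a.size > 1 and b.size > 1 else 1.0
    ci = (float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha)))
    p = float((np.sum(np.abs(null) >= abs(delta)) + 1) / (n_perm + 1))
    return GroupDifference(delta=delta, ci=ci, p_value=p, p_t=p_t,
                           coverage=coverage, n_a=int(a.size), n_b=int(b.size),
                           paired=paired)


@dataclass
class StudyReport:
    """Full per-session feature table, condition contrasts, behavior
    correlations and (when ground truth exists) recovery scores."""

    features: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    recovery: dict | None = None
    gaps: list = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.contrasts) + len(self.correlations)


def summarize_study(
    features: pd.DataFrame,
    seed: int | None = None,
    recovery: dict | None = None,
    drug_condition: str = "THC",
    n_perm: int = 2000,
    n_boot: int = 1000,
) -> StudyReport:
    """Contrast every study metric between conditions and correlate each
    excitation/mode metric with behavioral deficits.

    Metrics absent from the feature table (or entirely undefined) are listed
    under ``gaps`` rather than silently dropped.
    """
    rng = np.random.default_rng(seed)
    ctrl = features[features["condition"] == "control"]
    drug = features[features["condition"] == drug_condition]
    gaps: list[str] = []
    rows = []
    for metric in CONTRAST_METRICS:
        if metric not in features.columns:
            gaps.append(f"contrast:{metric}:missing-column")
            continue
        a = ctrl[metric].to_numpy(dtype=float)
        b = drug[metric].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            gaps.append(f"contrast:{metric}:empty-group")
            continue
        gd = group_difference(a, b, n_boot=n_boot, n_perm=n_perm,
                              seed=int(rng.integers(2 ** 31)))
        rows.append({
            "metric": metric, "control_mean": float(a.mean()),
            "drug_mean": float(b.mean()),
            "delta_drug_minus_control": -gd.delta,
            "ci_lo": -gd.ci[1], "ci_hi": -gd.ci[0],
            "p_perm": gd.p_value, "p_t": gd.p_t,
            "n_control": gd.n_a, "n_drug": gd.n_b,
        })
    contrasts = pd.DataFrame(rows)

    corr_rows = []
    for metric in CORRELATION_METRICS:
        if metric not in features.columns:
            gaps.append(f"correlation:{metric}:missing-column")
            continue
        try:
            ec = behavior_correlation(features, metric,
                                      drug_condition=drug_condition)
        except (InsufficientDataError, UndefinedMetricError) as exc:
            gaps.append(f"correlation:{metric}:{exc}")
            continue
        corr_rows.append({"metric": metric, "slope": ec.slope,
                          "intercept": ec.intercept,
                          "r_squared": ec.r_squared, "p_value": ec.p_value,
                          "n_sessions": len(ec.pairs)})
    correlations = pd.DataFrame(corr_rows)
    return StudyReport(features=features, contrasts=contrasts,
                       correlations=correlations, recovery=recovery, gaps=gaps)
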