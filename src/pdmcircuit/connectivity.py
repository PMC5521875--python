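"""Effective-connectivity layer: stepwise input selection, Monte-Carlo
surrogate significance with Fisher z, and ROC/AUC predictive power.

For every output (CA1) unit, candidate input (CA3) units are added greedily
as long as each addition improves the out-of-sample Pearson correlation
``rho`` between the one-step-ahead drive and the binary output by more than a
threshold ``epsilon`` (a Granger-style criterion).  The selected model is then
tested against a Monte-Carlo null: each surrogate circularly shifts every
input train by a random offset (preserving rates and rhythmicity), refits the
feedforward coefficients with the feedback filter retained, and records its
out-of-sample rho.  Fisher z-transformed surrogate rhos are fit with a
normal distribution, and the model is significant when the upper-tail
probability of the true z falls below the threshold (default 1e-4, with 40
surrogates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import AnalysisConfig, default_config
from .errors import (DegenerateNullError, InsufficientDataError, ParameterError,
                     UndefinedMetricError)
from .io import Session, SpikeTrain
from .laguerre import Filter, LaguerreBasis, laguerre_basis
from .mvar import MvarModel, Prediction, _values, build_design, predict


@dataclass
class SignificanceResult:
    """Surrogate test for one model's feedforward predictive content."""

    rho_true: float
    z_true: float
    surrogate_z: np.ndarray
    p_value: float
    threshold: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class ConnectivityGraph:
    """Per-session effective-connectivity result."""

    session_id: str
    models: dict = field(default_factory=dict)        # ca1 unit -> MvarModel
    significance: dict = field(default_factory=dict)  # ca1 unit -> SignificanceResult|None
    auc: dict = field(default_factory=dict)           # ca1 unit -> float (significant models)
    edges: list = field(default_factory=list)         # (ca3 unit, ca1 unit, Filter)
    fb_filters: dict = field(default_factory=dict)    # ca1 unit -> Filter (significant models)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_significant(self) -> int:
        return sum(1 for s in self.significance.values()
                   if s is not None and s.significant)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_auc(self) -> float:
        vals = [a for a in self.auc.values() if np.isfinite(a)]
        return float(np.mean(vals)) if vals else float("nan")


def _fisher_z(rho: float) -> float:
    return float(np.arctanh(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12)))


def _smooth_rho(p: np.ndarray, t: np.ndarray, sigma: float) -> float:
    if sigma > 0:
        p = gaussian_filter1d(p, sigma)
        t = gaussian_filter1d(t, sigma)
    if p.size < 3 or p.std() == 0 or t.std() == 0:
        return 0.0
    return float(np.corrcoef(p, t)[0, 1])


class _DesignWorkspace:
    """Shared design matrix, train/test split and Gram-matrix machinery for
    one output unit, so stepwise rounds and surrogates reuse the heavy work."""

    def __init__(self, output, inputs, basis: LaguerreBasis,
                 config: AnalysisConfig,
                 seg_starts: Sequence[int] | None = None):
        self.config = config
        self.basis = basis
        self.y = _values(output)
        self.X, self.valid = build_design(output, inputs, basis, seg_starts)
        T = self.y.size
        self.split = int(round(T * (1.0 - config.fit.test_fraction)))
        idx = np.arange(T)
        self.train_rows = self.valid & (idx < self.split)
        self.test_rows = self.valid & (idx >= self.split)
        self.A = self.X[self.train_rows]
        self.y_train = self.y[self.train_rows]
        self.Xte = self.X[self.test_rows]
        self.y_test = self.y[self.test_rows]
        self.G = self.A.T @ self.A
        self.c = self.A.T @ self.y_train
        self.L = basis.L
        self.n_inputs = len(inputs)

    def columns(self, selected: Sequence[int]) -> np.ndarray:
        L, N = self.L, self.n_inputs
        cols = [0]
        for n in selected:
            cols.extend(range(1 + n * L, 1 + (n + 1) * L))
        cols.extend(range(1 + N * L, 1 + N * L + L))
        return np.asarray(cols)

    def fit_cols(self, cols: np.ndarray) -> np.ndarray:
        Gs = self.G[np.ix_(cols, cols)].copy()
        lam = self.config.fit.ridge_lambda
        if lam > 0:
            Gs[np.diag_indices_from(Gs)] += lam
            Gs[0, 0] -= lam
        try:
            return np.linalg.solve(Gs, self.c[cols])
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(Gs, self.c[cols], rcond=None)[0]

    def oos_rho(self, cols: np.ndarray, beta: np.ndarray) -> float:
        pred = self.Xte[:, cols] @ beta
        return _smooth_rho(pred, self.y_test, self.config.fit.smooth_sigma)


def stepwise_select(
    output,
    candidates: Sequence,
    basis: LaguerreBasis | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    seg_starts: Sequence[int] | None = None,
) -> MvarModel:
    """Forward stepwise selection of input units for one output unit.

    Starting from the feedback-only model, each round adds the candidate that
    most improves out-of-sample rho, provided the improvement exceeds
    ``config.select.epsilon``; ties break lexicographically on unit id.  A
    model with zero selected inputs is a valid outcome.
    """
    if not len(candidates):
        raise ParameterError("candidate list must be non-empty")
    config = config or default_config()
    basis = basis or laguerre_basis(config.laguerre.alpha, config.laguerre.L,
                                    config.laguerre.M)
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].unit_id
                                  if isinstance(candidates[i], SpikeTrain)
                                  else str(i)))
    ws = _DesignWorkspace(output, candidates, basis, config, seg_starts)
    n_min = 10 * (1 + 2 * basis.L)
    if ws.train_rows.sum() <= n_min:
        raise InsufficientDataError("too few training bins for selection")

    selected: list[int] = []
    cols = ws.columns(selected)
    current_rho = ws.oos_rho(cols, ws.fit_cols(cols))
    trace = [("feedback_only", current_rho)]
    remaining = list(order)
    eps = config.select.epsilon
    while remaining:
        best_idx, best_rho = None, -np.inf
        for i in remaining:  # lexicographic order => first best wins ties
            cols_i = ws.columns(selected + [i])
            rho_i = ws.oos_rho(cols_i, ws.fit_cols(cols_i))
            if rho_i > best_rho:
                best_idx, best_rho = i, rho_i
        if best_idx is None or not np.isfinite(best_rho) \
                or best_rho - current_rho <= eps:
            break
        selected.append(best_idx)
        remaining.remove(best_idx)
        current_rho = best_rho
        trace.append((_uid(candidates[best_idx], best_idx), current_rho))

    selected_sorted = sorted(selected,
                             key=lambda i: _uid(candidates[i], i))
    cols = ws.columns(selected_sorted)
    beta = ws.fit_cols(cols)
    L = basis.L
    n_sel = len(selected_sorted)
    resid = ws.y_train - ws.A[:, cols] @ beta
    model = MvarModel(
        output_unit=_uid(output, "output"),
        input_units=[_uid(candidates[i], i) for i in selected_sorted],
        offset=float(beta[0]),
        ff_coeffs=beta[1:1 + n_sel * L].reshape(n_sel, L),
        fb_coeffs=beta[1 + n_sel * L:].copy(),
        basis=basis,
        bin_width=(output.bin_width if isinstance(output, SpikeTrain) else 0.004),
        diagnostics={
            "oos_rho": current_rho,
            "split": ws.split,
            "selection_trace": trace,
            "residual_variance": float(resid @ resid / max(resid.size - cols.size, 1)),
            "n_samples": int(ws.train_rows.sum()),
            "selected_indices": selected_sorted,
        },
    )
    return model


def _uid(x, fallback) -> str:
    return x.unit_id if isinstance(x, SpikeTrain) else f"unit{fallback}"


def surrogate_significance(
    model: MvarModel,
    data: tuple,
    n_surrogates: int | None = None,
    threshold: float | None = None,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
    seg_starts: Sequence[int] | None = None,
) -> SignificanceResult:
    """Monte-Carlo surrogate test of a model's feedforward predictive power.

    ``data`` is ``(output_train, input_trains)`` for the model's selected
    inputs, in model order.  Each surrogate independently shifts every input
    train circularly by at least ``config.surrogate.min_shift`` seconds
    (mode ``"permute"`` shuffles bins instead), refits the feedforward
    coefficients and offset with the feedback coefficients retained, and
    records its out-of-sample rho.  p is the upper-tail normal probability of
    the true Fisher z under a normal fit to the surrogate z-scores.
    """
    config = config or default_config()
    n_surrogates = n_surrogates if n_surrogates is not None else config.surrogate.n
    threshold = threshold if threshold is not None else config.surrogate.threshold
    if n_surrogates < 20:
        raise ParameterError("n_surrogates must be at least 20")
    if model.n_inputs == 0:
        raise ParameterError("surrogate test undefined for a zero-input model")
    output, inputs = data
    rng = np.random.default_rng(seed)
    ws = _DesignWorkspace(output, inputs, model.basis, config, seg_starts)
    L = model.basis.L
    N = model.n_inputs
    all_cols = ws.columns(range(N))
    beta_true = np.concatenate(([model.offset], np.ravel(model.ff_coeffs),
                                model.fb_coeffs))
    rho_true = ws.oos_rho(all_cols, beta_true)

    fb_cols = np.arange(1 + N * L, 1 + N * L + L)
    fb_part = ws.X[:, fb_cols] @ model.fb_coeffs
    r = ws.y - fb_part
    r_train = r[ws.train_rows]
    fb_te = fb_part[ws.test_rows]

    bw = output.bin_width if isinstance(output, SpikeTrain) else 0.004
    min_shift = max(int(round(config.surrogate.min_shift / bw)), 1)
    T = ws.y.size
    if T <= 2 * min_shift:
        raise ParameterError("series too short for the minimum circular shift")

    xs = [_values(tr) for tr in inputs]
    z_surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        F = np.empty((T, N * L))
        for n, x in enumerate(xs):
            if config.surrogate.mode == "permute":
                x_s = rng.permutation(x)
            else:
                off = int(rng.integers(min_shift, T - min_shift))
                x_s = np.roll(x, off)
            F[:, n * L:(n + 1) * L] = _basis_cols(x_s, model.basis)
        D = np.column_stack([np.ones(T), F])
        Dtr = D[ws.train_rows]
        G = Dtr.T @ Dtr
        try:
            beta_s = np.linalg.solve(G, Dtr.T @ r_train)
        except np.linalg.LinAlgError:
            beta_s = np.linalg.lstsq(Dtr, r_train, rcond=None)[0]
        pred = D[ws.test_rows] @ beta_s + fb_te
        z_surr[s] = _fisher_z(_smooth_rho(pred, ws.y_test,
                                          config.fit.smooth_sigma))
    sd = float(z_surr.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("surrogate Fisher z-scores have zero spread")
    z_true = _fisher_z(rho_true)
    p = float(norm.sf((z_true - z_surr.mean()) / sd))
    return SignificanceResult(rho_true=rho_true, z_true=z_true,
                              surrogate_z=z_surr, p_value=p,
                              threshold=threshold)


def _basis_cols(x: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    from .laguerre import convolve_basis
    return convolve_basis(x, basis, lag_start=0)


def roc_auc(prediction: Prediction, output, min_bins: int = 100) -> RocCurve:
    """ROC curve of the continuous drive against the binary output over valid
    bins; AUC by the trapezoid rule (equals the Mann-Whitney statistic)."""
    y = _values(output)[prediction.valid_mask].astype(int)
    p = prediction.values[prediction.valid_mask]
    if y.size < min_bins:
        raise InsufficientDataError(f"need at least {min_bins} valid bins")
    if y.min() == y.max():
        raise UndefinedMetricError("output has a single class; AUC undefined")
    fpr, tpr, thr = _sk_roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def build_graph(
    sessions: dict[str, Session] | Sequence[Session],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict[str, ConnectivityGraph]:
    """Run selection + significance for every CA1 unit of every session.

    Edges (with their feedforward filters) and feedback filters are harvested
    from significant models only; a zero-input model is never significant.
    """
    config = config or default_config()
    basis = laguerre_basis(config.laguerre.alpha, config.laguerre.L,
                           config.laguerre.M)
    if isinstance(sessions, dict):
        sessions = list(sessions.values())
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    graphs: dict[str, ConnectivityGraph] = {}
    for sess in sessions:
        graph = ConnectivityGraph(session_id=sess.session_id)
        child_seeds = ss.spawn(1)[0].generate_state(max(len(sess.ca1), 1))
        for k, out_train in enumerate(sess.ca1):
            if not sess.ca3:
                continue
            model = stepwise_select(out_train, sess.ca3, basis, config,
                                    seed=int(child_seeds[k] % (2 ** 31)))
            graph.models[out_train.unit_id] = model
            if model.n_inputs == 0:
                graph.significance[out_train.unit_id] = None
                continue
            sel = [tr for tr in sess.ca3 if tr.unit_id in model.input_units]
            sig = surrogate_significance(
                model, (out_train, sel), config=config,
                seed=int(child_seeds[k] % (2 ** 31)))
            graph.significance[out_train.unit_id] = sig
            if sig.significant:
                for uid, filt in zip(model.input_units,
                                     model.feedforward_filters()):
                    graph.edges.append((uid, out_train.unit_id, filt))
                graph.fb_filters[out_train.unit_id] = model.feedback_filter()
                pred = predict(model, sel, out_train)
                idx = np.arange(out_train.n_bins)
                pred.valid_mask &= idx >= model.diagnostics["split"]
                try:
                    graph.auc[out_train.unit_id] = roc_auc(pred, out_train).auc
                except (InsufficientDataError, UndefinedMetricError):
                    graph.auc[out_train.unit_id] = float("nan")
        graphs[sess.session_id] = graph
    return graphs
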