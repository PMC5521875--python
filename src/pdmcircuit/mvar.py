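"""Multi-input linear autoregressive spike-train model in Laguerre space.

One output unit's binary train is modelled as a continuous drive

    y(t) = c + sum_n sum_{tau=0..M} k_n(tau) x_n(t-tau)
             + sum_{tau=1..M+1} k_AR(tau) y(t-tau)

with the feedforward filters ``k_n`` and the feedback (autoregressive) filter
``k_AR`` expanded over a shared discrete Laguerre basis.  Estimation is
ordinary least squares of the binary output on the Laguerre regressors (a
linear-probability reading of the model); the offset ``c`` absorbs the
baseline rate.  Prediction is one-step-ahead and deterministic: the drive at
``t`` uses the *observed* output spikes at ``t-1 .. t-(M+1)``.

Concatenated trial segments are handled by zero-padding and masking: filters
never span a segment seam, and the first M+1 bins of each segment are
excluded from fitting and from reported correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisConfig, default_config
from .errors import InsufficientDataError, ParameterError, ValidationError
from .io import SpikeTrain
from .laguerre import Filter, LaguerreBasis, convolve_basis, reconstruct_filter


@dataclass
class MvarModel:
    """Fitted model for one output unit (N >= 0 selected inputs)."""

    output_unit: str
    input_units: list[str]
    offset: float
    ff_coeffs: np.ndarray          # shape (N, L)
    fb_coeffs: np.ndarray          # shape (L,)
    basis: LaguerreBasis
    bin_width: float = 0.004
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return len(self.input_units)

    def feedforward_filters(self) -> list[Filter]:
        return [reconstruct_filter(c, self.basis, "feedforward", self.bin_width)
                for c in np.atleast_2d(self.ff_coeffs)][: self.n_inputs]

    def feedback_filter(self) -> Filter:
        return reconstruct_filter(self.fb_coeffs, self.basis, "feedback",
                                  self.bin_width)


@dataclass
class Prediction:
    """One-step-ahead continuous drive aligned to the output train."""

    values: np.ndarray
    valid_mask: np.ndarray


def _values(x) -> np.ndarray:
    if isinstance(x, SpikeTrain):
        return x.values.astype(float)
    return np.asarray(x, dtype=float)


def _unit_id(x, fallback: str) -> str:
    return x.unit_id if isinstance(x, SpikeTrain) else fallback


def _check_alignment(output, inputs) -> None:
    if not isinstance(output, SpikeTrain):
        return
    for tr in inputs:
        if isinstance(tr, SpikeTrain):
            if tr.bin_width != output.bin_width or tr.n_bins != output.n_bins:
                raise ParameterError(
                    f"train {tr.unit_id!r} does not share the output's "
                    "bin width and extent")


def build_design(
    output,
    inputs: Sequence,
    basis: LaguerreBasis,
    seg_starts: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [1 | N x L feedforward | L feedback] and validity mask.

    ``seg_starts`` lists the first bin of each concatenated segment (0 must be
    included); history is zero-padded at each seam and the first M+1 bins of
    every segment are marked invalid.
    """
    y = _values(output)
    xs = [_values(tr) for tr in inputs]
    T = y.size
    if seg_starts is None:
        seg_starts = [0]
    seg_starts = sorted(int(s) for s in seg_starts)
    if seg_starts[0] != 0:
        raise ParameterError("seg_starts must include 0")
    bounds = seg_starts + [T]

    L, M = basis.L, basis.M
    X = np.empty((T, 1 + len(xs) * L + L))
    X[:, 0] = 1.0
    valid = np.ones(T, dtype=bool)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        if s1 - s0 <= M:
            valid[s0:s1] = False
            continue
        for n, x in enumerate(xs):
            X[s0:s1, 1 + n * L:1 + (n + 1) * L] = convolve_basis(
                x[s0:s1], basis, lag_start=0)
        X[s0:s1, 1 + len(xs) * L:] = convolve_basis(y[s0:s1], basis, lag_start=1)
        valid[s0:s0 + M + 1] = False
    return X, valid


def fit_mvar(
    output,
    inputs: Sequence,
    basis: LaguerreBasis,
    config: AnalysisConfig | None = None,
    seg_starts: Sequence[int] | None = None,
    fit_mask: np.ndarray | None = None,
) -> MvarModel:
    """Least-squares fit of the model over bins with full history.

    ``fit_mask`` optionally restricts the fitting bins further (train/test
    protocols); the design is always built over the whole series.
    """
    config = config or default_config()
    _check_alignment(output, inputs)
    y = _values(output)
    L = basis.L
    n_params = 1 + len(inputs) * L + L
    X, valid = build_design(output, inputs, basis, seg_starts)
    mask = valid if fit_mask is None else (valid & np.asarray(fit_mask, bool))
    n_samples = int(mask.sum())
    if n_samples <= 10 * n_params:
        raise InsufficientDataError(
            f"{n_samples} usable bins for {n_params} parameters "
            "(need > 10x the parameter count)")

    A, b = X[mask], y[mask]
    lam = config.fit.ridge_lambda
    if lam > 0:
        G = A.T @ A
        G[np.diag_indices_from(G)] += lam
        G[0, 0] -= lam  # never penalise the intercept
        beta = np.linalg.solve(G, A.T @ b)
        sv = np.linalg.svd(A, compute_uv=False)
    else:
        beta, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
        if rank < n_params:
            names = ", ".join(_unit_id(tr, f"input{i}")
                              for i, tr in enumerate(inputs))
            raise ValidationError(
                "rank-deficient design (collinear regressors) among inputs "
                f"[{names}]; enable fit.ridge_lambda to proceed")
    resid = b - A @ beta
    diag = {
        "residual_variance": float(resid @ resid / max(n_samples - n_params, 1)),
        "condition_number": float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf,
        "n_samples": n_samples,
    }
    ff = beta[1:1 + len(inputs) * L].reshape(len(inputs), L)
    return MvarModel(
        output_unit=_unit_id(output, "output"),
        input_units=[_unit_id(tr, f"input{i}") for i, tr in enumerate(inputs)],
        offset=float(beta[0]),
        ff_coeffs=ff,
        fb_coeffs=beta[1 + len(inputs) * L:].copy(),
        basis=basis,
        bin_width=output.bin_width if isinstance(output, SpikeTrain) else 0.004,
        diagnostics=diag,
    )


def predict(
    model: MvarModel,
    inputs: Sequence,
    output,
    seg_starts: Sequence[int] | None = None,
) -> Prediction:
    """Deterministic one-step-ahead drive given observed inputs and output."""
    if isinstance(inputs, (list, tuple)) and all(
            isinstance(tr, SpikeTrain) for tr in inputs) and model.input_units:
        have = [tr.unit_id for tr in inputs]
        if have != model.input_units:
            missing = [u for u in model.input_units if u not in have]
            raise ValidationError(
                f"input units {have} do not match model inputs "
                f"{model.input_units}; missing {missing}")
    X, valid = build_design(output, inputs, model.basis, seg_starts)
    beta = np.concatenate(([model.offset], np.ravel(model.ff_coeffs),
                           model.fb_coeffs))
    return Prediction(values=X @ beta, valid_mask=valid)


def prediction_rho(
    pred: Prediction,
    output,
    eval_mask: np.ndarray | None = None,
    smooth_sigma: float = 0.0,
) -> float:
    """Pearson correlation between the continuous drive and the binary output
    over valid (optionally restricted) bins; optional Gaussian smoothing of
    both series (sigma in bins) before correlating."""
    y = _values(output)
    mask = pred.valid_mask if eval_mask is None else (
        pred.valid_mask & np.asarray(eval_mask, bool))
    p, t = pred.values[mask], y[mask]
    if smooth_sigma > 0:
        p = gaussian_filter1d(p, smooth_sigma)
        t = gaussian_filter1d(t, smooth_sigma)
    if p.size < 3 or p.std() == 0 or t.std() == 0:
        return 0.0
    return float(np.corrcoef(p, t)[0, 1])
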