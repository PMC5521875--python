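"""Discrete orthonormal Laguerre basis, filter expansion and regressors.

The discrete Laguerre functions (DLFs) are exponentially decaying orthonormal
sequences controlled by a decay parameter ``alpha``; expanding lag filters
over ``L`` of them reduces an (M+1)-parameter filter to L coefficients.  Two
constructions are provided: the stable two-term recursion (production path)
and the closed-form binomial sum (used as an independent cross-check).

Defaults ``alpha=0.7, L=5, M=120`` give 480 ms of memory at 4 ms bins — long
enough to cover both the ~40 ms refractory trough and a low-theta (~3.5 Hz)
feedback resonance — with the truncated basis still orthonormal to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .errors import ParameterError

DEFAULT_ALPHA = 0.7
DEFAULT_L = 5
DEFAULT_M = 120
DEFAULT_BIN_WIDTH = 0.004

FILTER_KINDS = ("feedforward", "feedback")


@dataclass
class Filter:
    """Lag-indexed filter.  Feedforward filters act at lags 0..M, feedback
    (autoregressive) filters at lags 1..M+1; both store M+1 values."""

    kind: str
    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    coeffs: np.ndarray | None = None  # Laguerre coefficients when known

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.coeffs is not None:
            self.coeffs = np.asarray(self.coeffs, dtype=float)

    @property
    def lag_start(self) -> int:
        return 0 if self.kind == "feedforward" else 1

    @property
    def lags_seconds(self) -> np.ndarray:
        return (np.arange(self.values.size) + self.lag_start) * self.bin_width


@dataclass
class LaguerreBasis:
    """Orthonormal DLF basis matrix ``B`` of shape (M+1, L)."""

    alpha: float
    L: int
    M: int
    B: np.ndarray

    def project(self, values: Sequence[float]) -> np.ndarray:
        """Coefficients of the least-squares projection onto the basis span
        (exact LS solve, robust to the tiny truncation non-orthonormality)."""
        return np.linalg.lstsq(self.B, np.asarray(values, dtype=float),
                               rcond=None)[0]


def laguerre_basis(alpha: float = DEFAULT_ALPHA, L: int = DEFAULT_L,
                   M: int = DEFAULT_M) -> LaguerreBasis:
    """Build the DLF basis by the stable recursion.

    ``b_0(0) = sqrt(1-alpha)``, ``b_0(m) = sqrt(alpha) b_0(m-1)`` and
    ``b_j(m) = sqrt(alpha) b_j(m-1) + sqrt(alpha) b_{j-1}(m) - b_{j-1}(m-1)``.
    """
    _check_params(alpha, L, M)
    sa = np.sqrt(alpha)
    B = np.zeros((M + 1, L))
    B[0, 0] = np.sqrt(1.0 - alpha)
    for m in range(1, M + 1):
        B[m, 0] = sa * B[m - 1, 0]
    for j in range(1, L):
        B[0, j] = sa * B[0, j - 1]
        for m in range(1, M + 1):
            B[m, j] = sa * B[m - 1, j] + sa * B[m, j - 1] - B[m - 1, j - 1]
    return LaguerreBasis(alpha=alpha, L=L, M=M, B=B)


def laguerre_basis_closed_form(alpha: float, L: int, M: int) -> LaguerreBasis:
    """Closed-form DLF construction (binomial sum); cross-check for the
    recursion, numerically safe only for moderate lag/order."""
    _check_params(alpha, L, M)
    B = np.zeros((M + 1, L))
    for j in range(L):
        for m in range(M + 1):
            s = sum((-1) ** k * comb(m, k) * comb(j, k)
                    * alpha ** (j - k) * (1.0 - alpha) ** k
                    for k in range(j + 1))
            B[m, j] = alpha ** ((m - j) / 2.0) * np.sqrt(1.0 - alpha) * s
    return LaguerreBasis(alpha=alpha, L=L, M=M, B=B)


def _check_params(alpha: float, L: int, M: int) -> None:
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie strictly inside (0, 1)")
    if L < 1:
        raise ParameterError("L must be a positive count")
    if M < L:
        raise ParameterError("M must be at least L")


def convolve_basis(x: Sequence[float], basis: LaguerreBasis,
                   lag_start: int = 0) -> np.ndarray:
    """Convolve a series with every basis function: column ``j`` at time ``t``
    is ``sum_tau b_j(tau - lag_start) x(t - tau)`` with zero-padded history.

    ``lag_start=1`` shifts the series one bin into the past first, which
    realises the autoregressive (feedback) regressor that must not see the
    current output bin.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("x must be one-dimensional")
    if x.size <= basis.M:
        raise ParameterError("series shorter than the basis memory")
    if lag_start not in (0, 1):
        raise ParameterError("lag_start must be 0 or 1")
    if lag_start == 1:
        x = np.concatenate(([0.0], x[:-1]))
    from scipy.signal import oaconvolve
    return oaconvolve(x[:, None], basis.B, axes=0)[: x.size]


def reconstruct_filter(coeffs: Sequence[float], basis: LaguerreBasis,
                       kind: str, bin_width: float = DEFAULT_BIN_WIDTH) -> Filter:
    """Reconstruct the lag-domain filter ``B @ coeffs`` from its expansion."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (basis.L,):
        raise ParameterError(
            f"expected {basis.L} coefficients, got {coeffs.shape}")
    return Filter(kind=kind, values=basis.B @ coeffs, bin_width=bin_width,
                  coeffs=coeffs)
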