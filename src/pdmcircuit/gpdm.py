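"""Global principal dynamic modes (gPDMs) of a filter population.

All filters of one family (feedforward or feedback), pooled over sessions and
conditions, are stacked row-wise into a rectangular matrix; the leading right
singular vectors of that matrix are the gPDMs — shared dynamical building
blocks of the whole population.  Rows are not mean-centred by default (this
is an SVD of the filters themselves, not PCA); a ``center`` flag enables the
PCA variant.  One mode set is always estimated from the pooled
control + drug filters, never per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .laguerre import Filter


@dataclass
class GpdmSet:
    family: str                    # "feedforward" or "feedback"
    modes: np.ndarray              # (M+1, n_modes), orthonormal columns
    singular_values: np.ndarray    # all singular values, non-increasing
    variance_explained: np.ndarray # fraction per kept mode
    centered: bool = False

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def stack_filters(filters: Sequence[Filter]) -> np.ndarray:
    """Stack same-family filters into an (n_filters, M+1) matrix, rows in the
    (stable) order the filters are supplied."""
    if not len(filters):
        raise ParameterError("cannot stack an empty filter collection")
    kind = filters[0].kind
    n = filters[0].values.size
    bw = filters[0].bin_width
    rows = []
    for f in filters:
        if f.kind != kind:
            raise ParameterError("mixed filter families in one stack")
        if f.values.size != n or f.bin_width != bw:
            raise ParameterError("filters differ in length or bin width")
        rows.append(f.values)
    return np.vstack(rows)


def compute_gpdms(matrix: np.ndarray, n_modes: int = 3,
                  family: str = "feedforward",
                  center: bool = False) -> GpdmSet:
    """Leading right singular vectors of the stacked filter matrix.

    Each mode is sign-flipped so its largest-magnitude element is positive
    (SVD sign is arbitrary).  ``variance_explained[i] = s_i^2 / sum s^2``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ParameterError("expected a 2-D stacked filter matrix")
    if n_modes > min(matrix.shape):
        raise ParameterError(
            f"n_modes={n_modes} exceeds min(matrix.shape)={min(matrix.shape)}")
    work = matrix - matrix.mean(axis=0) if center else matrix
    _, s, vt = np.linalg.svd(work, full_matrices=False)
    modes = vt[:n_modes].T.copy()
    for j in range(n_modes):
        i = np.argmax(np.abs(modes[:, j]))
        if modes[i, j] < 0:
            modes[:, j] = -modes[:, j]
    total = float((s ** 2).sum())
    ve = (s[:n_modes] ** 2) / total if total > 0 else np.zeros(n_modes)
    return GpdmSet(family=family, modes=modes, singular_values=s,
                   variance_explained=ve, centered=center)


def gpdm_strength(filt: Filter | np.ndarray, mode: np.ndarray) -> float:
    """Expression strength of one mode in one filter: their inner product."""
    values = filt.values if isinstance(filt, Filter) else np.asarray(filt, float)
    mode = np.asarray(mode, dtype=float)
    if values.size != mode.size:
        raise ParameterError("filter and mode lengths differ")
    return float(values @ mode)


def session_strengths(filters: Sequence[Filter], modes: GpdmSet) -> np.ndarray:
    """Per-mode mean strength over one session's filters of the family."""
    if not len(filters):
        raise ParameterError("session has no filters of this family")
    mat = stack_filters(filters)
    return (mat @ modes.modes).mean(axis=0)
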