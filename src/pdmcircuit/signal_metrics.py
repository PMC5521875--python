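"""Single-train signal analyses: firing rate, Welch spectra with paired
group-difference bounds, and sample-presentation cell classification.

Spike-train spectra use Welch's method on the mean-subtracted binary series
(4 s Hann windows, 50% overlap by default) and are normalized per cell to
unit total power over 1-50 Hz before any averaging or differencing, so
condition contrasts compare spectral *shape* rather than rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .config import AnalysisConfig, default_config
from .errors import InsufficientDataError, ParameterError
from .io import SpikeTrain


@dataclass
class SignalSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    nperseg: int
    noverlap: int
    window: str = "hann"


@dataclass
class GroupSpectrumDiff:
    freqs: np.ndarray
    mean_diff: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    coverage: float
    n_units: int


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count over duration, in Hz."""
    if train.duration <= 0:
        raise ParameterError("train has zero duration")
    return float(train.values.sum() / train.duration)


def spiketrain_spectrum(train: SpikeTrain,
                        config: AnalysisConfig | None = None) -> SignalSpectrum:
    """Welch spectrum of the mean-subtracted binary series, normalized to
    unit total power over the configured band (default 1-50 Hz)."""
    config = config or default_config()
    if train.duration < 10.0:
        raise InsufficientDataError("need at least 10 s of data for a spectrum")
    fs = 1.0 / train.bin_width
    nperseg = min(int(round(4.0 * fs)), train.n_bins)
    x = train.values.astype(float)
    x = x - x.mean()
    freqs, power = welch(x, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2)
    lo, hi = config.bands.norm_band
    band = (freqs >= lo) & (freqs <= hi)
    total = power[band].sum()
    if total > 0:
        power = power / total
    return SignalSpectrum(freqs=freqs, power=power, nperseg=nperseg,
                          noverlap=nperseg // 2)


def signal_band_power(spec: SignalSpectrum, f_lo: float, f_hi: float) -> float:
    """Sum of normalized power over ``[f_lo, f_hi]`` (inclusive band)."""
    sel = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    return float(spec.power[sel].sum())


def spectrum_difference(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    freqs: np.ndarray,
    coverage: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
) -> GroupSpectrumDiff:
    """Mean within-unit difference spectrum (A - B) with bootstrap bounds.

    ``cells_a``/``cells_b`` are (n_units, n_freqs) arrays of per-unit spectra
    paired by row (a unit's spectra averaged within each condition first).
    Bounds are pointwise percentile intervals from resampling units with
    replacement.
    """
    cells_a = np.atleast_2d(np.asarray(cells_a, float))
    cells_b = np.atleast_2d(np.asarray(cells_b, float))
    if cells_a.shape != cells_b.shape:
        raise ParameterError("paired spectra must have identical shape")
    n_units = cells_a.shape[0]
    if n_units < 5:
        raise InsufficientDataError(
            "need at least 5 paired units for difference bounds")
    diffs = cells_a - cells_b
    mean_diff = diffs.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_units, size=(n_boot, n_units))
    boot = diffs[idx].mean(axis=1)
    alpha = (1.0 - coverage) / 2.0
    ci_lo = np.quantile(boot, alpha, axis=0)
    ci_hi = np.quantile(boot, 1.0 - alpha, axis=0)
    ci_lo = np.minimum(ci_lo, mean_diff)
    ci_hi = np.maximum(ci_hi, mean_diff)
    return GroupSpectrumDiff(freqs=np.asarray(freqs, float),
                             mean_diff=mean_diff, ci_lo=ci_lo, ci_hi=ci_hi,
                             coverage=coverage, n_units=n_units)


def classify_sample_presentation(
    train: SpikeTrain,
    sample_events: np.ndarray,
    window: float = 1.5,
    n_shifts: int = 1000,
    level: float = 0.99,
    seed: int | None = None,
    min_events: int = 20,
) -> tuple[bool | None, float]:
    """Classify a unit as sample-presentation responsive.

    The firing rate inside ``[event, event + window)`` is compared with a null
    built from circular shifts of the event times over the train extent; the
    unit is positive when the observed rate exceeds the null's ``level``
    quantile.  Returns ``(flag, effect)`` where effect is the observed rate
    relative to the null mean minus 1; ``flag`` is ``None`` (undetermined)
    with fewer than ``min_events`` events.  This criterion is
    implementation-defined (windowed-rate versus a shift null).
    """
    events = np.asarray(sample_events, dtype=float)
    if events.size < min_events:
        return None, float("nan")
    if train.values.sum() == 0:
        return False, 0.0
    spikes = train.spike_times()
    duration = train.duration

    def _windowed_rate(ev: np.ndarray) -> float:
        count = (np.searchsorted(spikes, ev + window)
                 - np.searchsorted(spikes, ev)).sum()
        return float(count) / (ev.size * window)

    observed = _windowed_rate(events)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shifts)
    rel = events - train.t_start
    for i in range(n_shifts):
        shifted = (rel + rng.uniform(0.0, duration)) % duration + train.t_start
        null[i] = _windowed_rate(shifted)
    crit = np.quantile(null, level)
    null_mean = null.mean()
    effect = observed / null_mean - 1.0 if null_mean > 0 else 0.0
    return bool(observed > crit), float(effect)
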