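"""Filter-level metrics: normalized spectra, band power, excitatory index.

Filters are short deterministic lag sequences, so spectra are plain
magnitude-squared FFTs of the zero-padded values (no tapering).  The
excitatory index (EI) is the positive filter area over the total absolute
area — 1 for a purely excitatory filter, 0 for a purely inhibitory one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .laguerre import Filter

NORMALIZATIONS = ("unit_total", "unit_max")


@dataclass
class FilterSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    normalization: str
    bin_width: float

    @property
    def nyquist(self) -> float:
        return 0.5 / self.bin_width

    @property
    def peak_freq(self) -> float:
        return float(self.freqs[np.argmax(self.power)])


def filter_spectrum(filt: Filter, nfft: int | None = None,
                    normalization: str = "unit_total") -> FilterSpectrum:
    """Magnitude-squared DFT of the zero-padded filter at non-negative
    frequencies.  Default nfft gives <= 0.25 Hz resolution at 4 ms bins."""
    if normalization not in NORMALIZATIONS:
        raise ParameterError(f"unknown normalization {normalization!r}")
    k = np.asarray(filt.values, dtype=float)
    if not np.any(k):
        raise UndefinedMetricError("spectrum of an all-zero filter is undefined")
    if nfft is None:
        nfft = 1
        while nfft < max(4 * k.size, int(np.ceil(4.0 / filt.bin_width))):
            nfft <<= 1
    if nfft < 4 * k.size:
        raise ParameterError("nfft must be at least 4x the filter length")
    power = np.abs(np.fft.rfft(k, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, filt.bin_width)
    if normalization == "unit_total":
        power = power / power.sum()
    else:
        power = power / power.max()
    return FilterSpectrum(freqs=freqs, power=power,
                          normalization=normalization,
                          bin_width=filt.bin_width)


def band_power(spectrum: FilterSpectrum, f_lo: float, f_hi: float) -> float:
    """Fraction of (unit_total) spectral power in ``[f_lo, f_hi)``."""
    if spectrum.normalization != "unit_total":
        raise ParameterError("band fractions require unit_total normalization")
    if not (0.0 <= f_lo < f_hi <= spectrum.nyquist):
        raise ParameterError("band must satisfy 0 <= f_lo < f_hi <= Nyquist")
    sel = (spectrum.freqs >= f_lo) & (spectrum.freqs < f_hi)
    if f_hi == spectrum.nyquist:  # close the last band at Nyquist inclusively
        sel |= spectrum.freqs == spectrum.nyquist
    return float(spectrum.power[sel].sum())


def excitatory_index(filt: Filter) -> float:
    """EI = sum of positive values / sum of absolute values, in [0, 1]."""
    k = np.asarray(filt.values, dtype=float)
    total = np.abs(k).sum()
    if total == 0:
        raise UndefinedMetricError("EI of an all-zero filter is undefined")
    return float(k.clip(min=0).sum() / total)
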