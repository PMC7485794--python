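"""Spectral preprocessing: Savitzky-Golay smoothing and per-band SNR.

Smoothing fits a moving least-squares polynomial along the wavelength axis of
each sample's spectrum.  Edges use a polynomial fit over the terminal window
(scipy's ``interp`` mode), so constants and low-degree polynomials pass
through unchanged everywhere.

The signal-to-noise ratio of a band is the ratio of the band's total signal
power (mean square across samples) to its variance across samples, in dB:
``SNR = 10 log10(mean(x^2) / var(x))`` with the population variance.  A band
that is constant across samples has zero variance and reports ``+inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .calibration import SpectrumSet, replace_values
from .exceptions import ConfigurationError

__all__ = ["SmoothingConfig", "savgol_smooth", "band_snr", "pooled_snr"]


@dataclass(frozen=True)
class SmoothingConfig:
    """Window length in bands (odd) and polynomial degree."""

    window_length: int = 11
    polyorder: int = 3

    def __post_init__(self):
        if self.window_length % 2 == 0:
            raise ConfigurationError("window_length: must be odd")
        if self.window_length < self.polyorder + 2:
            raise ConfigurationError("window_length: must be >= polyorder + 2")
        if self.polyorder < 0:
            raise ConfigurationError("polyorder: must be >= 0")


def savgol_smooth(s: SpectrumSet, cfg: SmoothingConfig = SmoothingConfig()) -> SpectrumSet:
    if s.n_bands < cfg.window_length:
        raise ConfigurationError(
            f"window_length {cfg.window_length} exceeds band count {s.n_bands}"
        )
    smoothed = savgol_filter(
        s.values, cfg.window_length, cfg.polyorder, axis=1, mode="interp"
    )
    return replace_values(s, smoothed)


def band_snr(s: SpectrumSet) -> np.ndarray:
    """Per-band SNR in dB across samples; ``+inf`` where variance is zero."""
    if s.n_samples < 2:
        raise ConfigurationError("band_snr: need at least 2 samples")
    power = np.mean(s.values**2, axis=0)
    var = np.var(s.values, axis=0)  # population variance
    with np.errstate(divide="ignore"):
        ratio = np.where(var > 0, power / np.where(var > 0, var, 1.0), np.inf)
        snr = 10.0 * np.log10(ratio)
    return snr


def pooled_snr(s: SpectrumSet) -> float:
    """Single summary SNR pooling all bands: total power over pooled variance, dB."""
    if s.n_samples < 2:
        raise ConfigurationError("pooled_snr: need at least 2 samples")
    power = float(np.mean(s.values**2))
    var = float(np.var(s.values))
    if var == 0:
        return float("inf")
    return 10.0 * np.log10(power / var)
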