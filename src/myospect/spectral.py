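"""Periodogram estimation, median frequency, and the fatigue half-split.

The power spectral density estimator is the plain rectangular-window,
mean-removed periodogram with no zero padding, so the bin spacing is
``fs / N``: 13.333 Hz for a 75 ms MUAP window at 20 kHz and 1/30 Hz for a
30 s interference segment. The median frequency (MDF) is the frequency
that splits the spectrum into halves of equal power,

    sum_{i<=MDF} P_i  =  sum_{i>=MDF} P_i  =  (1/2) sum_{i=1..M} P_i ,

resolved on the discrete bin grid as the lowest-indexed bin whose
cumulative power first reaches half the total (no interpolation between
bins; at the interference resolution of 1/30 Hz the convention is
immaterial).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core_io import (
    AnalysisConfig,
    DegenerateSpectrumError,
    EmgSignal,
    MuapWaveform,
    PowerSpectrum,
    SignalTooShortError,
)


def periodogram(source: EmgSignal | MuapWaveform | np.ndarray, fs: float | None = None) -> PowerSpectrum:
    """Rectangular-window, mean-removed periodogram as per-bin power.

    Returns one-sided bins from ``delta_f`` (the 0 Hz bin is dropped:
    mean removal empties it) up to Nyquist, scaled so the bin powers sum
    to the mean square of the mean-removed segment (Parseval).
    """
    if isinstance(source, (EmgSignal, MuapWaveform)):
        samples = source.samples
        fs = source.fs
    else:
        samples = np.asarray(source, dtype=float)
        if fs is None:
            raise ValueError("fs is required for bare sample arrays")
    if len(samples) < 2:
        raise DegenerateSpectrumError("need at least two samples for a spectrum")
    x = samples - samples.mean()
    if not np.any(x):
        raise DegenerateSpectrumError("constant input has no spectral content")
    freqs, psd = sps.periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    delta_f = freqs[1] - freqs[0]
    # density -> power per bin; drop the (empty) DC bin
    return PowerSpectrum(freqs[1:], psd[1:] * delta_f)


def median_frequency(spectrum: PowerSpectrum, band: tuple[float, float] | None = None) -> float:
    """Median frequency of a power spectrum, optionally band-restricted.

    Lowest-indexed bin whose cumulative power reaches half the total; at
    an exact half-split tie the lower of the two candidate bins is
    reported.
    """
    if band is not None:
        spectrum = spectrum.band(*band)
    total = spectrum.power.sum()
    if spectrum.M == 0 or total <= 0:
        raise DegenerateSpectrumError("median frequency undefined for zero total power")
    cumulative = np.cumsum(spectrum.power)
    idx = int(np.searchsorted(cumulative, total / 2.0))
    return float(spectrum.freqs[idx])


def mdf_of_interference(signal: EmgSignal, config: AnalysisConfig | None = None) -> float:
    """MDF of a preprocessed 30 s interference segment on the analysis band."""
    config = config or AnalysisConfig()
    return median_frequency(
        periodogram(signal), band=(config.bandpass_low, config.bandpass_high)
    )


def fatigue_half_split(
    signal: EmgSignal, config: AnalysisConfig | None = None
) -> tuple[float, float]:
    """MDF of the first and second 15 s halves of a 30 s segment.

    A drop from the first to the second half indicates spectral
    compression over time, the classical myoelectric manifestation of
    fatigue; under a stationary contraction the two values differ only by
    sampling variability.
    """
    config = config or AnalysisConfig()
    n_expected = round(config.interference_segment_s * signal.fs)
    if len(signal.samples) != n_expected:
        raise SignalTooShortError(
            f"half-split requires exactly {config.interference_segment_s} s "
            f"({n_expected} samples); got {len(signal.samples)}"
        )
    half = n_expected // 2
    band = (config.bandpass_low, config.bandpass_high)
    first = median_frequency(periodogram(signal.samples[:half], signal.fs), band=band)
    second = median_frequency(periodogram(signal.samples[half:], signal.fs), band=band)
    return first, second
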