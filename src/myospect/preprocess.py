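"""Signal conditioning for surface interference-pattern EMG.

The conditioning chain is: zero-phase Butterworth band-pass (20–1000 Hz),
a zero-phase notch comb on the 60 Hz mains line and its odd harmonics up
to 900 Hz, removal of the first and last 5 s (which also absorbs filter
transients), and selection of the initial 30 s analysis segment.
Intramuscular channels are analyzed raw and must not pass through this
chain.

All filters are applied forward-backward (``sosfiltfilt``) in
second-order-sections form: direct-form transfer functions of effective
order 8 at a 20 kHz rate are numerically fragile, and the
forward-backward pass cancels phase distortion so MUAP timing is
preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core_io import (
    AnalysisConfig,
    ConfigurationError,
    EmgSignal,
    SignalTooShortError,
)

#: Butterworth order per pass; forward-backward application doubles it.
BANDPASS_ORDER = 4
#: -3 dB width of each notch, Hz.
NOTCH_BANDWIDTH_HZ = 2.0


def _bandpass_sos(low: float, high: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ConfigurationError(
            f"band-pass cutoffs ({low}, {high}) Hz invalid for fs {fs} Hz"
        )
    return sps.butter(BANDPASS_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def _notch_sos(freq: float, fs: float) -> np.ndarray:
    if freq >= fs / 2.0:
        raise ConfigurationError(f"notch at {freq} Hz is at/above Nyquist for fs {fs} Hz")
    q = freq / NOTCH_BANDWIDTH_HZ
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.tf2sos(b, a)


def bandpass_filter(signal: EmgSignal, low: float = 20.0, high: float = 1000.0) -> EmgSignal:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    sos = _bandpass_sos(low, high, signal.fs)
    return signal.with_samples(sps.sosfiltfilt(sos, signal.samples))


def notch_comb(
    signal: EmgSignal,
    freqs: tuple[float, ...] = AnalysisConfig().notch_freqs,
) -> EmgSignal:
    """Zero-phase notch filters applied in cascade at each frequency."""
    out = signal.samples
    for freq in freqs:
        out = sps.sosfiltfilt(_notch_sos(freq, signal.fs), out)
    return signal.with_samples(out)


def trim_edges(signal: EmgSignal, trim_s: float = 5.0) -> EmgSignal:
    """Drop the initial and final ``trim_s`` seconds of a filtered trial."""
    n_trim = round(trim_s * signal.fs)
    if signal.duration <= 2 * trim_s:
        raise SignalTooShortError(
            f"signal of {signal.duration:.3f} s too short to trim {trim_s} s per edge"
        )
    return signal.with_samples(signal.samples[n_trim : len(signal.samples) - n_trim])


def take_initial_segment(signal: EmgSignal, seconds: float = 30.0) -> EmgSignal:
    """Keep the first ``seconds`` of the (trimmed) interference recording."""
    n = round(seconds * signal.fs)
    if len(signal.samples) < n:
        raise SignalTooShortError(
            f"signal of {signal.duration:.3f} s shorter than requested {seconds} s segment"
        )
    return signal.with_samples(signal.samples[:n])


def preprocess_interference(signal: EmgSignal, config: AnalysisConfig | None = None) -> EmgSignal:
    """Full conditioning chain for a surface interference recording.

    Band-pass, then notch comb, then edge trim, then the initial analysis
    segment. Intramuscular signals are returned untouched, mirroring the
    acquisition protocol in which only surface channels were filtered.

    Recordings delivered at exactly the analysis-segment length (e.g.
    simulated 30 s signals) are filtered but not trimmed, since there are
    no acquisition edges to discard.
    """
    config = config or AnalysisConfig()
    if signal.source == "intramuscular":
        return signal
    config.validate_for_fs(signal.fs)
    out = bandpass_filter(signal, config.bandpass_low, config.bandpass_high)
    out = notch_comb(out, config.notch_freqs)
    n_segment = round(config.interference_segment_s * signal.fs)
    if len(out.samples) == n_segment:
        return out
    out = trim_edges(out, config.edge_trim_s)
    return take_initial_segment(out, config.interference_segment_s)
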