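"""Surface MUAP waveform estimation by spike-triggered averaging.

Discharge instants are detected as supra-threshold absolute-amplitude
peaks (a simplified, fully automatic stand-in for interactive EMG
decomposition — validated on synthetic data with ground-truth triggers,
not intended for deposit-grade decomposition), grouped by waveform
similarity, and used to average 75 ms windows of the surface channel
centered on each discharge. Waveform quality is scored with a
peak-to-peak over edge-baseline-noise SNR; near-duplicate waveforms
recovered from different recordings keep only their highest-SNR copy.

Morphology is measured automatically: duration as the span of sustained
supra-threshold excursion and phase count as the number of
above-threshold lobes of alternating sign, surrogates for the study's
manual cursor measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import EmgSignal, MuapWaveform

logger = logging.getLogger("myospect")

#: Fraction of the averaging window, at each edge, treated as baseline.
BASELINE_FRACTION = 0.10
#: Waveforms below this peak-to-peak / baseline-SD ratio are flagged for discard.
SNR_DISCARD_THRESHOLD = 5.0


@dataclass(frozen=True)
class TriggerSet:
    """Peak-aligned discharge instants used to trigger averaging windows."""

    times: np.ndarray
    source: str = "surface"
    unit_id: str = "unspecified"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("trigger times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _robust_sd(x: np.ndarray) -> float:
    """Baseline noise SD via the median absolute deviation (Gaussian-consistent)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)) / 0.6744897501960817)


def detect_spikes(
    signal: EmgSignal, threshold_sd: float = 5.0, refractory_ms: float = 10.0
) -> TriggerSet:
    """Detect discharges as local |amplitude| maxima above a robust threshold.

    The threshold is ``threshold_sd`` times the MAD-based baseline SD, so
    large spikes do not inflate their own detection threshold. Peaks
    closer than ``refractory_ms`` collapse to the larger one, and each
    trigger is aligned to the extremum sample.
    """
    x = signal.samples
    sd = _robust_sd(x)
    if sd == 0.0:
        if np.ptp(x) == 0.0:
            logger.warning("detect_spikes: zero-variance signal; no triggers")
            return TriggerSet(np.empty(0), source=signal.source)
        sd = float(np.std(x)) or 1.0
    distance = max(1, round(refractory_ms / 1000.0 * signal.fs))
    peaks, _ = sps.find_peaks(np.abs(x), height=threshold_sd * sd, distance=distance)
    return TriggerSet(peaks / signal.fs, source=signal.source)


def _snippets(
    signal: EmgSignal, triggers: TriggerSet, window_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Window matrix (n_triggers x n_samples) for triggers fully inside the signal.

    Edge-clipped triggers are dropped rather than zero-padded, which
    would bias the average toward zero.
    """
    n_window = round(window_ms / 1000.0 * signal.fs)
    half_left = (n_window - 1) // 2
    idx = np.round(triggers.times * signal.fs).astype(int)
    keep = (idx - half_left >= 0) & (idx - half_left + n_window <= len(signal.samples))
    idx = idx[keep]
    starts = idx - half_left
    windows = signal.samples[starts[:, None] + np.arange(n_window)[None, :]] if len(idx) else np.empty((0, n_window))
    return windows, triggers.times[keep]


def _phase_features(snippet: np.ndarray, fs: float) -> tuple[float, int, float]:
    """(peak-to-peak, phase count, duration_ms) of a raw snippet."""
    p2p = float(np.ptp(snippet))
    n = len(snippet)
    edge = max(1, round(BASELINE_FRACTION * n))
    baseline = np.concatenate([snippet[:edge], snippet[-edge:]])
    thr = max(3.0 * float(np.std(baseline)), 0.05 * p2p)
    above = np.abs(snippet) > thr
    if not above.any():
        return p2p, 0, 0.0
    first, last = np.flatnonzero(above)[[0, -1]]
    duration_ms = (last - first) / fs * 1000.0
    phases = _count_lobes(snippet, thr)
    return p2p, phases, duration_ms


def _count_lobes(x: np.ndarray, threshold: float) -> int:
    """Number of supra-threshold excursions of alternating sign.

    The sign sequence of the supra-threshold samples is collapsed so
    that consecutive same-sign samples (and same-sign excursions briefly
    interrupted by noise) count as one lobe, while each baseline
    crossing inside or between excursions starts a new one.
    """
    supra = x[np.abs(x) > threshold]
    if supra.size == 0:
        return 0
    signs = np.sign(supra)
    return int(1 + np.count_nonzero(signs[1:] != signs[:-1]))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def _zero_lag_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def cluster_muaps(
    signal: EmgSignal,
    triggers: TriggerSet,
    window_ms: float = 75.0,
    ncc_threshold: float = 0.8,
    amplitude_tolerance: float = 1.5,
) -> list[TriggerSet]:
    """Partition triggers into putative motor units by snippet similarity.

    Greedy template grouping on (peak-to-peak amplitude, phase count,
    duration): a snippet joins an existing cluster when its zero-lag
    normalized cross-correlation with the cluster centroid is at least
    ``ncc_threshold`` and the amplitude ratio stays within
    ``amplitude_tolerance``; otherwise it seeds a new cluster. Amplitude
    is a grouping feature, so scaled copies of one shape form separate
    clusters.
    """
    if len(triggers) < 2:
        return [triggers]
    windows, times = _snippets(signal, triggers, window_ms)
    if len(windows) < 2:
        return [TriggerSet(times, source=triggers.source)]
    centroids: list[np.ndarray] = []
    members: list[list[int]] = []
    feats = [_phase_features(w, signal.fs) for w in windows]
    for i, w in enumerate(windows):
        p2p, phases, _dur = feats[i]
        assigned = False
        for c, centroid in enumerate(centroids):
            c_p2p = float(np.ptp(centroid))
            ratio = p2p / c_p2p if c_p2p else math.inf
            if (
                _zero_lag_ncc(w, centroid) >= ncc_threshold
                and 1.0 / amplitude_tolerance <= ratio <= amplitude_tolerance
            ):
                members[c].append(i)
                n = len(members[c])
                centroids[c] = centroid + (w - centroid) / n
                assigned = True
                break
        if not assigned:
            centroids.append(w.copy())
            members.append([i])
    return [
        TriggerSet(times[np.array(sorted(m))], source=triggers.source, unit_id=f"cluster{k}")
        for k, m in enumerate(members)
    ]


def spike_triggered_average(
    surface: EmgSignal,
    triggers: TriggerSet,
    window_ms: float = 75.0,
    min_windows: int = 100,
) -> MuapWaveform:
    """Average trigger-centered windows of the surface channel.

    Windows are centered on the trigger sample (half-window each side);
    triggers whose window leaves the recording are dropped. Raises when
    fewer than ``min_windows`` usable windows remain — the study accepted
    waveforms averaged from at least 100.
    """
    windows, _times = _snippets(surface, triggers, window_ms)
    if len(windows) < min_windows:
        raise ValueError(
            f"insufficient triggers: {len(windows)} usable windows, need {min_windows}"
        )
    mean = windows.mean(axis=0)
    waveform = MuapWaveform(
        mean,
        surface.fs,
        window_ms=window_ms,
        n_windows=len(windows),
        muscle=surface.muscle,
        unit_id=triggers.unit_id,
    )
    waveform.snr = waveform_snr(waveform)
    return waveform


def waveform_snr(waveform: MuapWaveform) -> float:
    """Peak-to-peak amplitude over the SD of the outer-10% baseline samples.

    The MUAP energy sits at the window center, so the first and last 10%
    of the 75 ms window approximate residual noise. A zero-noise baseline
    returns ``inf`` with a warning rather than raising.
    """
    x = waveform.samples
    edge = max(1, round(BASELINE_FRACTION * len(x)))
    baseline = np.concatenate([x[:edge], x[-edge:]])
    sd = float(np.std(baseline))
    if sd == 0.0:
        logger.warning("waveform_snr: zero baseline SD; returning inf sentinel")
        return math.inf
    return float(np.ptp(x)) / sd


def dedupe_waveforms(
    waveforms: list[MuapWaveform],
    similarity: float = 0.95,
    amplitude_tolerance: float = 2.0,
) -> list[MuapWaveform]:
    """Collapse near-duplicate waveforms, keeping the highest-SNR copy.

    Two waveforms are duplicates when their peak-aligned normalized
    cross-correlation reaches ``similarity`` and their peak-to-peak
    amplitudes differ by at most ``amplitude_tolerance``-fold. Grouping
    is transitive (union-find), mirroring the rule that a unit estimated
    from several recordings contributes one waveform.
    """
    n = len(waveforms)
    if n <= 1:
        return list(waveforms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def aligned_ncc(a: MuapWaveform, b: MuapWaveform) -> float:
        # best normalized cross-correlation over +/- a quarter window;
        # argmax-based alignment is fragile for multiphasic shapes whose
        # lobes have near-equal magnitude
        xa = a.samples - a.samples.mean()
        xb = b.samples - b.samples.mean()
        denom = np.linalg.norm(xa) * np.linalg.norm(xb)
        if denom == 0:
            return 0.0
        max_lag = len(xa) // 4
        full = sps.correlate(xa, xb, mode="full")
        center = len(xa) - 1
        window = full[center - max_lag : center + max_lag + 1]
        return float(window.max() / denom)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = waveforms[i], waveforms[j]
            p2p_i, p2p_j = a.peak_to_peak, b.peak_to_peak
            if p2p_i == 0 or p2p_j == 0:
                continue
            ratio = max(p2p_i, p2p_j) / min(p2p_i, p2p_j)
            if ratio <= amplitude_tolerance and aligned_ncc(a, b) >= similarity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    survivors = [
        max(idxs, key=lambda k: waveforms[k].snr) for idxs in groups.values()
    ]
    return [waveforms[k] for k in sorted(survivors)]


def _duration_bounds(
    x: np.ndarray, fs: float, onset_sd: float
) -> tuple[int, int, float]:
    """(first, last, threshold) of sustained supra-threshold excursion."""
    edge = max(1, round(BASELINE_FRACTION * len(x)))
    baseline = np.concatenate([x[:edge], x[-edge:]])
    # relative floor handles noise-free synthetic waveforms whose edge
    # baseline is numerically zero
    threshold = max(onset_sd * float(np.std(baseline)), 0.01 * float(np.max(np.abs(x), initial=0.0)))
    if threshold == 0.0:
        raise ValueError("duration undefined for an all-zero waveform")
    min_run = max(1, round(0.5e-3 * fs))
    runs = [(s, e) for s, e in _runs(np.abs(x) > threshold) if e - s >= min_run]
    if not runs:
        raise ValueError("no sustained supra-threshold excursion; duration undefined")
    return runs[0][0], runs[-1][1] - 1, threshold


def measure_duration(waveform: MuapWaveform, onset_sd: float = 3.0) -> float:
    """MUAP duration in ms, stored on the waveform.

    Time between the first and last samples where |amplitude| exceeds
    ``onset_sd`` times the edge-baseline SD, requiring each excursion to
    be sustained for at least 0.5 ms to ignore isolated noise samples.
    """
    first, last, _thr = _duration_bounds(waveform.samples, waveform.fs, onset_sd)
    duration_ms = (last - first) / waveform.fs * 1000.0
    waveform.duration_ms = duration_ms
    return duration_ms


def count_phases(waveform: MuapWaveform, onset_sd: float = 3.0) -> int:
    """Number of above-threshold lobes of alternating sign within the duration.

    Equivalently the number of baseline crossings between supra-threshold
    excursions plus one: a monophasic bump counts 1, a biphasic wave 2.
    """
    first, last, threshold = _duration_bounds(waveform.samples, waveform.fs, onset_sd)
    phases = _count_lobes(waveform.samples[first : last + 1], threshold)
    waveform.n_phases = phases
    return phases
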