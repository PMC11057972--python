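"""Interference-pattern EMG simulator and synthetic study cohorts.

Surface EMG is modeled the way phenomenological EMG simulators build it:
as the sum over active motor units of a unit-specific MUAP waveform
convolved with the unit's discharge train, plus additive white noise.
MUAP shapes come from the first two Hermite–Rodriguez functions,

    order 1:  h(t) = A * (t/λ) * exp(-(t/λ)²)
    order 2:  h(t) = A * (1 - 2 (t/λ)²) * exp(-(t/λ)²)

whose time scale λ (ms) sets both the waveform duration and, through
Fourier scaling, its median frequency (MDF ∝ 1/λ). Discharge trains are
Gaussian-interval renewal processes with a physiological 2 ms floor.

Per-muscle λ distributions are calibrated (``scripts/calibrate_lambdas.py``)
so that synthetic cohorts land near the observed group MDF means for the
four leg muscles — tibialis anterior (TA) lowest, then soleus (SO),
medial (MG) and lateral (LG) gastrocnemius — while contraction intensity
maps to proportionally more active units discharging slightly faster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import EmgSignal, MuapWaveform, SpikeTrain

logger = logging.getLogger("myospect")

#: Per-muscle Hermite–Rodriguez time-scale means (ms) for interference
#: cohorts, fitted by bisection against the spectral module so cohort
#: mean MDFs land on the observed group means (see
#: scripts/calibrate_lambdas.py). Values frozen from that fit.
INTERFERENCE_LAMBDA_MS = {
    "SO": 2.511,
    "MG": 2.442,
    "LG": 2.281,
    "TA": 3.179,
}
#: Group-mean interference MDF targets (Hz) used by the calibration fit,
#: intensity-pooled per muscle.
INTERFERENCE_MDF_TARGETS_HZ = {
    "SO": 124.0,
    "MG": 127.9,
    "LG": 136.9,
    "TA": 98.0,
}
#: Per-muscle λ means (ms) for isolated-MUAP populations, fitted against
#: the observed MUAP-waveform group MDF means.
MUAP_LAMBDA_MS = {
    "SO": 1.983,
    "MG": 2.084,
    "LG": 2.075,
    "TA": 2.827,
}
MUAP_MDF_TARGETS_HZ = {
    "SO": 147.562,
    "MG": 139.504,
    "LG": 140.924,
    "TA": 102.669,
}

#: Shortest physiologically admissible inter-spike interval, s.
ISI_FLOOR_S = 0.002

#: Coefficient of variation of the subject-level waveform time-scale
#: factor shared across a subject's muscles. Tissue filtering between the
#: fibers and the electrode (subcutaneous fat, skin) slows all of a
#: subject's surface MUAPs together, so most between-subject MDF spread
#: is common to the four muscles rather than muscle-specific.
SUBJECT_SHARED_CV = 0.10


@dataclass(frozen=True)
class MotorUnitModel:
    """One motor unit: waveform shape plus discharge statistics."""

    waveform_order: int = 1
    amplitude: float = 1.0
    lambda_ms: float = 2.0
    mean_rate: float = 10.0
    isi_cv: float = 0.15
    unit_id: str = "unspecified"

    def __post_init__(self):
        if self.waveform_order not in (1, 2):
            raise ValueError("waveform_order must be 1 or 2")
        if self.lambda_ms <= 0 or self.mean_rate <= 0:
            raise ValueError("lambda_ms and mean_rate must be positive")
        if not 0 <= self.isi_cv < 1:
            raise ValueError("isi_cv must lie in [0, 1)")


@dataclass(frozen=True)
class MuscleScenario:
    """Population parameters for one muscle's synthetic motor-unit pool.

    ``n_units`` is the active-unit count at the lowest (5% MVC)
    intensity; higher intensities recruit proportionally more units.
    λ is drawn per subject around ``lambda_mean_ms`` (between-subject
    spread ``lambda_sd_ms``) with a smaller within-subject jitter across
    units.
    """

    muscle: str
    n_units: int = 10
    lambda_mean_ms: float = 2.0
    lambda_sd_ms: float = 0.3
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.3
    rate_range: tuple[float, float] = (8.0, 12.0)
    isi_cv: float = 0.15
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be at least 1")
        if min(self.lambda_mean_ms, self.lambda_sd_ms, self.amplitude_mean) <= 0:
            raise ValueError("distribution parameters must be positive")


def default_scenarios() -> dict[str, MuscleScenario]:
    """Calibrated per-muscle scenarios for the four leg muscles."""
    # between-subject λ spread of ~11% yields MDF SDs in the observed
    # 15-25 Hz range at n = 20 subjects
    return {
        muscle: MuscleScenario(
            muscle=muscle,
            lambda_mean_ms=lam,
            lambda_sd_ms=0.11 * lam,
        )
        for muscle, lam in INTERFERENCE_LAMBDA_MS.items()
    }


def hermite_rodriguez(
    order: int,
    amplitude: float,
    lambda_ms: float,
    center_ms: float | None = None,
    window_ms: float = 75.0,
    fs: float = 20_000.0,
) -> MuapWaveform:
    """Sample a Hermite–Rodriguez MUAP model on a finite window.

    The waveform's effective support is |t - center| <= 4λ; a window that
    truncates it triggers a warning (the returned waveform is still the
    sampled restriction).
    """
    if lambda_ms <= 0:
        raise ValueError("lambda_ms must be positive")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = round(window_ms / 1000.0 * fs)
    t_ms = (np.arange(n) - (n - 1) / 2) / fs * 1000.0
    center = 0.0 if center_ms is None else center_ms
    if center - 4 * lambda_ms < t_ms[0] - 1e-9 or center + 4 * lambda_ms > t_ms[-1] + 1e-9:
        logger.warning(
            "hermite_rodriguez: support |t-%.3g| <= %.3g ms truncated by %g ms window",
            center,
            4 * lambda_ms,
            window_ms,
        )
    u = (t_ms - center) / lambda_ms
    envelope = np.exp(-(u**2))
    if order == 1:
        samples = amplitude * u * envelope
    else:
        samples = amplitude * (1.0 - 2.0 * u**2) * envelope
    return MuapWaveform(samples, fs, window_ms=n / fs * 1000.0)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_spike_train(
    mean_rate: float,
    isi_cv: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    unit_id: str = "unspecified",
) -> SpikeTrain:
    """Gaussian-interval renewal discharge train.

    Inter-spike intervals are N(1/rate, (cv/rate)²) truncated at a 2 ms
    floor; parameter combinations that would push a non-trivial mass of
    intervals to the floor (mean below the floor, or cv so large that
    truncation would distort the statistics) raise a parameter error.
    """
    if mean_rate <= 0 or duration <= 0:
        raise ValueError("mean_rate and duration must be positive")
    if not 0 <= isi_cv < 1:
        raise ValueError("isi_cv must lie in [0, 1)")
    mean_isi = 1.0 / mean_rate
    if mean_isi <= ISI_FLOOR_S:
        raise ValueError(
            f"mean ISI {mean_isi * 1e3:.2f} ms at/below the {ISI_FLOOR_S * 1e3:.0f} ms floor"
        )
    # more than ~4 SDs of headroom keeps the truncated mass negligible
    if isi_cv > 0 and (mean_isi - ISI_FLOOR_S) / (isi_cv * mean_isi) < 4.0:
        raise ValueError(
            f"isi_cv {isi_cv} implies substantial negative/sub-floor intervals "
            f"at rate {mean_rate}/s"
        )
    rng = _rng(seed)
    # draw in blocks until the train covers the duration
    n_expected = int(duration * mean_rate) + 1
    times: list[np.ndarray] = []
    start = rng.uniform(0.0, mean_isi)  # random phase so trains are unsynchronized
    cursor = start
    while cursor < duration:
        block = rng.normal(mean_isi, isi_cv * mean_isi, size=max(16, n_expected))
        block = np.maximum(block, ISI_FLOOR_S)
        cumulative = cursor + np.cumsum(block)
        times.append(cumulative[cumulative < duration])
        cursor = cumulative[-1]
    all_times = np.concatenate([[start]] + times) if start < duration else np.empty(0)
    all_times = all_times[all_times < duration]
    return SpikeTrain(all_times, duration=duration, unit_id=unit_id)


def _unit_kernel(unit: MotorUnitModel, fs: float) -> np.ndarray:
    """Sampled waveform over its effective support (±4λ, with margin).

    The length is forced odd so the model's center falls exactly on a
    sample and discharge instants map to integer sample indices.
    """
    support_ms = 8.5 * unit.lambda_ms
    n = max(3, round(support_ms / 1000.0 * fs)) | 1
    wf = hermite_rodriguez(
        unit.waveform_order, unit.amplitude, unit.lambda_ms, window_ms=n / fs * 1000.0, fs=fs
    )
    return wf.samples


def synthesize_interference(
    units: list[MotorUnitModel],
    duration: float = 30.0,
    fs: float = 20_000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    muscle: str = "unknown",
    subject: str = "unspecified",
    intensity: str = "unspecified",
) -> EmgSignal:
    """Sum of MUAP trains plus white Gaussian noise.

    Each unit's sampled waveform is added at every discharge instant of
    its renewal train (discharges whose waveform would leave the record
    are clipped at the edges). By Campbell's theorem the noise-free
    variance approaches ``sum_u rate_u * ∫ h_u(t)² dt``.
    """
    if not units:
        raise ValueError("at least one motor unit is required")
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    rng = _rng(seed)
    n = round(duration * fs)
    out = np.zeros(n)
    for unit in units:
        train = simulate_spike_train(unit.mean_rate, unit.isi_cv, duration, rng, unit.unit_id)
        kernel = _unit_kernel(unit, fs)
        half = (len(kernel) - 1) // 2
        centers = np.round(train.times * fs).astype(int)
        for c in centers:
            lo, hi = c - half, c - half + len(kernel)
            klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
            out[max(0, lo) : min(n, hi)] += kernel[klo:khi]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=n)
    return EmgSignal(
        out, fs, muscle=muscle, source="simulated", subject=subject, intensity=intensity
    )


def generate_protocol2_pair(
    unit: MotorUnitModel,
    duration: float = 30.0,
    fs: float = 20_000.0,
    surface_noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> tuple[EmgSignal, EmgSignal, SpikeTrain]:
    """Paired surface/intramuscular recording driven by one ground-truth train.

    Emulates the protocol in which a fine-wire channel supplies clean
    discharge triggers for spike-triggered averaging of the simultaneous
    surface channel: the intramuscular channel carries a short, sharp,
    high-SNR spike at each discharge; the surface channel carries the
    unit's (slower) surface waveform at the configured noise level.
    """
    rng = _rng(seed)
    truth = simulate_spike_train(unit.mean_rate, unit.isi_cv, duration, rng, unit.unit_id)
    n = round(duration * fs)

    def render(kernel: np.ndarray, noise_sd: float, source: str) -> EmgSignal:
        out = np.zeros(n)
        half = (len(kernel) - 1) // 2
        for c in np.round(truth.times * fs).astype(int):
            lo, hi = c - half, c - half + len(kernel)
            klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
            out[max(0, lo) : min(n, hi)] += kernel[klo:khi]
        if noise_sd > 0:
            out += rng.normal(0.0, noise_sd, size=n)
        return EmgSignal(out, fs, source=source, muscle="unknown")

    surface_kernel = _unit_kernel(unit, fs)
    # intramuscular spike: order-2 (dominant central peak, so the
    # absolute extremum lies unambiguously on the discharge instant),
    # 10x shorter than the surface waveform, peak-normalized for a
    # high-SNR channel (noise SD = peak / 20)
    intra_unit = MotorUnitModel(
        waveform_order=2,
        amplitude=1.0,
        lambda_ms=max(unit.lambda_ms / 10.0, 0.1),
        mean_rate=unit.mean_rate,
        isi_cv=unit.isi_cv,
    )
    intra_kernel = _unit_kernel(intra_unit, fs)
    intra_kernel = intra_kernel / np.max(np.abs(intra_kernel))
    surface = render(surface_kernel, surface_noise_sd, "simulated")
    intramuscular = render(intra_kernel, 1.0 / 20.0, "intramuscular")
    return surface, intramuscular, truth


def surface_template(
    unit: MotorUnitModel, window_ms: float = 75.0, fs: float = 20_000.0
) -> MuapWaveform:
    """The unit's surface waveform embedded in an averaging window.

    Exactly the kernel the simulators add at each discharge, zero-padded
    and centered the way :func:`~myospect.muap_estimation.spike_triggered_average`
    centers its windows — the ground-truth reference for validating
    waveform recovery.
    """
    n = round(window_ms / 1000.0 * fs)
    kernel = _unit_kernel(unit, fs)
    if len(kernel) > n:
        raise ValueError("window shorter than the waveform support")
    out = np.zeros(n)
    center = (n - 1) // 2
    half = (len(kernel) - 1) // 2
    out[center - half : center - half + len(kernel)] = kernel
    return MuapWaveform(out, fs, window_ms=n / fs * 1000.0)


def _intensity_label(pct: int) -> str:
    return f"{pct}%MVC"


def generate_study_cohort(
    scenarios: dict[str, MuscleScenario] | None = None,
    n_subjects: int = 20,
    intensities: tuple[int, ...] = (5, 10, 20),
    duration: float = 30.0,
    fs: float = 20_000.0,
    seed: int = 0,
) -> tuple[list[EmgSignal], pd.DataFrame]:
    """Synthetic cohort: one 30 s interference signal per (subject, muscle, intensity).

    Contraction intensity is realized as recruitment plus rate coding:
    the active-unit count scales with %MVC relative to the 5% baseline
    and mean discharge rates ramp linearly across the scenario's
    ``rate_range``. Per-subject waveform time scales are drawn around the
    calibrated per-muscle λ means, so the cohort reproduces the observed
    between-muscle MDF ordering (TA < SO < MG < LG) with realistic
    between-subject spread.

    Returns the signals and a truth table of generating parameters.
    """
    scenarios = scenarios or default_scenarios()
    base_pct = min(intensities)
    signals: list[EmgSignal] = []
    rows: list[dict] = []
    root_ss = np.random.SeedSequence(seed)
    muscle_list = sorted(scenarios)
    for s_idx in range(n_subjects):
        # subject-level time-scale factor shared across muscles and
        # intensities (common tissue-filtering effect)
        subject_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root_ss.entropy, spawn_key=(s_idx, 9999))
        )
        subject_factor = max(subject_rng.normal(1.0, SUBJECT_SHARED_CV), 0.5)
        for m_idx, muscle in enumerate(muscle_list):
            scenario = scenarios[muscle]
            # the muscle-specific residual spread is what remains of the
            # scenario's total between-subject SD after the shared factor
            total_cv = scenario.lambda_sd_ms / scenario.lambda_mean_ms
            residual_cv = math.sqrt(max(total_cv**2 - SUBJECT_SHARED_CV**2, 1e-6))
            for i_idx, pct in enumerate(intensities):
                child = np.random.SeedSequence(
                    entropy=root_ss.entropy, spawn_key=(s_idx, m_idx, i_idx)
                )
                rng = np.random.default_rng(child)
                subject_lambda = max(
                    scenario.lambda_mean_ms
                    * subject_factor
                    * rng.normal(1.0, residual_cv),
                    0.25 * scenario.lambda_mean_ms,
                )
                n_units = max(1, round(scenario.n_units * pct / base_pct))
                lo, hi = scenario.rate_range
                span = max(intensities) - base_pct
                rate_mean = lo + (hi - lo) * (pct - base_pct) / span if span else lo
                units = []
                for u in range(n_units):
                    lam = max(
                        rng.normal(subject_lambda, 0.05 * scenario.lambda_mean_ms),
                        0.2 * scenario.lambda_mean_ms,
                    )
                    units.append(
                        MotorUnitModel(
                            waveform_order=int(rng.integers(1, 3)),
                            amplitude=float(
                                rng.lognormal(
                                    math.log(scenario.amplitude_mean),
                                    scenario.amplitude_sd,
                                )
                            ),
                            lambda_ms=lam,
                            mean_rate=float(rng.uniform(0.9 * rate_mean, 1.1 * rate_mean)),
                            isi_cv=scenario.isi_cv,
                            unit_id=f"s{s_idx}_{muscle}_{pct}_u{u}",
                        )
                    )
                signal = synthesize_interference(
                    units,
                    duration=duration,
                    fs=fs,
                    noise_sd=scenario.noise_sd,
                    seed=rng,
                    muscle=muscle,
                    subject=f"S{s_idx:02d}",
                    intensity=_intensity_label(pct),
                )
                signals.append(signal)
                rows.append(
                    {
                        "subject": f"S{s_idx:02d}",
                        "muscle": muscle,
                        "intensity": _intensity_label(pct),
                        "n_units": n_units,
                        "subject_lambda_ms": subject_lambda,
                        "mean_rate_hz": rate_mean,
                        "noise_sd": scenario.noise_sd,
                        "target_mdf_hz": INTERFERENCE_MDF_TARGETS_HZ.get(muscle, np.nan),
                    }
                )
    return signals, pd.DataFrame(rows)


def generate_muap_population(
    muscle: str,
    n_waveforms: int = 50,
    fs: float = 20_000.0,
    window_ms: float = 75.0,
    baseline_noise_sd: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> list[MuapWaveform]:
    """Synthetic per-muscle surface MUAP population.

    λ is drawn around the calibrated per-muscle mean so population MDFs
    center near the observed group means (TA lower than SO/MG/LG, with
    correspondingly longer TA durations). The waveform orders alternate
    deterministically (a balanced biphasic/triphasic mixture), keeping
    the population's order composition fixed at small sample sizes. A
    small baseline noise keeps SNR finite, as in averaged real
    waveforms.
    """
    if muscle not in MUAP_LAMBDA_MS:
        raise ValueError(f"unknown muscle {muscle!r}")
    rng = _rng(seed)
    lam_mean = MUAP_LAMBDA_MS[muscle]
    out = []
    for k in range(n_waveforms):
        lam = max(rng.normal(lam_mean, 0.11 * lam_mean), 0.3 * lam_mean)
        order = 1 + (k % 2)
        amplitude = float(rng.lognormal(0.0, 0.3))
        wf = hermite_rodriguez(order, amplitude, lam, window_ms=window_ms, fs=fs)
        if baseline_noise_sd > 0:
            wf.samples = wf.samples + rng.normal(0.0, baseline_noise_sd * amplitude, len(wf.samples))
        wf.muscle = muscle
        wf.n_windows = 100
        wf.unit_id = f"{muscle}_synth{k}"
        from .muap_estimation import waveform_snr  # local import avoids a cycle

        wf.snr = waveform_snr(wf)
        out.append(wf)
    return out
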