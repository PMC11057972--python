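"""Domain types, file I/O, deposit loading, and configuration.

The in-memory containers mirror the objects the analysis manipulates: a
uniformly sampled EMG channel (:class:`EmgSignal`), an averaged surface
MUAP (:class:`MuapWaveform`), a one-sided periodogram
(:class:`PowerSpectrum`), a motor-unit discharge train
(:class:`SpikeTrain`), and the per-subject median-frequency table that
feeds the statistical layer (:class:`CohortTable`).

Signals travel through three plain formats: CSV (a single ``amplitude``
column or ``time_s,amplitude`` pairs), WAV (PCM 16/32-bit or float), and
HDF5 (dataset ``samples`` with an ``fs_hz`` attribute).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger("myospect")

MUSCLES = ("SO", "MG", "LG", "TA")
INTENSITIES = ("minimal", "weak", "5%MVC", "10%MVC", "20%MVC")

#: Acquisition sampling rate of the study recordings, Hz.
DEFAULT_FS = 20_000.0


class ConfigurationError(ValueError):
    """Missing or contradictory acquisition metadata / analysis settings."""


class SignalTooShortError(ValueError):
    """A signal does not cover the requested operation."""


class DegenerateSpectrumError(ValueError):
    """The input carries no usable spectral content (empty or constant)."""


class DepositError(FileNotFoundError):
    """The deposit directory holds no recognizable content."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class EmgSignal:
    """A uniformly sampled single-channel myoelectric time series.

    Parameters
    ----------
    samples
        Amplitudes in arbitrary units (typically mV).
    fs
        Sampling rate in Hz; the study acquired at 20 kHz.
    muscle
        One of ``SO``, ``MG``, ``LG``, ``TA`` or ``"unknown"``.
    source
        ``surface``, ``intramuscular`` or ``simulated``.
    subject
        Free-form participant/replicate identifier.
    intensity
        Contraction label (e.g. ``5%MVC``) or ``"unspecified"``.
    """

    samples: np.ndarray
    fs: float
    muscle: str = "unknown"
    source: str = "surface"
    subject: str = "unspecified"
    intensity: str = "unspecified"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "EmgSignal":
        """Copy of this signal with new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class MuapWaveform:
    """An averaged surface MUAP spanning a fixed window (default 75 ms).

    ``n_windows`` records how many trigger-centered windows entered the
    average; accepted waveforms use at least 100. ``snr`` is the
    peak-to-peak amplitude over the baseline noise SD estimated from the
    window edges. ``duration_ms`` and ``n_phases`` are filled by the
    morphological measurements when available.
    """

    samples: np.ndarray
    fs: float
    window_ms: float = 75.0
    n_windows: int | None = None
    muscle: str = "unknown"
    snr: float = math.inf
    duration_ms: float | None = None
    n_phases: int | None = None
    unit_id: str = "unspecified"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        expected = round(self.window_ms / 1000.0 * self.fs)
        if len(self.samples) != expected:
            raise ValueError(
                f"waveform has {len(self.samples)} samples; window of "
                f"{self.window_ms} ms at {self.fs} Hz requires {expected}"
            )
        if self.snr < 0:
            raise ValueError("snr must be non-negative")

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms, window centered at 0."""
        n = len(self.samples)
        return (np.arange(n) - (n - 1) / 2) / self.fs * 1000.0

    @property
    def peak_to_peak(self) -> float:
        return float(np.ptp(self.samples))


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram bins with uniform frequency spacing.

    ``power[i]`` is the power carried by the bin at ``freqs[i]`` in
    signal-units squared, so ``power.sum()`` equals the mean square of the
    (mean-removed) source segment by Parseval's theorem.
    """

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if freqs.size >= 2:
            df = np.diff(freqs)
            if not np.allclose(df, df[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frequency bins must be uniformly spaced")
        if np.any(power < -1e-12 * max(power.max(initial=0.0), 1.0)):
            raise ValueError("power bins must be non-negative")

    @property
    def M(self) -> int:
        """Number of frequency bins."""
        return len(self.freqs)

    @property
    def delta_f(self) -> float:
        """Bin spacing in Hz."""
        if self.M < 2:
            raise ValueError("spacing undefined for fewer than two bins")
        return float(self.freqs[1] - self.freqs[0])

    def band(self, low: float, high: float) -> "PowerSpectrum":
        """Restrict to bins with ``low <= f <= high``."""
        mask = (self.freqs >= low) & (self.freqs <= high)
        return PowerSpectrum(self.freqs[mask], self.power[mask])


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted motor-unit discharge instants over a recording of ``duration`` s."""

    times: np.ndarray
    duration: float
    unit_id: str = "unspecified"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("discharge times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("discharge times must lie in [0, duration)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def mean_rate(self) -> float:
        return len(self.times) / self.duration


COHORT_COLUMNS = (
    "subject",
    "muscle",
    "intensity",
    "mdf_full",
    "mdf_first_half",
    "mdf_second_half",
)


@dataclass
class CohortTable:
    """Per-(subject, muscle, intensity) MDF records for the statistical layer."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(COHORT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        keys = self.data[["subject", "muscle", "intensity"]]
        if keys.duplicated().any():
            raise ValueError("one row per (subject, muscle, intensity) required")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings of the study protocol.

    Defaults encode the published conditioning and segmentation choices:
    a 20–1000 Hz band-pass, notch filters on the 60 Hz mains line and the
    odd harmonics that fall inside the band, removal of the first and
    last 5 s of each trial, a 30 s interference segment split into 15 s
    halves for the fatigue comparison, and 75 ms spike-triggered windows
    with at least 100 triggers per accepted MUAP.
    """

    bandpass_low: float = 20.0
    bandpass_high: float = 1000.0
    notch_freqs: tuple[float, ...] = (60.0, 180.0, 300.0, 420.0, 540.0, 660.0, 780.0, 900.0)
    edge_trim_s: float = 5.0
    interference_segment_s: float = 30.0
    sta_window_ms: float = 75.0
    sta_min_windows: int = 100
    half_split_s: float = 15.0
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ConfigurationError("require 0 < bandpass_low < bandpass_high")
        if 2 * self.half_split_s != self.interference_segment_s:
            raise ConfigurationError("half_split_s must be half the interference segment")

    def validate_for_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.bandpass_high >= nyq:
            raise ConfigurationError(
                f"band-pass upper cutoff {self.bandpass_high} Hz >= Nyquist {nyq} Hz"
            )
        bad = [f for f in self.notch_freqs if f >= nyq]
        if bad:
            raise ConfigurationError(f"notch frequencies at/above Nyquist: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "notch_freqs" in raw:
            raw["notch_freqs"] = tuple(float(f) for f in raw["notch_freqs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        payload["notch_freqs"] = list(payload["notch_freqs"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path

    def log_effective(self) -> None:
        for f in fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


# ---------------------------------------------------------------------------
# signal file I/O


def _metadata_kwargs(metadata: dict | None) -> dict:
    metadata = metadata or {}
    out = {}
    for key in ("muscle", "source", "subject", "intensity"):
        if key in metadata:
            out[key] = str(metadata[key])
    return out


def _read_csv_signal(path: Path, fs_hint: float | None, metadata: dict | None) -> EmgSignal:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"could not parse {path} as CSV: {exc}") from exc
    # headerless single column of numbers comes back with the first value as name
    if frame.shape[1] == 1 and frame.columns[0] not in ("amplitude",):
        try:
            float(frame.columns[0])
        except ValueError:
            pass
        else:
            frame = pd.read_csv(path, header=None, names=["amplitude"])
    if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
        raise ValueError(f"non-numeric content in {path}")
    if frame.shape[1] == 1:
        samples = frame.iloc[:, 0].to_numpy(dtype=float)
        if fs_hint is None:
            raise ConfigurationError(
                f"{path}: single-column CSV carries no sampling rate; pass fs_hint"
            )
        fs = float(fs_hint)
    elif frame.shape[1] == 2:
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        samples = frame.iloc[:, 1].to_numpy(dtype=float)
        steps = np.diff(t)
        if len(steps) == 0 or np.any(steps <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        fs = 1.0 / float(np.median(steps))
        # the full span averages out per-step quantization; snap to integer
        # rates (the practical case) within float tolerance
        span_fs = (len(t) - 1) / float(t[-1] - t[0])
        if math.isclose(span_fs, fs, rel_tol=1e-6):
            fs = span_fs
        if math.isclose(fs, round(fs), rel_tol=1e-6):
            fs = float(round(fs))
        if fs_hint is not None and not math.isclose(fs, fs_hint, rel_tol=1e-3):
            raise ConfigurationError(
                f"{path}: inferred fs {fs:.6g} Hz contradicts fs_hint {fs_hint:.6g} Hz"
            )
    else:
        raise ValueError(f"{path}: expected 1 or 2 CSV columns, found {frame.shape[1]}")
    return EmgSignal(samples, fs, **_metadata_kwargs(metadata))


def _read_wav_signal(path: Path, fs_hint: float | None, metadata: dict | None) -> EmgSignal:
    fs, data = wavfile.read(path)
    if fs_hint is not None and not math.isclose(fs, fs_hint, rel_tol=1e-6):
        raise ConfigurationError(
            f"{path}: WAV header fs {fs} Hz contradicts fs_hint {fs_hint} Hz"
        )
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return EmgSignal(np.asarray(data, dtype=float), float(fs), **_metadata_kwargs(metadata))


def _read_hdf5_signal(path: Path, fs_hint: float | None, metadata: dict | None) -> EmgSignal:
    with h5py.File(path, "r") as fh:
        if "samples" not in fh:
            raise ValueError(f"{path}: HDF5 file lacks a 'samples' dataset")
        dset = fh["samples"]
        samples = np.asarray(dset[...], dtype=float)
        fs = dset.attrs.get("fs_hz", fh.attrs.get("fs_hz"))
        attrs = dict(dset.attrs)
        attrs.update(fh.attrs)
    if fs is None:
        if fs_hint is None:
            raise ConfigurationError(f"{path}: no fs_hz attribute and no fs_hint given")
        fs = fs_hint
    elif fs_hint is not None and not math.isclose(float(fs), fs_hint, rel_tol=1e-6):
        raise ConfigurationError(
            f"{path}: stored fs {fs} Hz contradicts fs_hint {fs_hint} Hz"
        )
    merged = {
        k: (v.decode() if isinstance(v, bytes) else str(v))
        for k, v in attrs.items()
        if k in ("muscle", "source", "subject", "intensity")
    }
    merged.update(_metadata_kwargs(metadata))
    return EmgSignal(samples, float(fs), **merged)


_READERS = {
    ".csv": _read_csv_signal,
    ".txt": _read_csv_signal,
    ".wav": _read_wav_signal,
    ".h5": _read_hdf5_signal,
    ".hdf5": _read_hdf5_signal,
}


def read_signal(
    path: str | Path,
    fs_hint: float | None = None,
    metadata: dict | None = None,
) -> EmgSignal:
    """Read an EMG channel from CSV/TXT, WAV, or HDF5.

    ``fs_hint`` supplies the sampling rate for formats that cannot carry
    one (single-column CSV); when the file declares a rate, a
    contradictory hint raises :class:`ConfigurationError` rather than
    being silently overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise ValueError(f"unsupported signal format: {path.suffix!r}")
    return reader(path, None if fs_hint is None else float(fs_hint), metadata)


def write_signal(signal: EmgSignal, path: str | Path, format: str | None = None) -> Path:
    """Write a signal as CSV (``time_s,amplitude``), WAV (float32), or HDF5."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("csv", "txt"):
        t = np.arange(len(signal.samples)) / signal.fs
        pd.DataFrame({"time_s": t, "amplitude": signal.samples}).to_csv(path, index=False)
    elif fmt == "wav":
        peak = float(np.max(np.abs(signal.samples), initial=0.0))
        scaled = signal.samples / peak if peak > 0 else signal.samples
        wavfile.write(path, int(round(signal.fs)), (scaled * 32767).astype(np.int16))
    elif fmt in ("h5", "hdf5"):
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("samples", data=signal.samples)
            dset.attrs["fs_hz"] = signal.fs
            for key in ("muscle", "source", "subject", "intensity"):
                dset.attrs[key] = getattr(signal, key)
    else:
        raise ValueError(f"unsupported output format: {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# deposit loading


def _muscle_from_name(*names: str) -> str | None:
    for name in names:
        upper = name.upper()
        for muscle in MUSCLES:
            # token match so e.g. "so_unit3.csv" or "SO/unit3.csv" hits
            tokens = upper.replace("-", "_").replace(".", "_").split("_")
            if muscle in tokens or upper == muscle:
                return muscle
    return None


def _load_deposit_waveform(path: Path, muscle: str, fs: float) -> MuapWaveform:
    if path.suffix.lower() in (".h5", ".hdf5"):
        sig = _read_hdf5_signal(path, fs, None)
        samples, fs = sig.samples, sig.fs
    else:
        frame = pd.read_csv(path)
        col = "amplitude" if "amplitude" in frame.columns else frame.columns[-1]
        samples = frame[col].to_numpy(dtype=float)
    window_ms = len(samples) / fs * 1000.0
    return MuapWaveform(samples, fs, window_ms=window_ms, muscle=muscle, unit_id=path.stem)


def load_deposit(
    root: str | Path, fs_hint: float = DEFAULT_FS
) -> tuple[list[MuapWaveform], list[EmgSignal]]:
    """Load a local copy of the study's open-data deposit.

    Expected layout (auto-detected, case-insensitive muscle labels taken
    from file or parent-directory names):

    - ``<root>/muaps/**``: one file per surface MUAP waveform, CSV
      (``amplitude`` column) or HDF5 (``samples`` + ``fs_hz``).
    - ``<root>/interference/**``: 30 s (or longer) interference-pattern
      recordings in any :func:`read_signal` format; intensity labels such
      as ``5%MVC``/``mvc05`` are picked up from file names when present.

    Files with no recognizable muscle label are skipped with a warning.
    Returns the waveforms and signals, and logs per-muscle counts.
    """
    root = Path(root)
    if not root.is_dir():
        raise DepositError(f"deposit root {root} is not a directory")
    files = sorted(p for p in root.rglob("*") if p.is_file())
    waveforms: list[MuapWaveform] = []
    signals: list[EmgSignal] = []
    for path in files:
        if path.suffix.lower() not in (".csv", ".txt", ".wav", ".h5", ".hdf5"):
            continue
        muscle = _muscle_from_name(path.stem, *(parent.name for parent in path.parents))
        if muscle is None:
            logger.warning("deposit: no muscle label for %s; skipped", path)
            continue
        kind_hint = "/".join(part.lower() for part in path.parts)
        try:
            if "muap" in kind_hint:
                waveforms.append(_load_deposit_waveform(path, muscle, fs_hint))
            else:
                intensity = "unspecified"
                lowered = path.stem.lower()
                for pct in ("5", "10", "20"):
                    if f"{pct}%" in lowered or f"mvc{pct.zfill(2)}" in lowered or f"{pct}mvc" in lowered:
                        intensity = f"{pct}%MVC"
                        break
                sig = read_signal(path, fs_hint=None, metadata={"muscle": muscle, "intensity": intensity})
                signals.append(sig)
        except ConfigurationError:
            # retry with the acquisition default once the file carries no rate
            if "muap" not in kind_hint:
                sig = read_signal(
                    path, fs_hint=fs_hint, metadata={"muscle": muscle}
                )
                signals.append(sig)
        except Exception as exc:  # noqa: BLE001 - skip unreadable entries
            logger.warning("deposit: could not load %s (%s); skipped", path, exc)
    if not waveforms and not signals:
        raise DepositError(f"no deposit content found under {root}")
    counts = {m: sum(w.muscle == m for w in waveforms) for m in MUSCLES}
    logger.info(
        "deposit: %d MUAP waveforms (%s), %d interference signals",
        len(waveforms),
        ", ".join(f"{m} {n}" for m, n in counts.items()),
        len(signals),
    )
    return waveforms, signals
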