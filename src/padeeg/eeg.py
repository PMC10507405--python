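"""Band spectral-energy features from single-channel EEG.

A recording is cut into tapered analysis windows; within each window the
energy of a frequency band is the sum of squared rFFT magnitudes over the
bins falling in that band. Per-recording features are the arithmetic means
of the per-window band energies — the summary used when a whole monitoring
period is reduced to one feature vector per subject.

Energy units are device-relative (squared amplitude units); downstream
classifiers standardize the features, so no absolute calibration is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .emotions import ValidationError

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "BandEnergy",
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "bandpass_filter",
    "reject_artifacts",
    "band_energies",
    "mean_band_energy",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Conventional clinical band edges in Hz, [low, high).
DEFAULT_BAND_EDGES: Mapping[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class EEGRecording:
    """Single-channel EEG time series (amplitudes in device units)."""

    visitor_id: str
    sampling_rate: float
    samples: np.ndarray
    channel_label: str = "Fp1"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class BandDefinition:
    """Named, disjoint, ordered frequency bands with [low, high) edges in Hz."""

    edges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, (low, high) in self.edges.items():
            if not 0.0 < low < high:
                raise ValidationError(f"band {name!r}: need 0 < low < high")
            if low < prev_high:
                raise ValidationError(f"band {name!r} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.edges)

    @property
    def max_edge(self) -> float:
        return max(high for _, high in self.edges.values())


DEFAULT_BANDS = BandDefinition()


@dataclass(frozen=True)
class BandEnergy:
    """Spectral energy per band for one window or one recording."""

    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} energy must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, b) for b in BAND_NAMES])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BandEnergy":
        return cls(**dict(zip(BAND_NAMES, map(float, values))))


def bandpass_filter(
    rec: EEGRecording, low: float, high: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    nyq = rec.sampling_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValidationError(
            f"band [{low}, {high}] Hz outside (0, Nyquist={nyq}) Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return EEGRecording(rec.visitor_id, rec.sampling_rate, filtered,
                        rec.channel_label)


def _window_slices(n_samples: int, win: int, hop: int) -> Iterator[slice]:
    start = 0
    while start + win <= n_samples:
        yield slice(start, start + win)
        start += hop


def reject_artifacts(
    rec: EEGRecording, amplitude_threshold: float, window_s: float = 1.0
) -> tuple[EEGRecording, np.ndarray]:
    """Drop windows whose peak |amplitude| exceeds the threshold.

    The recording is cut into consecutive non-overlapping windows; clean
    windows are concatenated into the returned recording. The boolean mask
    marks rejected windows (True = rejected).
    """
    if amplitude_threshold <= 0:
        raise ValidationError("amplitude_threshold must be positive")
    win = int(round(window_s * rec.sampling_rate))
    if win < 1 or rec.samples.size < win:
        raise ValidationError("recording shorter than one rejection window")
    slices = list(_window_slices(rec.samples.size, win, win))
    mask = np.array(
        [np.max(np.abs(rec.samples[s])) > amplitude_threshold for s in slices]
    )
    if mask.all():
        raise ValidationError("no clean data: every window exceeded the threshold")
    clean = np.concatenate(
        [rec.samples[s] for s, bad in zip(slices, mask) if not bad]
    )
    return EEGRecording(rec.visitor_id, rec.sampling_rate, clean,
                        rec.channel_label), mask


def band_energies(
    rec: EEGRecording,
    bands: BandDefinition = DEFAULT_BANDS,
    window_s: float = 1.0,
    overlap: float = 0.5,
    taper: str = "hann",
) -> list[BandEnergy]:
    """Per-window band energies via tapered short-time Fourier analysis.

    The recording's DC offset (its overall mean) is removed once; each
    analysis window is then multiplied by the taper and transformed with an
    rFFT, and the energy of band b is sum(|X(f)|^2) over bins with
    low <= f < high. Frequencies are resolved to 1/window_s Hz, so the
    default 1 s window gives 1 Hz bins. The offset is removed globally
    rather than per window because per-window demeaning biases the lowest
    band down for broadband signals.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must lie in [0, 1)")
    if rec.sampling_rate < 2.0 * bands.max_edge:
        raise ValidationError(
            f"sampling rate {rec.sampling_rate} Hz under-samples the "
            f"{bands.max_edge} Hz band edge"
        )
    win = int(round(window_s * rec.sampling_rate))
    if win < 2:
        raise ValidationError("window_s * sampling_rate must be at least 2")
    if rec.samples.size < win:
        raise ValidationError(
            f"recording of {rec.samples.size} samples shorter than one "
            f"{win}-sample window"
        )
    hop = max(1, int(round(win * (1.0 - overlap))))
    w = sps.get_window(taper, win, fftbins=True)
    freqs = np.fft.rfftfreq(win, d=1.0 / rec.sampling_rate)

    samples = rec.samples - rec.samples.mean()
    out: list[BandEnergy] = []
    for s in _window_slices(samples.size, win, hop):
        seg = samples[s]
        spec = np.abs(np.fft.rfft(seg * w)) ** 2
        energies = {
            name: float(spec[(freqs >= low) & (freqs < high)].sum())
            for name, (low, high) in bands.edges.items()
        }
        out.append(BandEnergy(**energies))
    return out


def mean_band_energy(per_window: Sequence[BandEnergy]) -> BandEnergy:
    """Arithmetic mean of band energies across retained windows."""
    if not per_window:
        raise ValidationError("no windows to average")
    stacked = np.stack([be.as_array() for be in per_window])
    return BandEnergy.from_array(stacked.mean(axis=0))
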