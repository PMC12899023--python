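"""FFT amplitude spectra and harmonic feature vectors for SSVEP decoding.

One-second windows at 256 Hz give a 1 Hz frequency resolution, so the
stimulation frequencies (7, 8, 9 Hz) and their second and third
harmonics fall exactly on DFT bins — no taper or detrending is applied
because integer-cycle sinusoids leak nothing by construction.

Amplitude scaling is the one-sided 2/N convention: a unit-amplitude
sinusoid on a bin reads 1.0, DC reads its own level.  The scale cancels
in classification but is fixed so spectra are physically interpretable
(µV per component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals_io import EpochSet

__all__ = [
    "AmplitudeSpectrum",
    "FeatureMatrix",
    "amplitude_spectrum",
    "harmonic_frequency_set",
    "extract_harmonic_features",
]


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum: freqs in Hz, amps in µV."""

    freqs: np.ndarray
    amps: np.ndarray

    def power(self) -> np.ndarray:
        """Spectral power per bin (squared one-sided amplitude)."""
        return self.amps**2

    def amplitude_at(self, f: float) -> float:
        idx = np.argmin(np.abs(self.freqs - f))
        if abs(self.freqs[idx] - f) > 1e-6:
            raise ValueError(f"{f} Hz does not align to a spectrum bin")
        return float(self.amps[idx])


@dataclass
class FeatureMatrix:
    """Per-epoch harmonic amplitudes, channel-major column order."""

    values: np.ndarray  # (n_epochs, n_features)
    feature_names: list[tuple[str, float]]  # (channel, frequency Hz)
    labels: np.ndarray
    subject_ids: np.ndarray

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def header(self) -> list[str]:
        return [f"{ch}@{f:g}Hz" for ch, f in self.feature_names]


def amplitude_spectrum(window: np.ndarray, fs: float) -> AmplitudeSpectrum:
    """One-sided FFT amplitude spectrum of a single window (no taper).

    amp(0) = |F0|/N, amp(k) = 2|Fk|/N for interior bins, amp(N/2) =
    |F_{N/2}|/N for even N.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be a 1-D vector of length >= 2")
    n = window.size
    spec = np.abs(np.fft.rfft(window)) / n
    amps = spec.copy()
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] = spec[-1]  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps)


def harmonic_frequency_set(
    stim_freqs: list[float], n_harmonics: int = 3
) -> list[float]:
    """Sorted unique harmonics {h*f : f in stim_freqs, h = 1..n_harmonics}."""
    return sorted({float(h * f) for f in stim_freqs for h in range(1, n_harmonics + 1)})


def extract_harmonic_features(
    epochs: EpochSet,
    stim_freqs: list[float] = (7.0, 8.0, 9.0),
    n_harmonics: int = 3,
    channels: list[str] | None = None,
) -> FeatureMatrix:
    """Concatenate FFT amplitudes at stimulation harmonics, channel-major.

    Defaults reproduce the 27-feature setup: 3 occipital channels x the
    9 frequencies [7, 8, 9, 14, 16, 18, 21, 24, 27] Hz.
    """
    if channels is None:
        channels = epochs.channels_with_role("target") or list(epochs.channel_labels)
    freq_set = harmonic_frequency_set(list(stim_freqs), n_harmonics)
    n = epochs.n_window_samples
    resolution = epochs.fs / n
    bins = []
    for f in freq_set:
        if f >= epochs.fs / 2:
            raise ValueError(f"requested frequency {f} Hz >= Nyquist")
        k = f / resolution
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"{f} Hz does not align to the {resolution:g} Hz bin grid"
            )
        bins.append(int(round(k)))
    ch_idx = [epochs.channel_index(c) for c in channels]

    # vectorized over epochs and channels; same scaling as amplitude_spectrum
    spec = np.abs(np.fft.rfft(epochs.epochs[:, ch_idx, :], axis=-1)) / n
    spec[..., 1:] *= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    values = spec[:, :, bins].reshape(epochs.n_epochs, -1)
    names = [(ch, f) for ch in channels for f in freq_set]
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=epochs.labels.copy(),
        subject_ids=epochs.subject_ids.copy(),
    )
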