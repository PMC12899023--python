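"""Training-free SSVEP classifiers: CCA against sinusoidal references, and
its filter-bank extension (FBCCA).

For each candidate stimulus frequency f a reference matrix of sines and
cosines at f, 2f, 3f is built; the first canonical correlation between
the multichannel occipital window and each reference set is computed and
the frequency with the largest coefficient wins.  Using both sine and
cosine columns makes the decision invariant to the unknown phase of the
SSVEP response.  FBCCA repeats this per band of a zero-phase Butterworth
filter bank and combines the per-band coefficients with decreasing
weights w(n) = n^-1.25 + 0.25, reflecting that low sub-bands (which
contain the fundamental) carry most of the information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .signals_io import EpochSet

__all__ = [
    "FilterBankSpec",
    "make_references",
    "canonical_correlation",
    "cca_classify",
    "fbcca_classify",
    "default_fbcca_weights",
]


def default_fbcca_weights(n_bands: int) -> np.ndarray:
    """Standard FBCCA sub-band weights w(n) = n^-1.25 + 0.25, n = 1..n_bands."""
    n = np.arange(1, n_bands + 1, dtype=float)
    return n**-1.25 + 0.25


@dataclass
class FilterBankSpec:
    """Zero-phase Butterworth filter bank for FBCCA."""

    bands: list[tuple[float, float]] = field(
        default_factory=lambda: [(6, 90), (14, 90), (22, 90), (30, 90), (38, 90)]
    )
    order: int = 4
    zero_phase: bool = True
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = default_fbcca_weights(len(self.bands))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.bands):
            raise ValueError("one weight per band required")
        if np.any(self.weights <= 0) or np.any(np.diff(self.weights) >= 0):
            raise ValueError("weights must be positive and strictly decreasing")

    def sos(self, fs: float) -> list[np.ndarray]:
        out = []
        for low, high in self.bands:
            if high >= fs / 2:
                raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
            out.append(
                signal.butter(
                    max(self.order // 2, 1), [low, high], btype="bandpass",
                    fs=fs, output="sos",
                )
            )
        return out


def make_references(
    f: float, n_harmonics: int = 3, fs: float = 256.0, n_samples: int = 256
) -> np.ndarray:
    """Sin/cos reference matrix (n_samples, 2*n_harmonics) at f, 2f, ... .

    Column order: sin(h=1), cos(h=1), sin(h=2), ...  Columns are exactly
    orthogonal whenever the window spans integer cycles of every
    harmonic.
    """
    if n_harmonics * f >= fs / 2:
        raise ValueError("top harmonic at or above Nyquist")
    t = np.arange(n_samples) / fs
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * f * t))
        cols.append(np.cos(2 * np.pi * h * f * t))
    return np.column_stack(cols)


def canonical_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """First canonical correlation between column sets A (n,p) and B (n,q).

    Columns are centered internally; orthonormal bases are obtained by
    SVD so rank-deficient inputs are handled gracefully.  Returns NaN
    when either side has no variance at all (degenerate input).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("A and B must share their row count")
    if A.shape[0] <= max(A.shape[1], B.shape[1]):
        raise ValueError("need more rows than columns on either side")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Ua = linalg.orth(Ac)
    Ub = linalg.orth(Bc)
    if Ua.size == 0 or Ub.size == 0:
        return float("nan")
    s = linalg.svd(Ua.T @ Ub, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def _epoch_matrix(epochs: EpochSet, channels: list[str] | None) -> np.ndarray:
    if channels is None:
        channels = epochs.channels_with_role("target") or list(epochs.channel_labels)
    idx = [epochs.channel_index(c) for c in channels]
    # (n_epochs, n_samples, n_channels)
    return np.transpose(epochs.epochs[:, idx, :], (0, 2, 1))


def cca_classify(
    epochs: EpochSet,
    stim_freqs: list[float] = (7.0, 8.0, 9.0),
    n_harmonics: int = 3,
    channels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each epoch with the frequency maximizing the first canonical
    correlation; returns (labels, rho matrix of shape n_epochs x n_freqs).

    Ties (and NaN-degenerate rows) resolve to the lowest frequency.
    """
    stim_freqs = sorted(float(f) for f in stim_freqs)
    X = _epoch_matrix(epochs, channels)
    n_samples = X.shape[1]
    refs = [
        make_references(f, n_harmonics, epochs.fs, n_samples) for f in stim_freqs
    ]
    rho = np.zeros((X.shape[0], len(stim_freqs)))
    for i in range(X.shape[0]):
        for k, ref in enumerate(refs):
            rho[i, k] = canonical_correlation(X[i], ref)
    decision = np.where(np.isnan(rho), -np.inf, rho)
    labels = np.array([stim_freqs[k] for k in np.argmax(decision, axis=1)])
    return labels, rho


def fbcca_classify(
    epochs: EpochSet,
    stim_freqs: list[float] = (7.0, 8.0, 9.0),
    bank: FilterBankSpec | None = None,
    n_harmonics: int = 3,
    channels: list[str] | None = None,
    square: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter-bank CCA: weighted sum of per-band first canonical correlations.

    decision_k = sum_n w(n) * rho_k(n)  (rho^2 when ``square``); returns
    (labels, decision matrix n_epochs x n_freqs).
    """
    bank = bank or FilterBankSpec()
    stim_freqs = sorted(float(f) for f in stim_freqs)
    X = _epoch_matrix(epochs, channels)
    n_samples = X.shape[1]
    refs = [
        make_references(f, n_harmonics, epochs.fs, n_samples) for f in stim_freqs
    ]
    decision = np.zeros((X.shape[0], len(stim_freqs)))
    for sos, w in zip(bank.sos(epochs.fs), bank.weights):
        if bank.zero_phase:
            Xf = signal.sosfiltfilt(sos, X, axis=1)
        else:
            Xf = signal.sosfilt(sos, X, axis=1)
        for i in range(X.shape[0]):
            for k, ref in enumerate(refs):
                r = canonical_correlation(Xf[i], ref)
                if not np.isnan(r):
                    decision[i, k] += w * (r * r if square else r)
    labels = np.array([stim_freqs[k] for k in np.argmax(decision, axis=1)])
    return labels, decision
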