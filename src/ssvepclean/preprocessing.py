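"""Acquisition-stage filtering: power-line notch and broad band-pass.

Both filters are Butterworth designs applied channel-wise in cascaded
second-order sections.  The stated ``order`` is the overall filter
order; scipy's band designs produce 2N-order filters from an N-order
prototype, so N = order // 2 is passed to ``butter``.  Filtering is
causal (single-pass) by default, with an optional zero-phase
(forward-backward) mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .signals_io import Recording

__all__ = ["FilterSpec", "notch_filter", "bandpass_filter", "apply_filter"]


@dataclass(frozen=True)
class FilterSpec:
    """Description of one Butterworth stage, serializable in run configs."""

    kind: str  # "notch_bandstop" | "bandpass"
    band: tuple[float, float]
    order: int
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("notch_bandstop", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band
        if high >= fs / 2:
            raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
        btype = "bandstop" if self.kind == "notch_bandstop" else "bandpass"
        return signal.butter(
            max(self.order // 2, 1), [low, high], btype=btype, fs=fs, output="sos"
        )


def _filter_array(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def apply_filter(rec: Recording, spec: FilterSpec, log: list[str] | None = None) -> Recording:
    """Return a filtered copy of the recording; metadata is unchanged."""
    filtered = _filter_array(rec.data, spec.sos(rec.fs), spec.zero_phase)
    if log is not None:
        log.append(
            f"{spec.kind} band={spec.band} order={spec.order} zero_phase={spec.zero_phase}"
        )
    return replace(rec, data=filtered)


def notch_filter(
    rec: Recording,
    band: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
    zero_phase: bool = False,
    log: list[str] | None = None,
) -> Recording:
    """Power-line notch: Butterworth band-stop, default 48-52 Hz, order 4."""
    return apply_filter(
        rec, FilterSpec("notch_bandstop", band, order, zero_phase), log=log
    )


def bandpass_filter(
    rec: Recording,
    band: tuple[float, float] = (0.5, 100.0),
    order: int = 8,
    zero_phase: bool = False,
    log: list[str] | None = None,
) -> Recording:
    """Broad band-pass preserving EEG content, default 0.5-100 Hz, order 8."""
    return apply_filter(rec, FilterSpec("bandpass", band, order, zero_phase), log=log)
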