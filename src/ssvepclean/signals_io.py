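"""Core data model and I/O for multichannel EEG/EMG/EOG recordings.

A :class:`Recording` holds a continuous multichannel time series in µV
together with its sampling rate, channel labels/roles, a stimulus
schedule (which flicker frequency was active when) and free-form
artifact annotations.  An :class:`EpochSet` holds non-overlapping,
labelled analysis windows cut from one or more recordings.

Supported containers: delimited text (one column per channel, one row
per sample, with a JSON sidecar carrying sampling rate, roles, schedule
and annotations) and 16-bit EDF for continuous data; an HDF5 container
for epoch caching.  Units are µV throughout and are never rescaled
silently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EpochSet",
    "read_recording",
    "write_recording",
    "segment_windows",
    "concat_epochs",
]

ROLES = ("target", "auxiliary", "other")


@dataclass
class Recording:
    """Continuous multichannel recording in µV.

    Attributes
    ----------
    data : (n_channels, n_samples) array, µV
    fs : sampling rate in Hz
    channel_labels : ordered channel names
    channel_roles : per-channel role in {"target", "auxiliary", "other"}
    schedule : list of (onset_s, duration_s, stimulus_hz)
    annotations : list of (onset_s, duration_s, label)
    subject_id : subject identifier
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str] = field(default_factory=list)
    schedule: list[tuple[float, float, float]] = field(default_factory=list)
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if not self.channel_roles:
            self.channel_roles = ["other"] * len(self.channel_labels)
        if len(self.channel_roles) != len(self.channel_labels):
            raise ValueError("channel_roles length must match channel_labels")
        for r in self.channel_roles:
            if r not in ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        self.schedule = [tuple(map(float, s)) for s in self.schedule]
        dur = self.duration_s
        last_end = -np.inf
        for onset, length, _freq in sorted(self.schedule):
            if onset < last_end - 1e-9:
                raise ValueError("schedule intervals overlap")
            if onset < -1e-9 or onset + length > dur + 1e-9:
                raise ValueError("schedule interval outside recording")
            last_end = onset + length

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channels_with_role(self, role: str) -> list[str]:
        return [c for c, r in zip(self.channel_labels, self.channel_roles) if r == role]


@dataclass
class EpochSet:
    """Labelled non-overlapping analysis windows.

    ``epochs`` has shape (n_epochs, n_channels, n_window_samples); a
    label is the active stimulus frequency in Hz (NaN if unlabelled).
    """

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    window_s: float
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids must match epoch count")
        expected = int(round(self.window_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"window has {self.epochs.shape[2]} samples, expected {expected}"
            )
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match epoch channel axis")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_window_samples(self) -> int:
        return self.epochs.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not present") from err

    def channels_with_role(self, role: str) -> list[str]:
        return [c for c, r in zip(self.channel_labels, self.channel_roles) if r == role]

    def select_channels(self, labels: Sequence[str]) -> "EpochSet":
        """Return a copy restricted to the given channels, in the given order."""
        idx = [self.channel_index(c) for c in labels]
        return EpochSet(
            epochs=self.epochs[:, idx, :].copy(),
            labels=self.labels.copy(),
            subject_ids=self.subject_ids.copy(),
            window_s=self.window_s,
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in idx],
            channel_roles=[self.channel_roles[i] for i in idx],
        )

    def select_epochs(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            window_s=self.window_s,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
        )

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s))
        return list(seen)

    # -- HDF5 caching -------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.epochs)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset(
                "subject_ids", data=np.asarray(self.subject_ids, dtype="S32")
            )
            f.attrs["window_s"] = self.window_s
            f.attrs["fs"] = self.fs
            f.attrs["channel_labels"] = json.dumps(self.channel_labels)
            f.attrs["channel_roles"] = json.dumps(self.channel_roles)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                epochs=f["epochs"][...],
                labels=f["labels"][...],
                subject_ids=np.array(
                    [s.decode() for s in f["subject_ids"][...]], dtype=object
                ),
                window_s=float(f.attrs["window_s"]),
                fs=float(f.attrs["fs"]),
                channel_labels=json.loads(f.attrs["channel_labels"]),
                channel_roles=json.loads(f.attrs["channel_roles"]),
            )


# ---------------------------------------------------------------------------
# sidecar helpers

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(rec: Recording, path: Path, include_fs: bool) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "channel_roles": dict(zip(rec.channel_labels, rec.channel_roles)),
        "schedule": [list(s) for s in rec.schedule],
        "annotations": [[o, d, str(lab)] for o, d, lab in rec.annotations],
    }
    if include_fs:
        meta["fs"] = rec.fs
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format)

_EDF_PHYS_RANGE = 3276.8  # µV; gives a 0.1 µV quantization step


def _edf_write(rec: Recording, path: Path, phys_range: float = _EDF_PHYS_RANGE) -> None:
    """Minimal EDF writer: one 1-s data record per second, int16 samples.

    The physical range is symmetric (±phys_range µV) so the quantization
    step is 2*phys_range/65536.  Trailing samples that do not fill a
    whole record are dropped (whole-second recordings round-trip
    losslessly up to quantization).
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-6:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        warnings.warn("EDF write truncates to whole 1-s records", stacklevel=2)
    ns = rec.n_channels

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            fixed("0", 8),
            fixed(rec.subject_id, 80),
            fixed("ssvepclean", 80),
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 * (ns + 1)), 8),
            fixed("", 44),
            fixed(str(n_rec), 8),
            fixed("1", 8),
            fixed(str(ns), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(fixed(lab, 16) for lab in rec.channel_labels),
            b"".join(fixed("AgAgCl", 80) for _ in range(ns)),
            b"".join(fixed("uV", 8) for _ in range(ns)),
            b"".join(fixed(f"{-phys_range:.1f}", 8) for _ in range(ns)),
            b"".join(fixed(f"{phys_range:.1f}", 8) for _ in range(ns)),
            b"".join(fixed("-32768", 8) for _ in range(ns)),
            b"".join(fixed("32767", 8) for _ in range(ns)),
            b"".join(fixed("", 80) for _ in range(ns)),
            b"".join(fixed(str(spr), 8) for _ in range(ns)),
            b"".join(fixed("", 32) for _ in range(ns)),
        ]
    )
    scale = 65535 / (2 * phys_range)
    with open(path, "wb") as f:
        f.write(header + per_sig)
        for r in range(n_rec):
            chunk = rec.data[:, r * spr : (r + 1) * spr]
            dig = np.round((chunk + phys_range) * scale - 32768.0)
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            f.write(dig.tobytes())


def _edf_read(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; recordings are stored in µV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# public I/O

def read_recording(
    path: str | Path,
    format: str | None = None,
    role_map: dict[str, str] | None = None,
) -> Recording:
    """Read a recording from delimited text or EDF.

    CSV files need a header row of channel labels and a JSON sidecar
    (``<file>.json``) declaring at least ``fs``.  Roles come from
    ``role_map`` (overriding any sidecar roles); unmapped channels
    default to ``"other"``.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format not in ("edf", "csv"):
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float).T
        if "fs" not in meta:
            raise ValueError("csv recordings require a sidecar declaring fs")
        fs = float(meta["fs"])
    else:
        data, fs, labels = _edf_read(path)
    roles_in = dict(meta.get("channel_roles", {}))
    if role_map:
        unknown = set(role_map) - set(labels)
        if unknown:
            raise ValueError(f"role_map names absent channels: {sorted(unknown)}")
        roles_in.update(role_map)
    roles = [roles_in.get(lab, "other") for lab in labels]
    return Recording(
        data=data,
        fs=fs,
        channel_labels=labels,
        channel_roles=roles,
        schedule=[tuple(s) for s in meta.get("schedule", [])],
        annotations=[(o, d, lab) for o, d, lab in meta.get("annotations", [])],
        subject_id=str(meta.get("subject_id", "S00")),
    )


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording (CSV round-trips exactly; EDF within 16-bit quantization).

    A JSON sidecar with roles, schedule, annotations and subject id is
    always written next to the data file.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        # %.17g keeps doubles bit-exact through the text round-trip
        pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
            path, index=False, float_format="%.17g"
        )
        _write_sidecar(rec, path, include_fs=True)
    elif format == "edf":
        _edf_write(rec, path)
        _write_sidecar(rec, path, include_fs=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# segmentation

def _label_for_interval(
    schedule: Iterable[tuple[float, float, float]], start: float, stop: float
) -> float:
    """Stimulus frequency of the schedule entry fully covering [start, stop); NaN otherwise."""
    for onset, dur, freq in schedule:
        if onset <= start + 1e-9 and stop <= onset + dur + 1e-9:
            return float(freq)
    return np.nan


def segment_windows(
    rec: Recording, window_s: float = 1.0, drop_unlabeled: bool = True
) -> EpochSet:
    """Cut a recording into non-overlapping windows of ``window_s`` seconds.

    Windows are half-open intervals [k*window_s, (k+1)*window_s); the
    trailing partial window is discarded.  Each window is labelled with
    the stimulus frequency of the schedule entry that fully covers it;
    windows straddling schedule boundaries (or outside any entry) are
    dropped when ``drop_unlabeled`` and the recording has a schedule.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win_samples = window_s * rec.fs
    if abs(n_win_samples - round(n_win_samples)) > 0.5:
        raise ValueError("window_s * fs must be close to an integer")
    n_win_samples = int(round(n_win_samples))
    n_windows = rec.n_samples // n_win_samples
    epochs, labels = [], []
    for k in range(n_windows):
        start_s = k * window_s
        lab = _label_for_interval(rec.schedule, start_s, start_s + window_s)
        if drop_unlabeled and rec.schedule and np.isnan(lab):
            continue
        epochs.append(rec.data[:, k * n_win_samples : (k + 1) * n_win_samples])
        labels.append(lab)
    shape = (len(epochs), rec.n_channels, n_win_samples)
    return EpochSet(
        epochs=np.array(epochs, dtype=float).reshape(shape),
        labels=np.array(labels, dtype=float),
        subject_ids=np.array([rec.subject_id] * len(epochs), dtype=object),
        window_s=window_s,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_roles=list(rec.channel_roles),
    )


def concat_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets in input order; subject ids are preserved."""
    if not sets:
        raise ValueError("need at least one EpochSet")
    first = sets[0]
    for s in sets[1:]:
        if s.channel_labels != first.channel_labels:
            raise ValueError("mismatched channel sets")
        if s.fs != first.fs or s.window_s != first.window_s:
            raise ValueError("mismatched fs/window_s")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        window_s=first.window_s,
        fs=first.fs,
        channel_labels=list(first.channel_labels),
        channel_roles=list(first.channel_roles),
    )
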