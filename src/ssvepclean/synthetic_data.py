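"""Synthetic SSVEP recordings with ground-truth artifact mixing.

Emulates the structure of the study protocol this package targets:
per subject, three 60-s sessions at 256 Hz, one per stimulation
frequency (7, 8, 9 Hz).  Occipital channels (O1, O2, Oz) carry the
SSVEP response — a sum of the first three harmonics with per-channel
phases — over 1/f background noise, plus artifact sources projected
through a known linear mixing matrix.  Auxiliary channels (Cz, Fp1,
HEOG, neck, cheek, jaw) record the artifact sources themselves plus
sensor noise and weak background, with no SSVEP leakage by default.

Artifact episodes of 1-2 s occur at random, non-overlapping times, as
EMG bursts (20-90 Hz band-limited noise under a smooth envelope), eye
blinks (stereotyped ~0.3-s biphasic pulses) or slow ocular/eyebrow
drifts (< 3 Hz bumps).  Because the mixing is known exactly, the
generator provides what a real recording cannot: the pristine SSVEP
component, the source time courses and the true projection gains, so
regression-cleaning accuracy is directly checkable.

All randomness flows from one master seed through documented
``(seed, subject, session)`` derivations, making every dataset
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signals_io import EpochSet, Recording, concat_epochs, segment_windows

__all__ = [
    "SourceSpec",
    "SynthConfig",
    "GroundTruth",
    "pink_noise",
    "draw_episodes",
    "make_artifact_source",
    "generate_session",
    "generate_dataset",
]

TARGET_CHANNELS = ("O1", "O2", "Oz")
AUX_CHANNELS = ("Cz", "Fp1", "HEOG", "neck", "cheek", "jaw")


@dataclass(frozen=True)
class SourceSpec:
    """One artifact source feeding one auxiliary channel.

    ``participation`` is the probability that this source joins a given
    artifact event: deliberate facial actions (smiling, jaw clenching,
    brow raising) engage several muscles at once, so sources are active
    in overlapping groups rather than independently.  The central
    channel participates in every event, modelling its role as a global
    artifact reference.
    """

    kind: str  # "emg_burst" | "eog_blink" | "eyebrow_drift"
    channel: str
    rate_per_min: float = 4.0  # used when a source is simulated standalone
    duration_range: tuple[float, float] = (1.0, 2.0)
    amplitude: float = 15.0  # µV (episode RMS for EMG, peak for blink/drift)
    participation: float = 0.6


def _default_sources() -> list[SourceSpec]:
    # amplitudes set to deliberate-artifact levels: the projected
    # occipital artifact is several times the SSVEP fundamental during
    # episodes, and ~30% of 1-s windows contain an artifact
    return [
        SourceSpec("emg_burst", "Cz", amplitude=50.0, participation=1.0),
        SourceSpec("eog_blink", "Fp1", amplitude=120.0),
        SourceSpec("eyebrow_drift", "HEOG", amplitude=120.0),
        SourceSpec("emg_burst", "neck", amplitude=100.0),
        SourceSpec("emg_burst", "cheek", amplitude=100.0),
        SourceSpec("emg_burst", "jaw", amplitude=100.0),
    ]


def _default_mixing() -> np.ndarray:
    # rows: sources (order of _default_sources), cols: O1, O2, Oz —
    # magnitudes shaped like the projection gains seen on real caps
    # (central channel dominant, ocular/muscular ~0.1-0.2)
    return np.array(
        [
            [0.42, 0.40, 0.44],  # Cz
            [0.12, 0.11, 0.13],  # Fp1
            [0.14, 0.13, 0.15],  # HEOG
            [0.10, 0.11, 0.10],  # neck
            [0.13, 0.12, 0.14],  # cheek
            [0.13, 0.14, 0.12],  # jaw
        ]
    )


@dataclass
class SynthConfig:
    fs: float = 256.0
    session_s: float = 60.0
    stim_freqs: tuple[float, ...] = (7.0, 8.0, 9.0)
    ssvep_amp: tuple[float, ...] = (1.0, 0.5, 0.25)  # µV per harmonic
    background_exponent: float = 1.0  # 1/f^alpha power
    background_rms: float = 4.0  # µV on occipital channels
    event_rate_per_min: float = 8.0  # shared artifact events
    phase_spread: float = 0.4  # rad, inter-channel SSVEP phase spread
    event_duration_range: tuple[float, float] = (1.0, 2.0)
    sources: list[SourceSpec] = field(default_factory=_default_sources)
    mixing: np.ndarray = field(default_factory=_default_mixing)
    mixing_jitter: float = 0.15  # relative inter-subject SD of mixing gains
    aux_noise_rms: float = 0.5  # µV white sensor noise on auxiliaries
    aux_background_rms: float = 0.2  # µV weak 1/f background on auxiliaries
    ssvep_leakage: float = 0.0  # SSVEP gain into auxiliaries (stress-test knob)
    n_subjects: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (len(self.sources), len(TARGET_CHANNELS)):
            raise ValueError(
                "mixing must be (n_sources, n_targets) "
                f"= ({len(self.sources)}, {len(TARGET_CHANNELS)})"
            )
        if not np.all(np.isfinite(self.mixing)):
            raise ValueError("mixing must be finite")
        if any(a < 0 for a in self.ssvep_amp):
            raise ValueError("ssvep_amp must be non-negative")
        for s in self.sources:
            lo, hi = s.duration_range
            if not 0 < lo <= hi < self.session_s:
                raise ValueError("episode durations must fit in the session")

    def artifact_free(self) -> "SynthConfig":
        """Copy with all artifact sources silenced."""
        return replace(
            self,
            sources=[replace(s, amplitude=0.0) for s in self.sources],
            mixing=self.mixing.copy(),
        )


@dataclass
class GroundTruth:
    """Exact decomposition of one session's occipital signals.

    recorded = clean + mixing.T @ sources + background, bit-identical by
    construction.
    """

    clean: np.ndarray  # (n_targets, n_samples) pristine SSVEP
    background: np.ndarray  # (n_targets, n_samples) 1/f noise
    sources: np.ndarray  # (n_sources, n_samples) artifact time courses
    mixing: np.ndarray  # (n_sources, n_targets) subject-level gains
    annotations: list[tuple[float, float, str]]
    stim_freq: float = 0.0


def pink_noise(
    n_samples: int, exponent: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Zero-mean noise with PSD ∝ 1/f^exponent, unit RMS, by spectral shaping."""
    if n_samples < 16:
        raise ValueError("need n_samples >= 16")
    if not 0.0 <= exponent <= 2.0:
        raise ValueError("exponent must be in [0, 2]")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * shape, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def draw_episodes(
    rng: np.random.Generator,
    session_s: float,
    rate_per_min: float,
    duration_range: tuple[float, float] = (1.0, 2.0),
    margin_s: float = 0.25,
    max_tries: int = 1000,
) -> list[tuple[float, float]]:
    """Random non-overlapping (onset_s, duration_s) episodes via rejection sampling."""
    n = int(round(rate_per_min * session_s / 60.0))
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        dur = float(rng.uniform(*duration_range))
        for _try in range(max_tries):
            onset = float(rng.uniform(0.0, session_s - dur))
            if all(
                onset + dur + margin_s <= o or o + d + margin_s <= onset
                for o, d in placed
            ):
                placed.append((onset, dur))
                break
    return sorted(placed)


def _blink_pulse(fs: float, width_s: float = 0.3) -> np.ndarray:
    """Stereotyped biphasic blink shape, unit peak."""
    n = int(round(width_s * fs))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.sin(np.pi * t)


def make_artifact_source(
    kind: str,
    n_samples: int,
    fs: float,
    episodes: Sequence[tuple[float, float]],
    amplitude: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[tuple[float, float, str]]]:
    """Source time course that is exactly zero outside the given episodes.

    emg_burst: 20-90 Hz noise under a Tukey on/off envelope, episode RMS
    = amplitude.  eog_blink: a train of ~0.3-s biphasic pulses, peak =
    amplitude.  eyebrow_drift: a < 3 Hz raised-cosine bump, peak =
    amplitude.  Returns (vector, annotations).
    """
    if kind not in ("emg_burst", "eog_blink", "eyebrow_drift"):
        raise ValueError(f"unknown source kind {kind!r}")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    eps = sorted((float(o), float(d)) for o, d in episodes)
    for (o1, d1), (o2, _d2) in zip(eps, eps[1:]):
        if o1 + d1 > o2 + 1e-9:
            raise ValueError("episodes overlap")
    if eps and (eps[0][0] < 0 or eps[-1][0] + eps[-1][1] > n_samples / fs + 1e-9):
        raise ValueError("episodes outside the session")

    x = np.zeros(n_samples)
    annotations = []
    sos = sos_slow = None
    if kind == "emg_burst":
        sos = sps.butter(4, [20.0, 90.0], btype="bandpass", fs=fs, output="sos")
        sos_slow = sps.butter(2, 4.0, btype="lowpass", fs=fs, output="sos")
    for onset, dur in eps:
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + dur) * fs)), n_samples)
        n = i1 - i0
        if n <= 0:
            continue
        if kind == "emg_burst":
            burst = sps.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]
            rms = np.sqrt(np.mean(burst**2))
            if rms > 0:
                burst /= rms
            # muscle contractions move the electrode too: a small slow
            # motion component (<10% of episode power) rides on the burst
            slow = sps.sosfilt(sos_slow, rng.standard_normal(n + int(fs)))[int(fs):]
            srms = np.sqrt(np.mean(slow**2))
            if srms > 0:
                burst += 0.25 * slow / srms
            burst *= sps.windows.tukey(n, alpha=0.4)
            rms = np.sqrt(np.mean(burst**2))
            if rms > 0:
                burst *= amplitude / rms
            x[i0:i1] = burst
        elif kind == "eog_blink":
            pulse = _blink_pulse(fs) * amplitude
            step = int(round(0.5 * fs))
            pos = 0
            while pos + pulse.size <= n:
                x[i0 + pos : i0 + pos + pulse.size] += pulse
                pos += step + int(rng.integers(0, int(0.2 * fs) + 1))
        else:  # eyebrow_drift: slow ramp with an abrupt release, as real
            # drifts end; the step edge leaks broadband power like real
            # motion transients
            t = np.arange(n) / n
            x[i0:i1] = amplitude * t
        annotations.append((onset, dur, kind))
    return x, annotations


def _subject_mixing(cfg: SynthConfig, subject_idx: int) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, subject_idx, 7919])
    jitter = 1.0 + cfg.mixing_jitter * rng.standard_normal(cfg.mixing.shape)
    return cfg.mixing * jitter


def generate_session(
    cfg: SynthConfig, subject: int, stim_f: float
) -> tuple[Recording, GroundTruth]:
    """One 60-s session for subject index ``subject`` at ``stim_f`` Hz."""
    if stim_f not in cfg.stim_freqs:
        raise ValueError(f"stim_f {stim_f} not in configured frequencies")
    session_idx = list(cfg.stim_freqs).index(stim_f)
    n = int(round(cfg.session_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    rng = np.random.default_rng([cfg.seed, subject, session_idx])

    n_t = len(TARGET_CHANNELS)
    # neighbouring occipital electrodes see the SSVEP nearly in phase:
    # one random phase per harmonic and session, plus a small
    # per-channel spread (the response is spatially near rank-1, which
    # is what makes artifact projections genuinely harmful)
    base = rng.uniform(0, 2 * np.pi, size=len(cfg.ssvep_amp))
    spread = rng.uniform(-cfg.phase_spread, cfg.phase_spread,
                         size=(n_t, len(cfg.ssvep_amp)))
    clean = np.zeros((n_t, n))
    for c in range(n_t):
        for h, amp in enumerate(cfg.ssvep_amp, start=1):
            clean[c] += amp * np.sin(
                2 * np.pi * h * stim_f * t + base[h - 1] + spread[c, h - 1]
            )

    background = np.stack(
        [
            cfg.background_rms * pink_noise(n, cfg.background_exponent, rng)
            for _ in range(n_t)
        ]
    )

    # shared artifact events: each deliberate facial action activates a
    # (random) group of sources simultaneously, so the artifact occupies
    # several spatial dimensions at once, as compound real actions do
    events = draw_episodes(
        rng, cfg.session_s, cfg.event_rate_per_min, cfg.event_duration_range
    )
    sources = np.zeros((len(cfg.sources), n))
    annotations: list[tuple[float, float, str]] = []
    for j, spec in enumerate(cfg.sources):
        if spec.amplitude > 0:
            eps = [e for e in events if rng.random() < spec.participation]
        else:
            eps = []
        src, ann = make_artifact_source(
            spec.kind, n, cfg.fs, eps, spec.amplitude, rng
        )
        sources[j] = src
        annotations.extend((o, d, f"{spec.kind}:{spec.channel}") for o, d, _ in ann)
    annotations.sort()

    mixing = _subject_mixing(cfg, subject)
    occipital = clean + background + mixing.T @ sources

    aux = np.zeros((len(AUX_CHANNELS), n))
    for a, ch in enumerate(AUX_CHANNELS):
        for j, spec in enumerate(cfg.sources):
            if spec.channel == ch:
                aux[a] += sources[j]
        if cfg.aux_background_rms > 0:
            aux[a] += cfg.aux_background_rms * pink_noise(n, 1.0, rng)
        if cfg.aux_noise_rms > 0:
            aux[a] += cfg.aux_noise_rms * rng.standard_normal(n)
        if cfg.ssvep_leakage > 0:
            aux[a] += cfg.ssvep_leakage * clean.mean(axis=0)

    rec = Recording(
        data=np.vstack([occipital, aux]),
        fs=cfg.fs,
        channel_labels=list(TARGET_CHANNELS) + list(AUX_CHANNELS),
        channel_roles=["target"] * n_t + ["auxiliary"] * len(AUX_CHANNELS),
        schedule=[(0.0, cfg.session_s, float(stim_f))],
        annotations=annotations,
        subject_id=f"S{subject + 1:02d}",
    )
    truth = GroundTruth(
        clean=clean,
        background=background,
        sources=sources,
        mixing=mixing,
        annotations=annotations,
        stim_freq=float(stim_f),
    )
    return rec, truth


def generate_dataset(
    cfg: SynthConfig, window_s: float = 1.0
) -> tuple[EpochSet, dict[str, list[GroundTruth]]]:
    """Full multi-subject dataset: per subject one session per stimulus
    frequency, segmented into labelled windows and concatenated."""
    if cfg.n_subjects < 1:
        raise ValueError("need n_subjects >= 1")
    sets = []
    truths: dict[str, list[GroundTruth]] = {}
    for s in range(cfg.n_subjects):
        per_subject = []
        for f in cfg.stim_freqs:
            rec, truth = generate_session(cfg, s, f)
            per_subject.append(segment_windows(rec, window_s))
            truths.setdefault(rec.subject_id, []).append(truth)
        sets.append(concat_epochs(per_subject))
    return concat_epochs(sets), truths
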