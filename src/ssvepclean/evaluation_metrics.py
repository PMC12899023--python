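"""Evaluation: LOSO protocol, accuracy, McNemar, paired group tests,
Wolpaw information transfer rate and spectral SNR.

Leave-one-subject-out (LOSO): in each split all windows of one subject
form the test set and the remaining subjects the training pool, so
accuracies estimate performance on unseen users.  Cleaning is fitted
per window on the test data itself without labels, so it never leaks
training-subject statistics into the test subject.

The Wolpaw ITR for an N-class task at accuracy P with one decision per
T seconds is

    ITR = (60/T) * [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]  bit/min

clamped to 0 for P <= 1/N (chance level) by convention.

Spectral SNR at a stimulation frequency f is the dB ratio of the power
in the f bin to the mean power of the six neighbouring bins at
f ± 1, 2, 3 Hz — a local contrast measure that cancels global gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import NetConfig, predict, train_compact_net, train_linear_svm
from .reference_methods import FilterBankSpec, cca_classify, fbcca_classify
from .regression_cleaner import clean_epochs
from .signals_io import EpochSet
from .spectral_features import extract_harmonic_features

__all__ = [
    "LosoSplit",
    "EvalConfig",
    "EvalReport",
    "loso_splits",
    "accuracy",
    "mcnemar_test",
    "group_paired_test",
    "wolpaw_itr",
    "snr_at_frequency",
    "snr_report",
    "run_full_evaluation",
]


@dataclass(frozen=True)
class LosoSplit:
    test_subject: str
    train_subjects: tuple[str, ...]


def loso_splits(subject_ids: Sequence[str]) -> list[LosoSplit]:
    """One split per unique subject, in order of first appearance."""
    subjects: list[str] = []
    for s in subject_ids:
        if str(s) not in subjects:
            subjects.append(str(s))
    if len(subjects) < 2:
        raise ValueError("LOSO needs >= 2 subjects")
    return [
        LosoSplit(s, tuple(t for t in subjects if t != s)) for s in subjects
    ]


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of correctly classified windows."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return 100.0 * float(np.mean(pred == truth))


def mcnemar_test(
    pred_a: np.ndarray, pred_b: np.ndarray, truth: np.ndarray
) -> tuple[int, int, float]:
    """Paired window-level comparison of two classifiers on the same items.

    Returns (b, c, p) with b = windows correct only under A, c = correct
    only under B.  Exact binomial two-sided p for b + c <= 25, otherwise
    the continuity-corrected chi-square approximation.  b + c = 0 (no
    discordant windows) is degenerate: p = 1.
    """
    pred_a, pred_b, truth = map(np.asarray, (pred_a, pred_b, truth))
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("inputs must share length")
    ok_a = pred_a == truth
    ok_b = pred_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    n = b + c
    if n == 0:
        return b, c, 1.0
    if n <= 25:
        p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
        p = min(p, 1.0)
    else:
        stat = (abs(b - c) - 1.0) ** 2 / n
        p = float(stats.chi2.sf(stat, df=1))
    return b, c, float(p)


def group_paired_test(
    acc_a: Sequence[float], acc_b: Sequence[float]
) -> dict[str, float]:
    """Two-sided paired t and Wilcoxon signed-rank p on per-subject accuracies.

    A zero-variance nonzero difference gives t p = 0.0 (the limit of the
    statistic); all-zero differences make both tests degenerate (p = 1
    for t, NaN for Wilcoxon).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length vectors of >= 5 subjects")
    diff = b - a
    if np.allclose(diff.std(), 0.0):
        p_t = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    else:
        p_t = float(stats.ttest_rel(b, a).pvalue)
    if np.allclose(diff, 0.0):
        p_w = float("nan")
    else:
        p_w = float(stats.wilcoxon(b, a, zero_method="wilcox").pvalue)
    return {"t": p_t, "wilcoxon": p_w}


def wolpaw_itr(
    P: float, n_classes: int, window_s: float, clamp: bool = True
) -> float:
    """Wolpaw information transfer rate in bit/min.

    ``clamp`` zeroes the rate at or below chance (P <= 1/N); disable it
    to get the raw formula value.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    if n_classes < 2:
        raise ValueError("need >= 2 classes")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    N = float(n_classes)
    if clamp and P <= 1.0 / N:
        return 0.0
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(60.0 / window_s * bits)


def snr_at_frequency(
    power: np.ndarray, f: float, freqs: np.ndarray | None = None
) -> float:
    """SNR in dB of the f bin against the mean power of the six bins at
    f ± 1, 2, 3 Hz.

    ``power`` is a one-sided power spectrum (squared amplitude); without
    ``freqs`` the bins are assumed to sit on an integer-Hz grid starting
    at 0.  Returns +inf when all neighbour bins are empty.
    """
    power = np.asarray(power, dtype=float)
    if freqs is None:
        freqs = np.arange(power.size, dtype=float)
    offsets = (-3, -2, -1, 1, 2, 3)
    def bin_at(freq: float) -> int:
        idx = int(np.argmin(np.abs(freqs - freq)))
        if abs(freqs[idx] - freq) > 1e-6:
            raise ValueError(f"no spectrum bin at {freq} Hz")
        return idx
    p_sig = power[bin_at(f)]
    neigh = np.array([power[bin_at(f + o)] for o in offsets])
    denom = neigh.mean()
    if denom == 0:
        return float("inf")
    return float(10.0 * np.log10(p_sig / denom))


def _window_power_spectra(epochs: EpochSet, channels: list[str]) -> np.ndarray:
    """(n_epochs, n_channels, n_bins) one-sided power spectra."""
    idx = [epochs.channel_index(c) for c in channels]
    n = epochs.n_window_samples
    spec = np.abs(np.fft.rfft(epochs.epochs[:, idx, :], axis=-1)) / n
    spec[..., 1:] *= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    return spec**2


def snr_report(
    epochs_raw: EpochSet,
    epochs_clean: EpochSet,
    stim_freqs: Sequence[float] = (7.0, 8.0, 9.0),
    channels: list[str] | None = None,
    domain: str = "db",
) -> pd.DataFrame:
    """Per-subject, per-frequency SNR before/after cleaning and the gain.

    Per-window SNR (dB) is averaged over a subject's windows at each
    stimulation frequency, then over the occipital channels (``domain=
    "linear"`` averages power ratios before taking dB instead).  Columns:
    subject, frequency, snr_raw_db, snr_clean_db, gain_db.
    """
    if epochs_raw.n_epochs != epochs_clean.n_epochs:
        raise ValueError("raw and clean epoch sets must be matched")
    if domain not in ("db", "linear"):
        raise ValueError("domain must be 'db' or 'linear'")
    if channels is None:
        channels = epochs_clean.channel_labels
    raw_ch = channels if set(channels) <= set(epochs_raw.channel_labels) else None
    pow_raw = _window_power_spectra(epochs_raw, raw_ch or channels)
    pow_clean = _window_power_spectra(epochs_clean, channels)
    resolution = epochs_raw.fs / epochs_raw.n_window_samples

    def mean_snr(power: np.ndarray, mask: np.ndarray, f: float) -> float:
        k = f / resolution
        if abs(k - round(k)) > 1e-6:
            raise ValueError(f"{f} Hz off the {resolution:g} Hz bin grid")
        k = int(round(k))
        neigh_bins = [int(round((f + o) / resolution)) for o in (-3, -2, -1, 1, 2, 3)]
        p_sig = power[mask][:, :, k]
        p_bg = power[mask][:, :, neigh_bins].mean(axis=-1)
        ratio = p_sig / p_bg
        if domain == "db":
            return float(np.mean(10.0 * np.log10(ratio)))
        return float(10.0 * np.log10(np.mean(ratio)))

    rows = []
    for subject in epochs_raw.subjects:
        s_mask = epochs_raw.subject_ids == subject
        for f in stim_freqs:
            mask = s_mask & (epochs_raw.labels == f)
            if not mask.any():
                raise ValueError(f"no epochs for subject {subject} at {f} Hz")
            snr_r = mean_snr(pow_raw, mask, f)
            snr_c = mean_snr(pow_clean, mask, f)
            rows.append((subject, f, snr_r, snr_c, snr_c - snr_r))
    return pd.DataFrame(
        rows, columns=["subject", "frequency", "snr_raw_db", "snr_clean_db", "gain_db"]
    )


# ---------------------------------------------------------------------------
# full evaluation


@dataclass
class EvalConfig:
    methods: tuple[str, ...] = ("svm", "compact_net", "cca", "fbcca")
    stim_freqs: tuple[float, ...] = (7.0, 8.0, 9.0)
    n_harmonics: int = 3
    auxiliaries: tuple[str, ...] | None = None  # None -> channels with role auxiliary
    svm_C: float = 1.0
    net: NetConfig = field(default_factory=NetConfig)
    bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    compute_mcnemar: bool = True
    compute_snr: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    """Assembled LOSO comparison of raw (O-only) vs cleaned (O-clean) variants."""

    accuracies: pd.DataFrame  # subject, method, variant, accuracy, run_sd
    mcnemar: pd.DataFrame     # subject, method, b, c, p
    group_tests: pd.DataFrame # method, p_t, p_wilcoxon
    itr: pd.DataFrame         # method, variant, mean_accuracy, itr_bit_min
    snr: pd.DataFrame         # snr_report output
    config: dict = field(default_factory=dict)

    def mean_accuracy(self, method: str, variant: str) -> float:
        df = self.accuracies
        sel = df[(df.method == method) & (df.variant == variant)]
        return float(sel.accuracy.mean())

    def to_json(self) -> dict:
        return {
            "accuracies": self.accuracies.to_dict(orient="records"),
            "mcnemar": self.mcnemar.to_dict(orient="records"),
            "group_tests": self.group_tests.to_dict(orient="records"),
            "itr": self.itr.to_dict(orient="records"),
            "snr": self.snr.to_dict(orient="records"),
            "config": self.config,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "EvalReport":
        return cls(
            accuracies=pd.DataFrame(payload["accuracies"]),
            mcnemar=pd.DataFrame(payload["mcnemar"]),
            group_tests=pd.DataFrame(payload["group_tests"]),
            itr=pd.DataFrame(payload["itr"]),
            snr=pd.DataFrame(payload["snr"]),
            config=payload.get("config", {}),
        )


def _trainfree_predictions(
    epochs: EpochSet, method: str, cfg: EvalConfig
) -> np.ndarray:
    if method == "cca":
        labels, _ = cca_classify(epochs, cfg.stim_freqs, cfg.n_harmonics)
    else:
        labels, _ = fbcca_classify(epochs, cfg.stim_freqs, cfg.bank, cfg.n_harmonics)
    return labels


def run_full_evaluation(dataset: EpochSet, config: EvalConfig | None = None) -> EvalReport:
    """LOSO-evaluate every configured method on the raw and cleaned variants.

    Feature definitions are identical across variants; only the input
    signal differs (raw occipital vs per-window regression residual), so
    accuracy differences isolate the effect of artifact reduction.
    """
    cfg = config or EvalConfig()
    targets = dataset.channels_with_role("target")
    if not targets:
        raise ValueError("dataset has no target channels")
    aux = list(cfg.auxiliaries) if cfg.auxiliaries else None
    raw = dataset.select_channels(targets)
    clean = clean_epochs(dataset, targets=targets, auxiliaries=aux).cleaned
    variants = {"O-only": raw, "O-clean": clean}
    splits = loso_splits(dataset.subject_ids)

    feats = {
        name: extract_harmonic_features(ep, cfg.stim_freqs, cfg.n_harmonics, targets)
        for name, ep in variants.items()
    }

    acc_rows, mcn_rows = [], []
    preds: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for method in cfg.methods:
        if method in ("cca", "fbcca"):
            for vname, ep in variants.items():
                labels = _trainfree_predictions(ep, method, cfg)
                for split in splits:
                    mask = ep.subject_ids == split.test_subject
                    acc = accuracy(labels[mask], ep.labels[mask])
                    acc_rows.append((split.test_subject, method, vname, acc, 0.0))
                    preds[(method, split.test_subject)] = preds.get(
                        (method, split.test_subject), {}
                    )
                    preds[(method, split.test_subject)][vname] = labels[mask]
        elif method in ("svm", "compact_net"):
            for si, split in enumerate(splits):
                for vname, fm in feats.items():
                    tr_mask = fm.subject_ids != split.test_subject
                    te_mask = ~tr_mask
                    from .spectral_features import FeatureMatrix

                    train_fm = FeatureMatrix(
                        fm.values[tr_mask], fm.feature_names,
                        fm.labels[tr_mask], fm.subject_ids[tr_mask],
                    )
                    test_fm = FeatureMatrix(
                        fm.values[te_mask], fm.feature_names,
                        fm.labels[te_mask], fm.subject_ids[te_mask],
                    )
                    if method == "svm":
                        model = train_linear_svm(train_fm, C=cfg.svm_C)
                        pred = predict(model, test_fm)
                        acc = accuracy(pred, test_fm.labels)
                        sd = 0.0
                        first_pred = pred
                    else:
                        net_cfg = NetConfig(
                            **{**cfg.net.__dict__, "seed_base": cfg.seed + 97 * si}
                        )
                        model = train_compact_net(train_fm, net_cfg)
                        run_preds = predict(model, test_fm)
                        run_accs = [accuracy(p, test_fm.labels) for p in run_preds]
                        acc = float(np.mean(run_accs))
                        sd = float(np.std(run_accs))
                        first_pred = run_preds[0]
                    acc_rows.append((split.test_subject, method, vname, acc, sd))
                    preds.setdefault((method, split.test_subject), {})[vname] = first_pred
        else:
            raise ValueError(f"unknown method {method!r}")

    acc_df = pd.DataFrame(
        acc_rows, columns=["subject", "method", "variant", "accuracy", "run_sd"]
    )

    if cfg.compute_mcnemar:
        for (method, subject), d in sorted(preds.items()):
            truth = raw.labels[raw.subject_ids == subject]
            b, c, p = mcnemar_test(d["O-clean"], d["O-only"], truth)
            mcn_rows.append((subject, method, b, c, p))
    mcn_df = pd.DataFrame(mcn_rows, columns=["subject", "method", "b", "c", "p"])

    group_rows = []
    for method in cfg.methods:
        sub = acc_df[acc_df.method == method]
        a = sub[sub.variant == "O-only"].sort_values("subject").accuracy.to_numpy()
        b_ = sub[sub.variant == "O-clean"].sort_values("subject").accuracy.to_numpy()
        if a.size >= 5:
            ps = group_paired_test(a, b_)
            group_rows.append((method, ps["t"], ps["wilcoxon"]))
    group_df = pd.DataFrame(group_rows, columns=["method", "p_t", "p_wilcoxon"])

    itr_rows = []
    n_classes = len(cfg.stim_freqs)
    for method in cfg.methods:
        for vname in variants:
            sel = acc_df[(acc_df.method == method) & (acc_df.variant == vname)]
            mean_acc = float(sel.accuracy.mean())
            itr = wolpaw_itr(mean_acc / 100.0, n_classes, dataset.window_s)
            itr_rows.append((method, vname, mean_acc, itr))
    itr_df = pd.DataFrame(
        itr_rows, columns=["method", "variant", "mean_accuracy", "itr_bit_min"]
    )

    snr_df = pd.DataFrame()
    if cfg.compute_snr:
        snr_df = snr_report(raw, clean, cfg.stim_freqs, channels=targets)

    return EvalReport(
        accuracies=acc_df,
        mcnemar=mcn_df,
        group_tests=group_df,
        itr=itr_df,
        snr=snr_df,
        config={
            "methods": list(cfg.methods),
            "stim_freqs": list(cfg.stim_freqs),
            "n_harmonics": cfg.n_harmonics,
            "auxiliaries": list(aux) if aux else "all",
            "svm_C": cfg.svm_C,
            "fbcca_weights": list(map(float, cfg.bank.weights)),
            "seed": cfg.seed,
        },
    )
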