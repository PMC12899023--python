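"""Per-window least-squares artifact removal using auxiliary channels.

The artifact component of an occipital channel y (256 samples per 1-s
window at 256 Hz) is modelled as a linear combination of the auxiliary
channels plus a constant bias:

    y = X b + e,      b = argmin ||y - X b||^2,      y_clean = y - X b

where X = [1, aux_1, ..., aux_p].  Every window and every target channel
is fitted independently, so cleaning uses no statistics beyond the
window itself — in particular no labels and no training-set information,
which keeps leave-one-subject-out evaluation honest.

The fitted coefficients b (one gain per auxiliary channel) are
interpretable as projection gains of each artifact source onto the
occipital electrode; their pooled statistics (mean |b|, SD, CV) rank the
auxiliary channels by importance, and an exhaustive search over the
2^p - 1 non-empty auxiliary subsets finds the per-subject set that
maximizes post-cleaning classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signals_io import EpochSet

__all__ = [
    "BetaTensor",
    "BetaSummary",
    "CleanResult",
    "fit_window_regression",
    "clean_epochs",
    "summarize_betas",
    "enumerate_aux_subsets",
    "search_best_subset",
]


@dataclass
class BetaTensor:
    """Regression coefficients, (n_windows, n_targets, p+1); column 0 is the bias."""

    betas: np.ndarray
    aux_labels: list[str]
    target_labels: list[str]
    degenerate: np.ndarray  # (n_windows, n_targets) bool: rank-deficient design

    def to_frame(self, subject_ids: np.ndarray | None = None) -> pd.DataFrame:
        """Long-format table: subject, window, target, auxiliary, beta."""
        n_w, n_t, _ = self.betas.shape
        rows = []
        for w in range(n_w):
            subj = str(subject_ids[w]) if subject_ids is not None else ""
            for t, tgt in enumerate(self.target_labels):
                for a, aux in enumerate(self.aux_labels):
                    rows.append((subj, w, tgt, aux, self.betas[w, t, a + 1]))
        return pd.DataFrame(
            rows, columns=["subject", "window", "target", "auxiliary", "beta"]
        )


@dataclass
class BetaSummary:
    """Per-auxiliary mean |beta| (bias excluded), SD of |beta| and CV = SD/mean."""

    table: pd.DataFrame  # index: auxiliary, columns: mean_abs_beta, sd, cv


@dataclass
class CleanResult:
    """Cleaned target-channel epochs plus fit diagnostics."""

    cleaned: EpochSet
    betas: BetaTensor
    variance_explained: np.ndarray  # (n_windows, n_targets), NaN for flat windows


def fit_window_regression(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares fit of one window; returns the coefficient vector.

    Rank-deficient designs get the minimum-norm solution (no exception:
    real caps have bridged electrodes).  Use :func:`design_matrix` to
    build X with its leading bias column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p+1) and y (n,) with matching n")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many samples as coefficients")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def design_matrix(aux: np.ndarray) -> np.ndarray:
    """Stack a constant bias column in front of the auxiliary samples.

    ``aux`` is (p, n) channel-major; the result is (n, p+1).
    """
    aux = np.asarray(aux, dtype=float)
    return np.column_stack([np.ones(aux.shape[1]), aux.T])


def clean_epochs(
    epochs: EpochSet,
    targets: Sequence[str] | None = None,
    auxiliaries: Sequence[str] | None = None,
) -> CleanResult:
    """Remove the auxiliary-channel projection from every target channel.

    Defaults: channels with role "target" / "auxiliary".  Window count,
    ordering and labels are preserved; auxiliary channels are never
    modified (the result contains targets only).
    """
    if targets is None:
        targets = epochs.channels_with_role("target")
    if auxiliaries is None:
        auxiliaries = epochs.channels_with_role("auxiliary")
    targets = list(targets)
    auxiliaries = list(auxiliaries)
    if not auxiliaries:
        raise ValueError("auxiliary set must be non-empty")
    if not targets:
        raise ValueError("target set must be non-empty")
    overlap = set(targets) & set(auxiliaries)
    if overlap:
        raise ValueError(f"channels listed as both target and auxiliary: {sorted(overlap)}")

    t_idx = [epochs.channel_index(c) for c in targets]
    a_idx = [epochs.channel_index(c) for c in auxiliaries]
    n_w = epochs.n_epochs
    p = len(auxiliaries)
    betas = np.zeros((n_w, len(targets), p + 1))
    degenerate = np.zeros((n_w, len(targets)), dtype=bool)
    var_exp = np.full((n_w, len(targets)), np.nan)
    cleaned = np.empty((n_w, len(targets), epochs.n_window_samples))

    for w in range(n_w):
        X = design_matrix(epochs.epochs[w, a_idx, :])
        rank = np.linalg.matrix_rank(X)
        for t, ti in enumerate(t_idx):
            y = epochs.epochs[w, ti, :]
            b = fit_window_regression(y, X)
            y_clean = y - X @ b
            betas[w, t] = b
            degenerate[w, t] = rank < X.shape[1]
            cleaned[w, t] = y_clean
            vy = np.var(y)
            if vy > 0:
                var_exp[w, t] = 1.0 - np.var(y_clean) / vy

    cleaned_set = EpochSet(
        epochs=cleaned,
        labels=epochs.labels.copy(),
        subject_ids=epochs.subject_ids.copy(),
        window_s=epochs.window_s,
        fs=epochs.fs,
        channel_labels=targets,
        channel_roles=["target"] * len(targets),
    )
    return CleanResult(
        cleaned=cleaned_set,
        betas=BetaTensor(betas, auxiliaries, targets, degenerate),
        variance_explained=var_exp,
    )


def summarize_betas(betas: BetaTensor, sd: str = "population") -> BetaSummary:
    """Pool |beta| over windows and targets; report mean, SD and CV per auxiliary.

    The bias column is excluded; degenerate windows are dropped.  SD is
    population (divide by N) by default, ``sd="sample"`` for N-1.
    """
    if sd not in ("population", "sample"):
        raise ValueError("sd must be 'population' or 'sample'")
    ok = ~betas.degenerate  # (n_w, n_t)
    if not ok.any():
        raise ValueError("all windows are degenerate")
    rows = {}
    for a, aux in enumerate(betas.aux_labels):
        vals = np.abs(betas.betas[:, :, a + 1][ok])
        mean = float(vals.mean())
        ddof = 0 if sd == "population" else 1
        s = float(vals.std(ddof=ddof))
        rows[aux] = (mean, s, s / mean if mean > 0 else np.inf)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_abs_beta", "sd", "cv"]
    )
    table.index.name = "auxiliary"
    return BetaSummary(table=table)


def enumerate_aux_subsets(auxiliaries: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^p - 1 non-empty auxiliary subsets, by size then lexicographic order.

    "Lexicographic" follows the position of each channel in the input
    list, so the order is deterministic for a fixed montage.
    """
    auxiliaries = list(auxiliaries)
    if not auxiliaries:
        raise ValueError("auxiliary list must be non-empty")
    if len(auxiliaries) > 16:
        raise ValueError("subset enumeration capped at 16 channels")
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(auxiliaries) + 1):
        subsets.extend(combinations(auxiliaries, size))
    return subsets


def search_best_subset(
    dataset: EpochSet,
    subject: str,
    evaluate: Callable[[EpochSet, str], float],
    auxiliaries: Sequence[str] | None = None,
) -> tuple[tuple[str, ...], dict[tuple[str, ...], float]]:
    """Exhaustive auxiliary-subset search for one subject.

    For every non-empty subset the whole dataset is cleaned with that
    subset and ``evaluate(cleaned_dataset, subject)`` returns the
    subject's test accuracy under the caller's protocol (typically a
    single leave-one-subject-out split).  Returns the argmax subset and
    the full accuracy map.  Ties go to the smaller subset, then to
    enumeration order.  Note the selection criterion is the evaluated
    subject's own test accuracy — an optimistic-selection procedure that
    characterizes channel relevance rather than an unbiased estimate.
    """
    if auxiliaries is None:
        auxiliaries = dataset.channels_with_role("auxiliary")
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("subset search needs >= 2 subjects for a training pool")
    if subject not in subjects:
        raise ValueError(f"subject {subject!r} not in dataset")
    accuracies: dict[tuple[str, ...], float] = {}
    best: tuple[str, ...] | None = None
    best_acc = -np.inf
    for subset in enumerate_aux_subsets(auxiliaries):
        cleaned = clean_epochs(dataset, auxiliaries=list(subset)).cleaned
        acc = float(evaluate(cleaned, subject))
        accuracies[subset] = acc
        if acc > best_acc + 1e-12:
            best, best_acc = subset, acc
    assert best is not None
    return best, accuracies
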