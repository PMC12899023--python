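"""Reference results reported for the original 12-subject SSVEP study
whose protocol and montage this package models.

These per-subject leave-one-subject-out accuracies (%), before (O-only)
and after (O-clean) regression-based artifact removal, and the pooled
regression-coefficient statistics are included as benchmark inputs:
summary statistics (means, improvements, information transfer rates)
can be recomputed from them and compared against analyses of synthetic
or newly recorded data.  Values are stored exactly as published for the
study dataset; nothing here is computed by this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECTS",
    "svm_accuracy_table",
    "cnn_accuracy_table",
    "cca_accuracy_table",
    "fbcca_accuracy_table",
    "beta_summary_table",
    "beta_per_subject_table",
]

SUBJECTS = [f"S{i}" for i in range(1, 13)]

# per-subject LOSO accuracy (%): {subject: (O-only, O-clean)}
_SVM = {
    "S1": (52.2, 77.8), "S2": (90.0, 93.3), "S3": (55.6, 68.5),
    "S4": (91.1, 95.6), "S5": (92.8, 99.4), "S6": (90.4, 94.3),
    "S7": (53.3, 59.4), "S8": (41.1, 48.9), "S9": (52.2, 59.4),
    "S10": (81.1, 92.2), "S11": (53.3, 70.0), "S12": (96.1, 99.4),
}
_CNN = {
    "S1": (48.7, 78.1), "S2": (90.6, 93.3), "S3": (57.2, 66.9),
    "S4": (92.1, 96.0), "S5": (89.3, 99.4), "S6": (93.1, 94.4),
    "S7": (53.0, 52.0), "S8": (40.0, 48.0), "S9": (49.6, 58.7),
    "S10": (87.4, 95.7), "S11": (51.5, 73.9), "S12": (95.6, 99.4),
}
_CCA = {
    "S1": (52.8, 72.8), "S2": (96.7, 96.7), "S3": (59.4, 69.4),
    "S4": (97.8, 97.8), "S5": (81.1, 95.6), "S6": (71.7, 86.1),
    "S7": (85.0, 86.1), "S8": (87.8, 92.2), "S9": (48.9, 47.8),
    "S10": (55.6, 73.9), "S11": (53.3, 55.0), "S12": (92.8, 98.3),
}
_FBCCA = {
    "S1": (60.6, 71.7), "S2": (96.1, 96.7), "S3": (58.9, 68.3),
    "S4": (97.8, 97.8), "S5": (80.0, 95.6), "S6": (76.1, 85.6),
    "S7": (86.7, 86.1), "S8": (82.2, 87.8), "S9": (47.8, 45.0),
    "S10": (61.1, 78.3), "S11": (51.1, 53.7), "S12": (88.9, 95.0),
}

# pooled regression-coefficient statistics per auxiliary channel:
# mean |beta|, SD, CV
_BETA_SUMMARY = {
    "Cz": (0.416, 0.175, 0.42),
    "Fp1": (0.115, 0.144, 1.25),
    "HEOG": (0.136, 0.162, 1.19),
    "neck": (0.097, 0.079, 0.82),
    "cheek": (0.127, 0.164, 1.28),
    "jaw": (0.132, 0.199, 1.51),
}

# per-subject mean |beta| per auxiliary channel
_BETA_PER_SUBJECT = {
    "S1": (0.518, 0.074, 0.082, 0.165, 0.109, 0.040),
    "S2": (0.399, 0.071, 0.124, 0.106, 0.081, 0.278),
    "S3": (0.398, 0.073, 0.126, 0.062, 0.090, 0.114),
    "S4": (0.425, 0.143, 0.088, 0.152, 0.111, 0.073),
    "S5": (0.291, 0.139, 0.136, 0.139, 0.153, 0.163),
    "S6": (0.310, 0.108, 0.140, 0.123, 0.161, 0.182),
    "S7": (0.379, 0.067, 0.100, 0.112, 0.142, 0.115),
    "S8": (0.354, 0.112, 0.098, 0.146, 0.138, 0.097),
    "S9": (0.426, 0.118, 0.120, 0.092, 0.136, 0.089),
    "S10": (0.405, 0.102, 0.132, 0.129, 0.149, 0.141),
    "S11": (0.386, 0.083, 0.096, 0.108, 0.130, 0.127),
    "S12": (0.373, 0.094, 0.109, 0.115, 0.144, 0.121),
}


def _acc_frame(table: dict[str, tuple[float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s, *table[s]) for s in SUBJECTS],
        columns=["subject", "o_only", "o_clean"],
    )
    df["improvement"] = np.round(df.o_clean - df.o_only, 1)
    return df


def svm_accuracy_table() -> pd.DataFrame:
    """Per-subject linear-SVM LOSO accuracies (%), raw vs cleaned."""
    return _acc_frame(_SVM)


def cnn_accuracy_table() -> pd.DataFrame:
    """Per-subject compact-network LOSO accuracies (%), raw vs cleaned."""
    return _acc_frame(_CNN)


def cca_accuracy_table() -> pd.DataFrame:
    """Per-subject CCA LOSO accuracies (%), raw vs cleaned."""
    return _acc_frame(_CCA)


def fbcca_accuracy_table() -> pd.DataFrame:
    """Per-subject FBCCA LOSO accuracies (%), raw vs cleaned."""
    return _acc_frame(_FBCCA)


def beta_summary_table() -> pd.DataFrame:
    """Pooled mean |beta|, SD and CV per auxiliary channel."""
    df = pd.DataFrame.from_dict(
        _BETA_SUMMARY, orient="index", columns=["mean_abs_beta", "sd", "cv"]
    )
    df.index.name = "auxiliary"
    return df


def beta_per_subject_table() -> pd.DataFrame:
    """Per-subject mean |beta| per auxiliary channel."""
    return pd.DataFrame.from_dict(
        _BETA_PER_SUBJECT,
        orient="index",
        columns=["Cz", "Fp1", "HEOG", "neck", "cheek", "jaw"],
    ).rename_axis("subject")
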