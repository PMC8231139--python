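"""Evaluation machinery: Dice overlap, Bland-Altman agreement, subject-level
data splitting, and equal-interval movement-cycle frame selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLASS_NAMES, N_CLASSES

__all__ = [
    "AgreementStats",
    "SplitSpec",
    "dice_similarity",
    "bland_altman",
    "subject_split",
    "select_cycle_frames",
    "evaluate_segmentation",
]


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired differences d = x - y.

    ``limits_of_agreement`` are the standard mean +/- 1.96 SD bounds that
    contain ~95% of differences for Gaussian-distributed disagreement.
    """

    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    n: int


@dataclass
class SplitSpec:
    """Subject-level split description.

    ``wrists_per_subject`` and ``frames_per_wrist`` describe a balanced
    cohort (the reference protocol: 28 subjects x 2 wrists x 15 selected
    frames, 21 subjects for training).
    """

    n_subjects: int = 28
    wrists_per_subject: int = 2
    frames_per_wrist: int = 15
    n_train_subjects: int = 21
    seed: int = 0


def dice_similarity(a: np.ndarray, b: np.ndarray, class_id: int) -> float:
    """Dice similarity coefficient 2|A.B| / (|A| + |B|) of one class.

    1 means complete overlap, 0 no overlap.  When the class is absent in
    both masks the DSC is defined as 1 (perfect agreement on absence).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("masks must have identical shapes")
    am = a == class_id
    bm = b == class_id
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(am, bm).sum() / denom)


def bland_altman(x, y) -> AgreementStats:
    """Agreement statistics of two paired measurement series (d = x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need 1D series with n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(mean_difference=mean, sd_difference=sd,
                          limits_of_agreement=(mean - 1.96 * sd, mean + 1.96 * sd),
                          n=len(d))


def plot_bland_altman(x, y, ax=None, label_x="mean of methods",
                      label_y="difference"):
    """Bland-Altman scatter with mean-difference and limit lines.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt
    stats = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2, x - y, s=12, alpha=0.7)
    ax.axhline(stats.mean_difference, color="k")
    for lim in stats.limits_of_agreement:
        ax.axhline(lim, color="gray", linestyle="--")
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    return ax


def subject_split(spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded subject-level partition into train/test subject indices.

    Both wrists (and all frames) of a subject land on the same side, so
    no subject leaks across the split.  Returns (train_subjects,
    test_subjects) as sorted index arrays.
    """
    if spec.n_train_subjects > spec.n_subjects or spec.n_train_subjects < 0:
        raise ValueError("impossible split: n_train_subjects outside 0..n_subjects")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_subjects)
    train = np.sort(order[:spec.n_train_subjects])
    test = np.sort(order[spec.n_train_subjects:])
    return train, test


def split_image_counts(spec: SplitSpec) -> tuple[int, int]:
    """(train, test) image counts implied by a balanced cohort split."""
    per_subject = spec.wrists_per_subject * spec.frames_per_wrist
    train, test = subject_split(spec)
    return len(train) * per_subject, len(test) * per_subject


def select_cycle_frames(n_cycle_frames: int, n_select: int = 15) -> np.ndarray:
    """Equal-temporal-interval frame subsampling of one movement cycle.

    Returns ``n_select`` strictly increasing indices spanning frame 0 to
    the last frame, at (near-)equal spacing: index_k = round-half-up of
    k * (L - 1) / (n - 1).
    """
    if n_cycle_frames < n_select:
        raise ValueError("cycle shorter than the number of frames to select")
    if n_select == 1:
        return np.array([0])
    k = np.arange(n_select)
    idx = np.floor(k * (n_cycle_frames - 1) / (n_select - 1) + 0.5).astype(int)
    return idx


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-class DSC table (mean +/- SD over frames) for aligned sequences.

    DSC is computed per frame and class, then averaged over frames.  Rows
    are the bone classes present in either sequence plus an ``overall``
    row averaging all per-frame, per-class values.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("sequences must be aligned")
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    classes = sorted(set(np.unique(pred)) | set(np.unique(truth)))
    classes = [c for c in classes if 0 < c <= N_CLASSES]
    rows = []
    all_vals = []
    for c in classes:
        vals = [dice_similarity(p, t, c) for p, t in zip(pred, truth)]
        all_vals.extend(vals)
        rows.append({"class_id": int(c), "class_name": CLASS_NAMES[int(c)],
                     "dsc_mean": float(np.mean(vals)), "dsc_sd": float(np.std(vals)),
                     "n_frames": len(vals)})
    if not rows:
        import warnings
        warnings.warn("no foreground classes found in either sequence")
        return pd.DataFrame(columns=["class_id", "class_name", "dsc_mean",
                                     "dsc_sd", "n_frames"])
    rows.append({"class_id": 0, "class_name": "overall",
                 "dsc_mean": float(np.mean(all_vals)), "dsc_sd": float(np.std(all_vals)),
                 "n_frames": len(pred)})
    return pd.DataFrame(rows)
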