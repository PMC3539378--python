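"""ROC analysis and the evaluation protocols.

Classifier quality is summarized by the area under the ROC curve (A_z),
computed by the trapezoidal rule over the threshold sweep of the
continuous decision scores.  With tie handling this equals the normalized
Mann-Whitney U statistic, so a reasonable classifier satisfies
0.5 <= A_z <= 1 and an uninformative one sits at 0.5.

Two protocols are provided: a stratified half/half train/test split
(mirroring a 500-train / 500-test design at any scale) and leave-one-out
scoring where each sample is scored by a model trained on the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "ROCResult",
    "roc_auc",
    "split_eval",
    "leave_one_out_eval",
    "plot_roc",
]


@dataclass
class ROCResult:
    """ROC curve points and the area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    protocol: str = "none"
    extra: dict = field(default_factory=dict)


def roc_auc(scores: np.ndarray, labels: np.ndarray, protocol: str = "none") -> ROCResult:
    """ROC curve and trapezoidal AUC from continuous scores.

    The curve runs from (0, 0) to (1, 1); the trapezoidal area equals the
    tie-corrected Mann-Whitney statistic
    ``(#[s_pos > s_neg] + 0.5 * #[s_pos == s_neg]) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.int64)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, thr, auc, n_pos, n_neg, protocol)


def split_eval(
    features: np.ndarray,
    labels: np.ndarray,
    classifier,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> ROCResult:
    """Stratified random split: train on one half, score the held-out half."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).ravel().astype(np.int64)
    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    classifier.fit(X[train_idx], y[train_idx])
    scores = classifier.decision_scores(X[test_idx])
    result = roc_auc(scores, y[test_idx], protocol="split")
    result.extra.update(
        {
            "train_index": train_idx,
            "test_index": test_idx,
            "seed": seed,
            "test_fraction": test_fraction,
        }
    )
    return result


def leave_one_out_eval(
    features: np.ndarray, labels: np.ndarray, classifier
) -> np.ndarray:
    """Score every sample with a model trained on the remaining n-1.

    Returns the n held-out scores (feed them to :func:`roc_auc`).  The
    classifier object is refitted in place for each fold.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).ravel().astype(np.int64)
    n = y.size
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        classifier.fit(X[mask], y[mask])
        scores[i] = float(np.asarray(classifier.decision_scores(X[i : i + 1])).ravel()[0])
    return scores


def plot_roc(result: ROCResult, path: str) -> None:
    """Write a ROC curve plot as PNG (matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(result.fpr, result.tpr, label=f"A_z = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(f"ROC ({result.protocol}), n={result.n_pos + result.n_neg}")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
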