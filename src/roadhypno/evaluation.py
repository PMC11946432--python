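"""Regression metrics and grouped K-fold cross-validation.

Six regression metrics score the continuous hypnosis-degree (or posterior)
readout against the numeric state label; classification accuracy scores the
Viterbi path.  Cross-validation folds are formed at the recording level —
whole driver sessions move between train and validation together — so the
decoder is never trained and tested on temporally adjacent rows of the same
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .fusion import FeatureMatrix, STATES

__all__ = ["EvalReport", "regression_metrics", "accuracy", "kfold_cv"]


@dataclass
class EvalReport:
    """Regression metrics plus per-fold classification accuracies."""

    mse: float | None = None
    rmse: float | None = None
    mae: float | None = None
    max_error: float | None = None
    r2: float | None = None
    ev: float | None = None
    degenerate_target: bool = False  # Var(y)=0: r2/ev undefined
    fold_accuracies: list[float] = field(default_factory=list)
    fold_segment_accuracies: list[float] = field(default_factory=list)
    mean_accuracy: float | None = None
    mean_segment_accuracy: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "mse": self.mse, "rmse": self.rmse, "mae": self.mae,
            "max_error": self.max_error, "r2": self.r2, "ev": self.ev,
            "degenerate_target": self.degenerate_target,
            "fold_accuracies": self.fold_accuracies,
            "fold_segment_accuracies": self.fold_segment_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "mean_segment_accuracy": self.mean_segment_accuracy,
            "seed": self.seed,
        }


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """MSE, RMSE, MAE, maximum error, R² and explained variance.

    Variances are population variances (divisor n).  When ``Var(y) = 0``
    the report flags R² and EV as undefined instead of dividing by zero.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    resid = y - p
    mse = float(np.mean(resid**2))
    report = EvalReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(resid))),
        max_error=float(np.max(np.abs(resid))),
    )
    var_y = float(np.var(y))
    if var_y > 0:
        report.r2 = 1.0 - mse / var_y
        report.ev = 1.0 - float(np.var(resid)) / var_y
    else:
        report.degenerate_target = True
    return report


def accuracy(true_labels: np.ndarray, decoded_labels: np.ndarray) -> float:
    """Fraction of grid rows whose decoded state equals the label."""
    t = np.asarray(true_labels)
    d = np.asarray(decoded_labels)
    if t.shape != d.shape:
        raise ValueError("label arrays must have equal length")
    return float(np.mean(t == d))


def _segment_accuracy(true_labels: np.ndarray, decoded_labels: np.ndarray) -> float:
    """Fraction of maximal constant-label segments decoded correctly.

    A segment counts as correct when the majority of its rows are decoded
    as its label.
    """
    t = np.asarray(true_labels)
    d = np.asarray(decoded_labels)
    boundaries = np.flatnonzero(t[1:] != t[:-1]) + 1
    edges = np.concatenate([[0], boundaries, [len(t)]])
    hits = 0
    n_seg = len(edges) - 1
    for a, b in zip(edges[:-1], edges[1:]):
        hits += np.mean(d[a:b] == t[a]) > 0.5
    return hits / n_seg


def kfold_cv(matrices: list[FeatureMatrix], k: int = 5,
             config: RunConfig | None = None, seed: int = 0) -> EvalReport:
    """Grouped K-fold cross-validation of the full hybrid decoder.

    Recordings (not rows) are shuffled once with ``seed`` and split into K
    near-equal folds; each fold is decoded by a model trained on the other
    K−1 folds.  The headline accuracy is the mean of the per-fold row
    accuracies; segment-level accuracies are reported alongside.  The
    regression metrics score the pooled hypnosis posterior against the 0/1
    row label.
    """
    from . import hybrid_hmm  # late import: avoids a module cycle

    if k > len(matrices):
        raise ValueError(f"K={k} exceeds the number of recordings ({len(matrices)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(matrices))
    folds = np.array_split(order, k)
    fold_acc, fold_seg = [], []
    pooled_y, pooled_p = [], []
    for fold in folds:
        val_idx = set(int(i) for i in fold)
        train_ms = [m for i, m in enumerate(matrices) if i not in val_idx]
        bundle = hybrid_hmm.train_from_matrices(train_ms, config)
        accs, segs = [], []
        for i in sorted(val_idx):
            m = matrices[i]
            result = hybrid_hmm.predict(m, bundle)
            accs.append(accuracy(m.labels, result.viterbi_labels))
            segs.append(_segment_accuracy(m.labels, result.viterbi_labels))
            pooled_y.append((np.asarray(m.labels) == STATES[1]).astype(float))
            pooled_p.append(result.posteriors[:, 1])
        fold_acc.append(float(np.mean(accs)))
        fold_seg.append(float(np.mean(segs)))
    report = regression_metrics(np.concatenate(pooled_y), np.concatenate(pooled_p))
    report.fold_accuracies = fold_acc
    report.fold_segment_accuracies = fold_seg
    report.mean_accuracy = float(np.mean(fold_acc))
    report.mean_segment_accuracy = float(np.mean(fold_seg))
    report.seed = seed
    return report
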