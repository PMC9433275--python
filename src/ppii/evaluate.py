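"""Binary classification metrics (Sens/Spec/ACC/MCC, ROC/AUC) and the two
hyperparameter sweep harnesses (window size and kernel combinations).

MCC with any zero marginal is reported as 0 (the correlation is undefined
there); the decision threshold on the PPII probability defaults to 0.5 and
uses the >= rule, with half credit for score ties inside the AUC statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .dataset import (LabeledSequence, make_all_windows, split,
                      undersample_balance)
from .errors import ConfigError, InputError
from .model import CNNConfig, EncoderConfig, TrainConfig, train

logger = logging.getLogger(__name__)

KERNEL_COMBINATIONS = (
    (3,), (3, 4), (3, 4, 5), (3, 4, 5, 6), (3, 4, 5, 6, 7),
)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise InputError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sens: float
    spec: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    threshold: float = 0.5


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def _check_scores(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or len(labels) == 0:
        raise InputError("labels and scores must be equal-length nonempty 1-D")
    if not set(np.unique(labels)) <= {0, 1}:
        raise InputError("labels must be binary {0, 1}")
    return labels.astype(int), scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Counts at the given operating point; score >= threshold is positive."""
    labels, scores = _check_scores(labels, scores)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def metrics(c: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Sens = TP/(TP+FN), Spec = TN/(TN+FP), ACC = (TP+TN)/total and the
    Matthews correlation coefficient; degenerate denominators fall back to
    0 (logged), the standard convention where the quantity is undefined."""
    def _ratio(num, den, name):
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting 0",
                           name)
            return 0.0
        return num / den

    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        logger.warning("MCC undefined (zero marginal); reporting 0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / denom
    return MetricsReport(sens=sens, spec=spec, acc=acc, mcc=mcc,
                         threshold=threshold)


def roc_auc(labels, scores) -> tuple[ROCCurve, float]:
    """ROC over all distinct score thresholds and the trapezoid AUC, which
    equals P(score_pos > score_neg) + 0.5 P(tie)."""
    labels, scores = _check_scores(labels, scores)
    if len(np.unique(labels)) < 2:
        raise InputError("AUC undefined: only one class present")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr), \
        float(_trapezoid_auc(fpr, tpr))


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics plus AUC in one report."""
    report = metrics(confusion(labels, scores, threshold), threshold)
    report.auc = roc_auc(labels, scores)[1]
    return report


def _train_eval_cycle(sequences: Sequence[LabeledSequence], window: int,
                      encoder: EncoderConfig, cnn: CNNConfig,
                      train_cfg: TrainConfig, seed: int,
                      threshold: float) -> MetricsReport:
    samples = make_all_windows(sequences, window)
    ss = np.random.SeedSequence(seed)
    bal_seed, split_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                            for s in ss.spawn(2))
    balanced = undersample_balance(samples, seed=bal_seed)
    ds = split(balanced, "balanced_4to1", seed=split_seed)
    model, _ = train(ds, encoder, cnn, replace(train_cfg, seed=seed))
    scores = model.predict_samples(ds.val)
    ys = np.array([s.label for s in ds.val])
    return evaluate_scores(ys, scores, threshold)


def window_sweep(sequences: Sequence[LabeledSequence],
                 sizes: Sequence[int],
                 encoder: EncoderConfig, cnn: CNNConfig,
                 train_cfg: TrainConfig, seed: int = 0,
                 threshold: float = 0.5) -> pd.DataFrame:
    """One train/evaluate cycle per window size on identically seeded
    balance/split decisions; rows ordered as given."""
    for w in sizes:
        if w < 3 or w % 2 == 0:
            raise ConfigError(f"window sizes must be odd and >= 3, got {w}")
    rows = []
    for w in sizes:
        rep = _train_eval_cycle(sequences, w, encoder, cnn, train_cfg,
                                seed, threshold)
        rows.append({"window": w, "sens": rep.sens, "spec": rep.spec,
                     "mcc": rep.mcc, "acc": rep.acc, "auc": rep.auc})
    return pd.DataFrame(rows)


def kernel_sweep(sequences: Sequence[LabeledSequence],
                 combinations: Sequence[Sequence[int]] = KERNEL_COMBINATIONS,
                 window: int = 15,
                 encoder: Optional[EncoderConfig] = None,
                 cnn: Optional[CNNConfig] = None,
                 train_cfg: Optional[TrainConfig] = None,
                 seed: int = 0, threshold: float = 0.5) -> pd.DataFrame:
    """Train/evaluate once per kernel-size combination (n-gram channel set)
    at a fixed window; emits the Sens/Spec/MCC/ACC comparison table."""
    encoder = encoder or EncoderConfig.tiny()
    base_cnn = cnn or CNNConfig.tiny()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for combo in combinations:
        combo = tuple(combo)
        if max(combo) > window:
            raise ConfigError(f"kernel {max(combo)} exceeds window {window}")
        rep = _train_eval_cycle(
            sequences, window, encoder,
            replace(base_cnn, kernel_sizes=combo), train_cfg, seed, threshold)
        rows.append({
            "kernels": "_".join(str(m) for m in combo) + "_kernel",
            "sens": rep.sens, "spec": rep.spec, "mcc": rep.mcc,
            "acc": rep.acc, "auc": rep.auc})
    return pd.DataFrame(rows)


def write_roc_csv(curve: ROCCurve, path) -> None:
    pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr,
                  "tpr": curve.tpr}).to_csv(path, index=False)


def plot_roc(curves: dict[str, tuple[ROCCurve, float]], path) -> None:
    """Optional ROC overlay plot (one line per labeled curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (curve, area) in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={area:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
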