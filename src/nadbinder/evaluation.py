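"""Cross-validated evaluation of residue classifiers.

Folds are assigned at chain level (a whole sequence, and hence every
window cut from it, lives in exactly one fold) so that overlapping windows
of one protein never appear on both sides of a train/test split.

Threshold-dependent measures follow the standard definitions:

    Sn  = TP / (TP + FN) * 100          (coverage of interacting residues)
    Sp  = TN / (TN + FP) * 100          (coverage of non-interacting residues)
    Acc = (TP + TN) / total * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 (and flagged) when any denominator factor vanishes.
The threshold-independent measure is the ROC curve with trapezoidal AUC,
built from a native sweep over the decision scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .encoding import PSSMProfile, WindowConfig, build_feature_matrix
from .structures import ProteinChain, ResidueLabelSet
from .svm import KernelSpec, ResidueSVC, apply_threshold, balance_dataset

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "ROCCurve",
    "CVPlan",
    "CVResult",
    "confusion",
    "performance",
    "roc_auc",
    "make_folds",
    "cross_validate",
    "sweep_windows",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class PerformanceReport:
    """Sn/Sp/Acc as percentages, MCC in [-1, 1]."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    threshold: float | None = None
    window: int | None = None
    mcc_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC,
            "threshold": self.threshold, "window": self.window,
        }


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class CVPlan:
    k: int
    assignment: dict[str, int]

    def fold_chains(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]


@dataclass
class CVResult:
    mean: PerformanceReport
    per_fold: list[PerformanceReport] = field(default_factory=list)


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        TP=int(((pred == 1) & (truth == 1)).sum()),
        FP=int(((pred == 1) & (truth == 0)).sum()),
        TN=int(((pred == 0) & (truth == 0)).sum()),
        FN=int(((pred == 0) & (truth == 1)).sum()),
    )


def performance(
    counts: ConfusionCounts,
    threshold: float | None = None,
    window: int | None = None,
) -> PerformanceReport:
    """Sn/Sp/Acc/MCC from a 2x2 tally; zero MCC denominator -> MCC 0, flagged."""
    if counts.total == 0:
        raise ValueError("cannot compute performance of an empty evaluation")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    undefined = denom == 0
    mcc = 0.0 if undefined else (tp * tn - fp * fn) / math.sqrt(denom)
    return PerformanceReport(sn, sp, acc, mcc, threshold, window, undefined)


def roc_auc(scores, truth) -> ROCCurve:
    """ROC by sweeping the threshold over all distinct scores (ties grouped);
    AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise ValueError("length mismatch between scores and truth")
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes in the truth vector")
    fpr, tpr, thr = _sk_roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


def make_folds(chain_ids: list[str], k: int = 5, seed: int | None = None) -> CVPlan:
    """Seeded uniform shuffle then round-robin: fold sizes differ by <= 1."""
    ids = list(chain_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} chains, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate chain ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return CVPlan(k, {ids[j]: i % k for i, j in enumerate(order)})


def cross_validate(
    chains: list[ProteinChain],
    labels: list[ResidueLabelSet],
    spec: KernelSpec | str | None = None,
    cfg: WindowConfig | None = None,
    mode: str = "binary",
    profiles: dict[str, PSSMProfile] | None = None,
    k: int = 5,
    seed: int | None = 0,
    balance: str = "equal",
    threshold: float = 0.0,
    scaler: str = "logistic",
) -> CVResult:
    """k-fold chain-level cross-validation of the windowed SVM.

    For each fold the model is trained on the other k-1 folds and scored
    on the held-out fold at ``threshold``; the final report is the
    unweighted mean of the per-fold metrics. In "equal" balance mode the
    negative sample is drawn once per run with ``seed`` and intersected
    with each fold's training chains; evaluation always uses the full
    held-out fold.
    """
    if cfg is None:
        cfg = WindowConfig()
    if spec is None:
        spec = KernelSpec()
    if isinstance(spec, str):
        spec = KernelSpec.from_string(spec)
    X, y, index = build_feature_matrix(chains, labels, mode, cfg, profiles, scaler)
    plan = make_folds([c.id for c in chains], k=k, seed=seed)
    fold_of_row = index["chain_id"].map(plan.assignment).to_numpy()

    train_mask = np.ones(len(y), dtype=bool)
    if balance == "equal":
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        if len(neg_idx) >= len(pos_idx):
            rng = np.random.default_rng(seed)
            keep_neg = rng.choice(neg_idx, size=len(pos_idx), replace=False)
            train_mask = np.zeros(len(y), dtype=bool)
            train_mask[pos_idx] = True
            train_mask[keep_neg] = True
    elif balance != "real":
        raise ValueError(f"balance must be 'equal' or 'real', got {balance!r}")

    per_fold = []
    for fold in range(k):
        tr = (fold_of_row != fold) & train_mask
        te = fold_of_row == fold
        model = ResidueSVC.from_kernel_spec(spec, threshold=threshold, random_state=seed)
        model.fit(X[tr], y[tr])
        pred = apply_threshold(model.decision_function(X[te]), threshold)
        per_fold.append(performance(confusion(pred, y[te]), threshold, cfg.W))
    mean = PerformanceReport(
        Sn=float(np.mean([r.Sn for r in per_fold])),
        Sp=float(np.mean([r.Sp for r in per_fold])),
        Acc=float(np.mean([r.Acc for r in per_fold])),
        MCC=float(np.mean([r.MCC for r in per_fold])),
        threshold=threshold,
        window=cfg.W,
        mcc_undefined=any(r.mcc_undefined for r in per_fold),
    )
    return CVResult(mean, per_fold)


def sweep_windows(
    chains: list[ProteinChain],
    labels: list[ResidueLabelSet],
    spec: KernelSpec | str | None = None,
    W_list: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21),
    mode: str = "binary",
    profiles: dict[str, PSSMProfile] | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """One cross-validated row per window size (columns mirror the usual
    performance tables: window, kernel, thr, Sn, Sp, Acc, MCC)."""
    if spec is None:
        spec = KernelSpec()
    if isinstance(spec, str):
        spec = KernelSpec.from_string(spec)
    rows = []
    for W in W_list:
        res = cross_validate(
            chains, labels, spec, WindowConfig(W), mode, profiles, **cv_kwargs
        )
        rows.append(
            {
                "window": W,
                "kernel": spec.to_string(),
                "thr": res.mean.threshold,
                "Sn": res.mean.Sn,
                "Sp": res.mean.Sp,
                "Acc": res.mean.Acc,
                "MCC": res.mean.MCC,
            }
        )
    return pd.DataFrame(rows, columns=["window", "kernel", "thr", "Sn", "Sp", "Acc", "MCC"])


def plot_roc(curves: dict[str, ROCCurve], path: str) -> None:
    """One ROC curve per labeled model, AUC in the legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} ({curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
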