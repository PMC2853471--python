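"""Kernel-SVM residue classifier.

The decision rule is a standard soft-margin SVM over window features, with
the historical SVM_light-style parameterization: kernel type t (0 linear,
1 polynomial, 2 rbf, 3 sigmoid), degree d, gamma g, cost C and a
cost-factor j that up-weights errors on the positive (interacting) class.
Any standard max-margin solver satisfies the contract; libsvm via
scikit-learn is used here.

Training sets may be balanced ("equal" mode: all positives plus an equal
seeded sample of negatives) or left at the natural ~1:13 imbalance
("real" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.utils.multiclass import check_classification_targets, type_of_target
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "KernelSpec",
    "BalancingWarning",
    "balance_dataset",
    "ResidueSVC",
    "train",
    "decision_scores",
    "apply_threshold",
]

_KERNEL_CODES = {0: "linear", 1: "polynomial", 2: "rbf", 3: "sigmoid"}
_KERNEL_NAMES = {v: k for k, v in _KERNEL_CODES.items()}
_SKLEARN_KERNELS = {
    "linear": "linear",
    "polynomial": "poly",
    "rbf": "rbf",
    "sigmoid": "sigmoid",
}


class BalancingWarning(UserWarning):
    """Emitted when equal-mode balancing is impossible and real mode is used."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel + cost parameters in the short-letter notation t/d/g/j/c."""

    kernel_type: str = "rbf"
    degree: int = 3
    gamma: float = 0.1
    cost: float = 1.0
    cost_factor: float = 1.0

    def __post_init__(self):
        if self.kernel_type not in _SKLEARN_KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel_type!r}; "
                f"expected one of {sorted(_SKLEARN_KERNELS)}"
            )
        if self.cost <= 0 or self.cost_factor <= 0:
            raise ValueError("cost c and cost-factor j must be positive")
        if self.kernel_type == "rbf" and self.gamma <= 0:
            raise ValueError("rbf kernel requires positive gamma g")

    @classmethod
    def from_string(cls, text: str) -> "KernelSpec":
        """Parse a config line like ``t 2 g 0.1 j 1 c 10`` or ``t 1 d 3``."""
        fields = text.replace("=", " ").split()
        if len(fields) % 2:
            raise ValueError(f"cannot parse kernel spec {text!r}")
        kv = dict(zip(fields[::2], fields[1::2]))
        out: dict = {}
        long_names = {
            "t": "kernel_type", "kernel": "kernel_type",
            "d": "degree", "degree": "degree",
            "g": "gamma", "gamma": "gamma",
            "c": "cost", "cost": "cost",
            "j": "cost_factor", "cost_factor": "cost_factor",
        }
        for key, value in kv.items():
            if key not in long_names:
                raise ValueError(f"unknown kernel parameter {key!r} in {text!r}")
            name = long_names[key]
            if name == "kernel_type":
                out[name] = _KERNEL_CODES[int(value)] if value.isdigit() else value
            elif name == "degree":
                out[name] = int(value)
            else:
                out[name] = float(value)
        return cls(**out)

    def to_string(self) -> str:
        parts = [f"t {_KERNEL_NAMES[self.kernel_type]}"]
        if self.kernel_type == "polynomial":
            parts.append(f"d {self.degree}")
        if self.kernel_type in ("rbf", "sigmoid"):
            parts.append(f"g {self.gamma:g}")
        parts.append(f"j {self.cost_factor:g}")
        parts.append(f"c {self.cost:g}")
        return " ".join(parts)


def balance_dataset(
    pos_rows: np.ndarray,
    neg_rows: np.ndarray,
    seed: int | None = None,
    mode: str = "equal",
) -> tuple[np.ndarray, np.ndarray]:
    """Build a training set from class-separated rows.

    "equal": all positives plus a seeded uniform sample (without
    replacement) of as many negatives. "real": everything, unchanged.
    Returns (X, y). If equal mode is requested with fewer negatives than
    positives, a :class:`BalancingWarning` is emitted and real mode used.
    """
    pos_rows = np.asarray(pos_rows)
    neg_rows = np.asarray(neg_rows)
    if mode not in ("equal", "real"):
        raise ValueError(f"mode must be 'equal' or 'real', got {mode!r}")
    if mode == "equal":
        if len(neg_rows) < len(pos_rows):
            warnings.warn(
                f"cannot balance: {len(neg_rows)} negatives < {len(pos_rows)} "
                "positives; falling back to real mode",
                BalancingWarning,
                stacklevel=2,
            )
        else:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(neg_rows), size=len(pos_rows), replace=False)
            neg_rows = neg_rows[np.sort(pick)]
    X = np.vstack([pos_rows, neg_rows])
    y = np.concatenate([np.ones(len(pos_rows), dtype=int), np.zeros(len(neg_rows), dtype=int)])
    return X, y


class ResidueSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin kernel SVM for per-residue interaction calls.

    Parameters
    ----------
    kernel : {'linear', 'polynomial', 'rbf', 'sigmoid'}, default 'rbf'
    degree : int, default 3
        Polynomial degree d.
    gamma : float, default 0.1
        Kernel coefficient g for rbf/sigmoid/polynomial.
    C : float, default 1.0
        Soft-margin cost c.
    cost_factor : float, default 1.0
        Weight j on positive-class training errors (class_weight {1: j}).
    threshold : float, default 0.0
        Decision-score cut: predict interacting iff score >= threshold
        (ties count as positive). Lower values trade specificity for
        sensitivity.
    balance : {'none', 'equal'}, default 'none'
        'equal' down-samples training negatives to the positive count
        using ``random_state``.
    random_state : int or None
        Seed for negative down-sampling.

    Attributes
    ----------
    svc_ : fitted sklearn.svm.SVC
    classes_ : ndarray [0, 1]
    n_features_in_ : int
    n_pos_, n_neg_ : training class counts after balancing
    """

    def __init__(
        self,
        kernel: str = "rbf",
        degree: int = 3,
        gamma: float = 0.1,
        C: float = 1.0,
        cost_factor: float = 1.0,
        threshold: float = 0.0,
        balance: str = "none",
        random_state: int | None = None,
    ):
        self.kernel = kernel
        self.degree = degree
        self.gamma = gamma
        self.C = C
        self.cost_factor = cost_factor
        self.threshold = threshold
        self.balance = balance
        self.random_state = random_state

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.multi_class = False
        return tags

    @classmethod
    def from_kernel_spec(cls, spec: KernelSpec | str, **kwargs) -> "ResidueSVC":
        if isinstance(spec, str):
            spec = KernelSpec.from_string(spec)
        return cls(
            kernel=spec.kernel_type,
            degree=spec.degree,
            gamma=spec.gamma,
            C=spec.cost,
            cost_factor=spec.cost_factor,
            **kwargs,
        )

    @property
    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(self.kernel, self.degree, self.gamma, self.C, self.cost_factor)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        check_classification_targets(y)
        y_type = type_of_target(y, input_name="y")
        if y_type != "binary":
            raise ValueError(
                f"Only binary classification is supported. The type of the "
                f"target is {y_type}."
            )
        self._label_encoder_ = LabelEncoder().fit(y)
        self.classes_ = self._label_encoder_.classes_
        if len(self.classes_) < 2:
            raise ValueError(
                "Classifier can't train when only one class is present "
                "(got 1 class)"
            )
        y = self._label_encoder_.transform(y)
        if self.balance == "equal":
            X, y = balance_dataset(X[y == 1], X[y == 0], seed=self.random_state)
        elif self.balance != "none":
            raise ValueError(f"balance must be 'none' or 'equal', got {self.balance!r}")
        self.n_pos_ = int((y == 1).sum())
        self.n_neg_ = int((y == 0).sum())
        self.svc_ = SVC(
            kernel=_SKLEARN_KERNELS[self.kernel],
            degree=self.degree,
            gamma=self.gamma,
            C=self.C,
            class_weight={0: 1.0, 1: self.cost_factor},
            random_state=self.random_state,
        )
        self.svc_.fit(X, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margin score per row; larger = more interacting-like."""
        check_is_fitted(self, "svc_")
        X = validate_data(self, X, reset=False, dtype=float)
        scores = self.svc_.decision_function(X)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite decision scores")
        return scores

    def predict(self, X) -> np.ndarray:
        calls = apply_threshold(self.decision_function(X), self.threshold)
        return self.classes_[calls]


def train(
    features: np.ndarray,
    labels: np.ndarray,
    spec: KernelSpec | str | None = None,
    seed: int | None = None,
    balance: str = "none",
) -> ResidueSVC:
    """Fit a :class:`ResidueSVC` from a kernel spec (default rbf g=0.1 c=1 j=1)."""
    features = np.asarray(features, dtype=float)
    if features.size == 0:
        raise ValueError("empty feature matrix")
    if spec is None:
        spec = KernelSpec()
    model = ResidueSVC.from_kernel_spec(spec, balance=balance, random_state=seed)
    return model.fit(features, labels)


def decision_scores(model: ResidueSVC, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features.reshape(1, -1)
    return model.decision_function(features)


def apply_threshold(scores: np.ndarray, thr: float) -> np.ndarray:
    """Binary predictions: 1 iff score >= thr (tie counts as positive)."""
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    return (np.asarray(scores) >= thr).astype(int)
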