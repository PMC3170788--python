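"""SVM classification on precomputed fused kernels and confusion-group refinement.

The global stage is a one-vs-one multi-class SVM trained on the fused kernel
over all classes. Some modality groups — by default {CT, MR, XR}, {NM, PET}
and {GX, PX} — are systematically confused with each other by the global
classifier; for each such group a *local* SVM is trained only on the group's
training samples, with the per-feature mean-distance normalizers gamma_m
recomputed on that subset so that within-group contrasts are no longer
drowned out by the much larger between-group distances. At prediction time a
sample whose global label falls inside a group is re-decided by that group's
local classifier (single pass, groups are disjoint); predictions outside all
groups are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from modclass.kernels import (
    compute_gamma,
    cross_distances,
    jkec_combine,
    pairwise_distances,
    rbf_kernel,
)

DEFAULT_LABELS = ("CT", "GX", "MR", "NM", "PET", "PX", "US", "XR")
DEFAULT_CONFUSION_GROUPS = (("CT", "MR", "XR"), ("NM", "PET"), ("GX", "PX"))


def define_confusion_groups(groups=None) -> list[frozenset[str]]:
    """Validated list of disjoint confusion groups (default: the three modality groups)."""
    raw = DEFAULT_CONFUSION_GROUPS if groups is None else groups
    out: list[frozenset[str]] = []
    seen: set[str] = set()
    for g in raw:
        fs = frozenset(g)
        if len(fs) < 2:
            raise ValueError(f"confusion group {sorted(fs)} must have >= 2 members")
        if fs & seen:
            raise ValueError(f"confusion groups overlap on {sorted(fs & seen)}")
        seen |= fs
        out.append(fs)
    return out


def train_global(fused_kernel: np.ndarray, labels, c_param: float = 1.0) -> SVC:
    """One-vs-one multi-class SVM on a precomputed square train kernel."""
    k = np.asarray(fused_kernel, dtype=float)
    y = np.asarray(labels)
    if c_param <= 0:
        raise ValueError("c_param must be positive")
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"train kernel must be square, got {k.shape}")
    if y.shape[0] != k.shape[0]:
        raise ValueError(f"kernel order {k.shape[0]} != label count {y.shape[0]}")
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least 2 distinct labels")
    svm = SVC(C=c_param, kernel="precomputed")
    svm.fit(k, y)
    return svm


def fuse_train_kernels(
    features: dict[str, np.ndarray],
    metrics: dict[str, str],
) -> tuple[np.ndarray, dict[str, float], dict[str, np.ndarray]]:
    """Per-feature distances -> gammas -> kernels -> fused train kernel.

    Returns (fused kernel, gamma per feature, kernel per feature).
    """
    gammas: dict[str, float] = {}
    per_feature: dict[str, np.ndarray] = {}
    for name, mat in features.items():
        d = pairwise_distances(mat, metrics[name])
        gammas[name] = compute_gamma(d)
        per_feature[name] = rbf_kernel(d, gammas[name])
    fused = jkec_combine(list(per_feature.values()))
    return fused, gammas, per_feature


def fuse_test_kernels(
    test_features: dict[str, np.ndarray],
    train_features: dict[str, np.ndarray],
    gammas: dict[str, float],
    metrics: dict[str, str],
) -> np.ndarray:
    """Fused test-vs-train kernel using the stored training gammas."""
    if set(test_features) != set(train_features):
        raise ValueError(
            f"feature sets differ: {sorted(test_features)} vs {sorted(train_features)}"
        )
    kernels = []
    for name in train_features:
        d = cross_distances(test_features[name], train_features[name], metrics[name])
        kernels.append(rbf_kernel(d, gammas[name]))
    return jkec_combine(kernels)


@dataclass
class LocalModel:
    """Group-restricted SVM with its own subset features and gammas."""

    group: frozenset[str]
    svm: SVC
    train_features: dict[str, np.ndarray]
    gammas: dict[str, float]
    metrics: dict[str, str]

    def predict(self, test_features: dict[str, np.ndarray]) -> np.ndarray:
        k = fuse_test_kernels(test_features, self.train_features, self.gammas, self.metrics)
        return self.svm.predict(k)


def train_local(
    features: dict[str, np.ndarray],
    labels,
    group: frozenset[str],
    metrics: dict[str, str],
    c_param: float = 1.0,
) -> LocalModel | None:
    """Train the group's local SVM on the samples whose true label is in the group.

    gamma_m is recomputed on the group subset. Returns None (with a warning)
    when fewer than two of the group's classes are present in the data.
    """
    y = np.asarray(labels)
    mask = np.isin(y, list(group))
    present = set(y[mask].tolist())
    if len(present) < 2:
        warnings.warn(
            f"confusion group {sorted(group)}: only {len(present)} class(es) present; "
            "skipping local classifier",
            stacklevel=2,
        )
        return None
    sub = {name: mat[mask] for name, mat in features.items()}
    fused, gammas, _ = fuse_train_kernels(sub, metrics)
    svm = train_global(fused, y[mask], c_param)
    return LocalModel(group=frozenset(group), svm=svm, train_features=sub, gammas=gammas, metrics=dict(metrics))


def refine_predictions(
    global_preds,
    test_features: dict[str, np.ndarray],
    local_models: list[LocalModel],
) -> np.ndarray:
    """Single-pass refinement: re-decide samples globally predicted inside a group.

    A sample whose global label belongs to a group with a trained local model
    gets that model's prediction (necessarily within the group); every other
    sample is returned unchanged.
    """
    preds = np.asarray(global_preds).copy()
    for lm in local_models:
        if lm is None:
            continue
        mask = np.isin(preds, list(lm.group))
        if not mask.any():
            continue
        sub = {name: mat[mask] for name, mat in test_features.items()}
        preds[mask] = lm.predict(sub)
    return preds


@dataclass
class PredictionReport:
    """Per-sample predictions plus accuracy and Table-style confusion summary."""

    sample_ids: list[str]
    global_labels: np.ndarray
    refined_labels: np.ndarray
    true_labels: np.ndarray | None = None
    confusion: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def accuracy(self, refined: bool = True) -> float:
        if self.true_labels is None:
            raise ValueError("no ground truth in this report")
        if self.n == 0:
            return float("nan")
        preds = self.refined_labels if refined else self.global_labels
        return float(np.mean(preds == self.true_labels))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": self.sample_ids,
            "global_label": self.global_labels,
            "refined_label": self.refined_labels,
        }
        if self.true_labels is not None:
            data["true_label"] = self.true_labels
        return pd.DataFrame(data)


def confusion_matrix_percent(y_true, y_pred, labels) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent (rows = true class).

    Each row with nonzero support sums to 100; zero-support rows are NaN.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    labels = list(labels)
    counts = np.zeros((len(labels), len(labels)))
    index = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(yt, yp):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / support
    return pd.DataFrame(pct, index=labels, columns=labels)
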