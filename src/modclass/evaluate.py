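"""Evaluation drivers: stratified cross-validation, fixed splits, metric comparison.

Cross-validation reports three conditions per fold, mirroring the standard
ablation: all visual features fused; visual + textual; and visual + textual
with confusion-group refinement. Everything fold-dependent (codebook, gammas,
SVMs, local classifiers) is trained on the training folds only; per-sample
quantities that cannot leak (histograms of a single image, SIFT descriptors,
caption keyword vectors) are computed once and reused across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from modclass.classifier import (
    PredictionReport,
    confusion_matrix_percent,
    define_confusion_groups,
    fuse_test_kernels,
    fuse_train_kernels,
    refine_predictions,
    train_global,
    train_local,
)
from modclass.config import ExperimentConfig
from modclass.features_bow import build_codebook
from modclass.kernels import compute_gamma, cross_distances, pairwise_distances, rbf_kernel
from modclass.pipeline import (
    bow_features,
    compute_descriptors,
    fixed_visual_features,
    load_vocabulary,
    text_features,
)

logger = logging.getLogger("modclass")

CONDITIONS = ("visual", "visual_textual", "visual_textual_refined")


@dataclass
class CrossValResult:
    """Per-fold predictions for each condition plus recomputable aggregates."""

    conditions: tuple[str, ...]
    fold_true: list[np.ndarray] = field(default_factory=list)
    fold_preds: dict[str, list[np.ndarray]] = field(default_factory=dict)
    fold_test_idx: list[np.ndarray] = field(default_factory=list)

    def fold_accuracies(self, condition: str) -> list[float]:
        return [
            float(np.mean(p == t))
            for p, t in zip(self.fold_preds[condition], self.fold_true)
        ]

    def mean_accuracy(self, condition: str) -> float:
        return float(np.mean(self.fold_accuracies(condition)))

    def aggregate_accuracy(self, condition: str) -> float:
        """Pooled accuracy recomputed from the per-sample outputs."""
        preds = np.concatenate(self.fold_preds[condition])
        truth = np.concatenate(self.fold_true)
        return float(np.mean(preds == truth))

    def frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            for k, acc in enumerate(self.fold_accuracies(cond)):
                rows.append({"condition": cond, "fold": k, "accuracy": acc})
        return pd.DataFrame(rows)


def _fold_models_and_predictions(
    train_feats: dict[str, np.ndarray],
    test_feats: dict[str, np.ndarray],
    y_train: np.ndarray,
    config: ExperimentConfig,
) -> dict[str, np.ndarray]:
    """Train the three conditions on one split and predict the test side."""
    metrics = {name: config.metric_for(name) for name in train_feats}
    train_k, test_k = {}, {}
    for name in train_feats:
        d_train = pairwise_distances(train_feats[name], metrics[name])
        gamma = compute_gamma(d_train)
        train_k[name] = rbf_kernel(d_train, gamma)
        d_test = cross_distances(test_feats[name], train_feats[name], metrics[name])
        test_k[name] = rbf_kernel(d_test, gamma)

    out: dict[str, np.ndarray] = {}
    visual_names = [n for n in train_feats if n != "text"]
    svm_vis = train_global(np.mean([train_k[n] for n in visual_names], axis=0), y_train, config.svm_c)
    out["visual"] = svm_vis.predict(np.mean([test_k[n] for n in visual_names], axis=0))

    all_names = list(train_feats)
    svm_full = train_global(np.mean([train_k[n] for n in all_names], axis=0), y_train, config.svm_c)
    global_preds = svm_full.predict(np.mean([test_k[n] for n in all_names], axis=0))
    out["visual_textual"] = global_preds

    groups = define_confusion_groups(config.confusion_groups)
    present = set(y_train.tolist())
    locals_ = []
    for group in groups:
        if not (group & present):
            continue
        lm = train_local(train_feats, y_train, group, metrics, config.svm_c)
        if lm is not None:
            locals_.append(lm)
    out["visual_textual_refined"] = refine_predictions(global_preds, test_feats, locals_)
    return out


def _precompute(images, captions, config: ExperimentConfig):
    feats = fixed_visual_features(images, config)
    descriptors = compute_descriptors(images, config) if "bow" in config.features else None
    if "text" in config.features:
        feats["text"] = text_features(captions, load_vocabulary(config))
    return feats, descriptors


def _split_features(feats, descriptors, train_idx, test_idx, config):
    train = {n: m[train_idx] for n, m in feats.items()}
    test = {n: m[test_idx] for n, m in feats.items()}
    if descriptors is not None:
        train_desc = [descriptors[i] for i in train_idx]
        stacked = np.vstack(train_desc)
        n_centers = min(config.codebook_size, stacked.shape[0])
        codebook = build_codebook(stacked, n_centers, config.seed, config.kmeans_max_iter)
        train["bow"] = bow_features(train_desc, codebook)
        test["bow"] = bow_features([descriptors[i] for i in test_idx], codebook)
    return train, test


def run_cross_validation(images, captions, labels, config: ExperimentConfig) -> CrossValResult:
    """Stratified k-fold evaluation of the three fusion conditions."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        small = classes[counts < config.n_folds].tolist()
        raise ValueError(f"classes {small} have fewer samples than n_folds={config.n_folds}")
    feats, descriptors = _precompute(images, captions, config)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    result = CrossValResult(conditions=CONDITIONS, fold_preds={c: [] for c in CONDITIONS})
    for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_f, test_f = _split_features(feats, descriptors, train_idx, test_idx, config)
        preds = _fold_models_and_predictions(train_f, test_f, y[train_idx], config)
        result.fold_true.append(y[test_idx])
        result.fold_test_idx.append(test_idx)
        for cond in CONDITIONS:
            result.fold_preds[cond].append(preds[cond])
        logger.info(
            "fold %d: visual=%.3f visual+textual=%.3f +refine=%.3f",
            k,
            np.mean(preds["visual"] == y[test_idx]),
            np.mean(preds["visual_textual"] == y[test_idx]),
            np.mean(preds["visual_textual_refined"] == y[test_idx]),
        )
    return result


def fixed_split_indices(labels, n_train_per_class: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split: first n_train_per_class shuffled samples train, rest test."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) <= n_train_per_class:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples; needs > {n_train_per_class}"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train_per_class])
        test_idx.extend(perm[n_train_per_class:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def run_fixed_split(
    images,
    captions,
    labels,
    config: ExperimentConfig,
    n_train_per_class: int,
    seed: int,
) -> tuple[PredictionReport, dict[str, np.ndarray]]:
    """Train on a per-class random subset, test on the remainder.

    Returns the refined-prediction report (with the row-percent confusion
    matrix) and the per-condition test predictions.
    """
    y = np.asarray(labels)
    train_idx, test_idx = fixed_split_indices(y, n_train_per_class, seed)
    feats, descriptors = _precompute(images, captions, config)
    train_f, test_f = _split_features(feats, descriptors, train_idx, test_idx, config)
    preds = _fold_models_and_predictions(train_f, test_f, y[train_idx], config)
    truth = y[test_idx]
    labels_all = sorted(set(y.tolist()))
    report = PredictionReport(
        sample_ids=[f"t{i:05d}" for i in test_idx],
        global_labels=preds["visual_textual"],
        refined_labels=preds["visual_textual_refined"],
        true_labels=truth,
        confusion=confusion_matrix_percent(truth, preds["visual_textual_refined"], labels_all),
    )
    return report, preds


def compare_metrics(
    images,
    captions,
    labels,
    config: ExperimentConfig,
    n_train_per_class: int,
    seed: int,
) -> pd.DataFrame:
    """Single-feature accuracy for each distance metric on one fixed split.

    Output: one row per (feature, metric) with the global-classifier accuracy
    on the test side — the ablation that motivates the default chi-square
    choice.
    """
    y = np.asarray(labels)
    train_idx, test_idx = fixed_split_indices(y, n_train_per_class, seed)
    feats, descriptors = _precompute(images, captions, config)
    train_f, test_f = _split_features(feats, descriptors, train_idx, test_idx, config)
    rows = []
    for name in config.features:
        for metric in ("L1", "L2", "chi2"):
            d_train = pairwise_distances(train_f[name], metric)
            gamma = compute_gamma(d_train)
            svm = train_global(rbf_kernel(d_train, gamma), y[train_idx], config.svm_c)
            d_test = cross_distances(test_f[name], train_f[name], metric)
            preds = svm.predict(rbf_kernel(d_test, gamma))
            rows.append(
                {
                    "feature": name,
                    "metric": metric,
                    "accuracy": float(np.mean(preds == y[test_idx])),
                }
            )
    return pd.DataFrame(rows)
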