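"""End-to-end composition: extraction -> kernels -> global SVM -> refinement.

`fit` trains the full hierarchical model (global classifier plus one local
classifier per confusion group with enough training classes); `predict`
extracts features for new samples with the training-time configuration,
builds the fused test-vs-train kernel with the stored gammas, and applies the
global classifier followed by the single-pass confusion-group refinement.

Feature bundles are plain ``{feature_name: (n_samples, dim) array}`` dicts,
so adding the textual feature never requires re-extracting visual features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from modclass import io as mio
from modclass.classifier import (
    LocalModel,
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
from modclass.features_bow import Codebook, bow_histogram, build_codebook, image_descriptors
from modclass.features_global import (
    color_histogram,
    edge_histogram,
    gray_histogram,
    standardize,
    variance_histogram,
)
from modclass.features_text import Vocabulary, binary_keyword_histogram, default_vocabulary


def load_vocabulary(config: ExperimentConfig) -> Vocabulary:
    if config.vocabulary_path is None:
        return default_vocabulary()
    return Vocabulary.from_file(config.vocabulary_path)


def compute_descriptors(images, config: ExperimentConfig) -> list[np.ndarray]:
    """Dense SIFT descriptors per standardized image (codebook-independent)."""
    return [
        image_descriptors(
            standardize(img, config.standardize_size), config.patch_size, config.patch_stride
        )
        for img in images
    ]


def fixed_visual_features(images, config: ExperimentConfig) -> dict[str, np.ndarray]:
    """The codebook-independent visual features for a list of images."""
    wanted = [f for f in config.features if f in ("gray", "color", "edge", "variance")]
    rows: dict[str, list[np.ndarray]] = {f: [] for f in wanted}
    for img in images:
        std = standardize(img, config.standardize_size)
        if "gray" in rows:
            rows["gray"].append(gray_histogram(std, config.gray_bins))
        if "color" in rows:
            rows["color"].append(color_histogram(std, config.color_bins))
        if "edge" in rows:
            rows["edge"].append(edge_histogram(std, config.edge_grid, config.edge_bins))
        if "variance" in rows:
            rows["variance"].append(
                variance_histogram(std, config.variance_radius, config.variance_bins)
            )
    return {name: np.asarray(mat) for name, mat in rows.items()}


def bow_features(descriptor_list, codebook: Codebook) -> np.ndarray:
    return np.asarray([bow_histogram(d, codebook) for d in descriptor_list])


def text_features(captions, vocab: Vocabulary) -> np.ndarray:
    return np.asarray([binary_keyword_histogram(c, vocab) for c in captions])


def extract_features(
    images,
    captions,
    config: ExperimentConfig,
    codebook: Codebook | None = None,
    vocab: Vocabulary | None = None,
    descriptors: list[np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Full feature bundle for a sample list under *config*.

    ``codebook`` is required when the bow feature is enabled (it must come
    from training data only); precomputed ``descriptors`` may be passed to
    avoid recomputation across folds.
    """
    features = fixed_visual_features(images, config)
    if "bow" in config.features:
        if codebook is None:
            raise ValueError("bow feature requires a codebook")
        if descriptors is None:
            descriptors = compute_descriptors(images, config)
        features["bow"] = bow_features(descriptors, codebook)
    if "text" in config.features:
        if vocab is None:
            vocab = load_vocabulary(config)
        features["text"] = text_features(captions, vocab)
    return features


@dataclass
class ModalityModel:
    """Trained hierarchical model: global SVM + per-group local SVMs.

    Stores everything prediction needs: training feature bundle (for
    test-vs-train distances), the per-feature gammas frozen at train time,
    the codebook and vocabulary, and the configuration snapshot.
    """

    config: ExperimentConfig
    class_labels: list[str]
    train_labels: np.ndarray
    train_features: dict[str, np.ndarray] = field(repr=False)
    gammas: dict[str, float] = field(default_factory=dict)
    svm: object = None
    local_models: list[LocalModel] = field(default_factory=list)
    codebook: Codebook | None = None
    vocab: Vocabulary | None = None
    train_sample_ids: list[str] = field(default_factory=list)

    @property
    def metrics(self) -> dict[str, str]:
        return {name: self.config.metric_for(name) for name in self.train_features}

    def save(self, directory: str | Path) -> None:
        """Write the model archive: text-only directory, no binary artifacts."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(d / "config.yaml")
        ids = self.train_sample_ids or [f"s{i:05d}" for i in range(len(self.train_labels))]
        (d / "labels.tsv").write_text(
            "\n".join(f"{sid}\t{lab}" for sid, lab in zip(ids, self.train_labels)) + "\n"
        )
        with open(d / "gammas.tsv", "w") as fh:
            for name, g in self.gammas.items():
                fh.write(f"{name}\t{g:.17g}\n")
        for name, mat in self.train_features.items():
            mio.write_feature_matrix(d / f"features_{name}.tsv", ids, mat)
        if self.codebook is not None:
            self.codebook.save(d / "codebook.tsv")
        if self.vocab is not None:
            self.vocab.save(d / "vocabulary.txt")
        # support coefficients for inspection; loading refits deterministically
        with open(d / "svm.tsv", "w") as fh:
            fh.write("# support_index\tdual_coefs...\n")
            for s, coefs in zip(self.svm.support_, self.svm.dual_coef_.T):
                fh.write(str(int(s)) + "\t" + "\t".join(f"{c:.17g}" for c in coefs) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ModalityModel":
        d = Path(directory)
        config = ExperimentConfig.from_yaml(d / "config.yaml")
        pairs = [ln.split("\t") for ln in (d / "labels.tsv").read_text().splitlines() if ln]
        ids = [p[0] for p in pairs]
        labels = np.asarray([p[1] for p in pairs])
        features = {}
        for f in sorted(d.glob("features_*.tsv")):
            name = f.stem.removeprefix("features_")
            _, mat = mio.read_feature_matrix(f)
            features[name] = mat
        codebook = Codebook.load(d / "codebook.tsv") if (d / "codebook.tsv").exists() else None
        vocab = (
            Vocabulary.from_file(d / "vocabulary.txt")
            if (d / "vocabulary.txt").exists()
            else None
        )
        return _assemble_model(features, labels, config, codebook, vocab, ids)


def _assemble_model(features, labels, config, codebook, vocab, sample_ids) -> ModalityModel:
    metrics = {name: config.metric_for(name) for name in features}
    fused, gammas, _ = fuse_train_kernels(features, metrics)
    svm = train_global(fused, labels, config.svm_c)
    groups = define_confusion_groups(config.confusion_groups)
    present = set(np.asarray(labels).tolist())
    local_models = []
    for group in groups:
        if not (group & present):
            continue  # group entirely foreign to this label set: not applicable
        lm = train_local(features, labels, group, metrics, config.svm_c)
        if lm is not None:
            local_models.append(lm)
    return ModalityModel(
        config=config,
        class_labels=sorted(present),
        train_labels=np.asarray(labels),
        train_features=features,
        gammas=gammas,
        svm=svm,
        local_models=local_models,
        codebook=codebook,
        vocab=vocab,
        train_sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def fit(
    images,
    captions,
    labels,
    config: ExperimentConfig | None = None,
    sample_ids=None,
    descriptors: list[np.ndarray] | None = None,
) -> ModalityModel:
    """Train the full pipeline on labeled (image, caption) samples.

    The codebook is built from the training images only. ``descriptors`` may
    carry precomputed per-image SIFT descriptors (for fold reuse).
    """
    config = config or ExperimentConfig()
    labels = np.asarray(labels)
    if len(labels) != len(images):
        raise ValueError("one label per image required")
    codebook = None
    vocab = load_vocabulary(config) if "text" in config.features else None
    if "bow" in config.features:
        if descriptors is None:
            descriptors = compute_descriptors(images, config)
        stacked = np.vstack(descriptors)
        n_centers = min(config.codebook_size, stacked.shape[0])
        codebook = build_codebook(stacked, n_centers, config.seed, config.kmeans_max_iter)
    features = extract_features(images, captions, config, codebook, vocab, descriptors)
    return _assemble_model(features, labels, config, codebook, vocab, sample_ids)


def predict(
    model: ModalityModel,
    images,
    captions,
    sample_ids=None,
    true_labels=None,
    descriptors: list[np.ndarray] | None = None,
) -> PredictionReport:
    """Classify new samples: global prediction plus confusion-group refinement."""
    n = len(images)
    if sample_ids is None:
        sample_ids = [f"t{i:05d}" for i in range(n)]
    if n == 0:
        empty = np.asarray([], dtype=model.train_labels.dtype)
        return PredictionReport(list(sample_ids), empty, empty.copy(), None, None)
    features = extract_features(
        images, captions, model.config, model.codebook, model.vocab, descriptors
    )
    if set(features) != set(model.train_features):
        raise ValueError("extracted feature set does not match the trained model")
    fused = fuse_test_kernels(features, model.train_features, model.gammas, model.metrics)
    global_preds = model.svm.predict(fused)
    refined = refine_predictions(global_preds, features, model.local_models)
    truth = None if true_labels is None else np.asarray(true_labels)
    confusion = None
    if truth is not None:
        labels = sorted(set(model.class_labels) | set(truth.tolist()))
        confusion = confusion_matrix_percent(truth, refined, labels)
    return PredictionReport(list(sample_ids), global_preds, refined, truth, confusion)
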