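"""Experiment configuration: feature toggles, parameters, metrics, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

ALL_FEATURES = ("gray", "color", "edge", "variance", "bow", "text")
VISUAL_FEATURES = ("gray", "color", "edge", "variance", "bow")

DEFAULT_LABELS = ("CT", "GX", "MR", "NM", "PET", "PX", "US", "XR")
DEFAULT_CONFUSION_GROUPS = (("CT", "MR", "XR"), ("NM", "PET"), ("GX", "PX"))


@dataclass
class ExperimentConfig:
    """All knobs of the pipeline with their defaults.

    ``metric`` is the default distance for every feature (chi-square, which
    performed best across features in validation of this family of methods);
    ``metrics`` overrides it per feature name. ``confusion_groups`` lists the
    label groups handled by local classifiers; groups whose labels are absent
    from the training data are skipped with a warning at train time.
    """

    features: tuple[str, ...] = ALL_FEATURES
    standardize_size: int = 256
    gray_bins: int = 256
    color_bins: tuple[int, int, int] = (4, 4, 4)
    edge_grid: tuple[int, int] = (4, 4)
    edge_bins: int = 20
    variance_radius: int = 2
    variance_bins: int = 32
    patch_size: int = 16
    patch_stride: int = 8
    codebook_size: int = 200
    kmeans_max_iter: int = 100
    metric: str = "chi2"
    metrics: dict[str, str] = field(default_factory=dict)
    svm_c: float = 1.0
    confusion_groups: tuple[tuple[str, ...], ...] = DEFAULT_CONFUSION_GROUPS
    n_folds: int = 5
    seed: int = 0
    vocabulary_path: str | None = None

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        unknown = [f for f in self.features if f not in ALL_FEATURES]
        if unknown:
            raise ValueError(f"unknown features {unknown}; valid: {ALL_FEATURES}")
        self.color_bins = tuple(int(b) for b in self.color_bins)
        self.edge_grid = tuple(int(g) for g in self.edge_grid)
        self.confusion_groups = tuple(tuple(g) for g in self.confusion_groups)
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def metric_for(self, feature: str) -> str:
        return self.metrics.get(feature, self.metric)

    @property
    def visual_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.features if f != "text")

    def with_(self, **kwargs) -> "ExperimentConfig":
        """A copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["features"] = list(self.features)
        data["color_bins"] = list(self.color_bins)
        data["edge_grid"] = list(self.edge_grid)
        data["confusion_groups"] = [list(g) for g in self.confusion_groups]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.vocabulary_path is not None and not Path(cfg.vocabulary_path).exists():
            raise ValueError(f"vocabulary file not found: {cfg.vocabulary_path}")
        return cfg
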