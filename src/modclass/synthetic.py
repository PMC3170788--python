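"""Deterministic synthetic image/caption generator with controllable class structure.

Each class is defined by a handful of generative knobs that map one-to-one
onto the pipeline's feature channels: a base gray level (mean/std, drawn once
per image) drives the gray histogram; an oriented sinusoidal grating drives
the edge-orientation histogram; per-pixel Gaussian noise drives the local
variance histogram; an RGB tint drives the color histogram; and per-class
caption keywords (emitted independently with a configurable probability,
mixed with non-vocabulary filler words) drive the textual feature.

Classes listed in ``confusable_pairs`` are forced to share identical visual
parameters at construction time, so any systematic visual separability of
such a pair indicates a pipeline bug rather than signal; only their captions
can tell them apart.

Randomness is counter-based: one master seed plus (class index, item index)
seeds an independent generator per image and per caption, so any subset of
the dataset is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from modclass.features_text import Vocabulary
from modclass.io import DatasetManifest, save_image, save_manifest

#: Filler words guaranteed outside the default vocabulary.
FILLER_WORDS = (
    "figure", "shows", "image", "view", "seen", "noted", "patient",
    "arrow", "region", "area", "study", "finding", "with", "the",
)


@dataclass
class ClassSpec:
    """Generative parameters of one synthetic class."""

    name: str
    intensity_mean: float = 128.0
    intensity_std: float = 0.0  # per-image jitter of the base level
    texture_orientation: float | None = None  # grating normal, degrees
    texture_amplitude: float = 0.0
    texture_period: float = 8.0  # pixels per grating cycle
    noise_std: float = 0.0  # per-pixel Gaussian noise
    tint: tuple[float, float, float] = (1.0, 1.0, 1.0)  # RGB channel scaling
    keywords: tuple[str, ...] = ()
    keyword_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity_std < 0 or self.noise_std < 0 or self.texture_amplitude < 0:
            raise ValueError("std and amplitude parameters must be >= 0")
        if not 0.0 <= self.keyword_prob <= 1.0:
            raise ValueError("keyword_prob must lie in [0, 1]")
        if self.texture_period <= 0:
            raise ValueError("texture_period must be positive")
        self.tint = tuple(float(t) for t in self.tint)
        self.keywords = tuple(self.keywords)

    def visual_params(self) -> tuple:
        return (
            self.intensity_mean,
            self.intensity_std,
            self.texture_orientation,
            self.texture_amplitude,
            self.texture_period,
            self.noise_std,
            self.tint,
        )


@dataclass
class SyntheticSpec:
    """Whole-dataset recipe: classes, sizes, seed, engineered confusable pairs."""

    classes: list[ClassSpec]
    image_size: int = 64
    n_per_class: int = 40
    seed: int = 0
    confusable_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        by_name = {c.name: i for i, c in enumerate(self.classes)}
        for a, b in self.confusable_pairs:
            if a not in by_name or b not in by_name:
                raise ValueError(f"confusable pair ({a}, {b}) references unknown class")
            # force the pair to share the first member's visual parameters
            src = self.classes[by_name[a]]
            dst = self.classes[by_name[b]]
            self.classes[by_name[b]] = replace(
                dst,
                intensity_mean=src.intensity_mean,
                intensity_std=src.intensity_std,
                texture_orientation=src.texture_orientation,
                texture_amplitude=src.texture_amplitude,
                texture_period=src.texture_period,
                noise_std=src.noise_std,
                tint=src.tint,
            )


def _item_rng(seed: int, class_idx: int, item_idx: int, stream: int) -> np.random.Generator:
    """Counter-based per-item generator: independent and subset-reproducible."""
    return np.random.default_rng(np.random.SeedSequence([seed, class_idx, item_idx, stream]))


def generate_image(
    cls: ClassSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    """One RGB image: base level + oriented grating + noise, tinted and clipped."""
    if size < 1:
        raise ValueError("size must be >= 1")
    base = cls.intensity_mean + cls.intensity_std * rng.standard_normal()
    canvas = np.full((size, size), base, dtype=float)
    if cls.texture_orientation is not None and cls.texture_amplitude > 0:
        theta = np.radians(cls.texture_orientation)
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        phase = (xx * np.cos(theta) + yy * np.sin(theta)) * (2 * np.pi / cls.texture_period)
        canvas += cls.texture_amplitude * np.sin(phase)
    if cls.noise_std > 0:
        canvas += cls.noise_std * rng.standard_normal((size, size))
    rgb = canvas[:, :, None] * np.asarray(cls.tint)[None, None, :]
    return np.clip(np.rint(rgb), 0, 255).astype(np.int64)


def generate_caption(cls: ClassSpec, vocab: Vocabulary, rng: np.random.Generator) -> str:
    """One caption: class keywords emitted independently, plus filler words."""
    for kw in cls.keywords:
        if kw not in vocab:
            raise ValueError(f"class {cls.name!r} keyword {kw!r} not in vocabulary")
    vocab_terms = set(vocab.keywords)
    fillers = [w for w in FILLER_WORDS if w not in vocab_terms]
    words = [kw for kw in cls.keywords if rng.random() < cls.keyword_prob]
    n_fill = int(rng.integers(3, 8))
    words += [fillers[i] for i in rng.integers(0, len(fillers), n_fill)]
    order = rng.permutation(len(words))
    return " ".join(words[i] for i in order)


def generate_arrays(
    spec: SyntheticSpec, vocab: Vocabulary
) -> tuple[list[np.ndarray], list[str], np.ndarray]:
    """In-memory dataset: (images, captions, labels), deterministic from the spec."""
    images, captions, labels = [], [], []
    for ci, cls in enumerate(spec.classes):
        for ii in range(spec.n_per_class):
            images.append(
                generate_image(cls, spec.image_size, _item_rng(spec.seed, ci, ii, 0))
            )
            captions.append(generate_caption(cls, vocab, _item_rng(spec.seed, ci, ii, 1)))
            labels.append(cls.name)
    return images, captions, np.asarray(labels)


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path, vocab: Vocabulary
) -> DatasetManifest:
    """Write PNG images plus a manifest TSV under *out_dir*; fully reproducible."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    images, captions, labels = generate_arrays(spec, vocab)
    ids, paths = [], []
    k = 0
    for cls in spec.classes:
        for ii in range(spec.n_per_class):
            sid = f"{cls.name}_{ii:04d}"
            rel = f"images/{sid}.png"
            save_image(images[k], out / rel)
            ids.append(sid)
            paths.append(rel)
            k += 1
    manifest = DatasetManifest(ids, paths, list(captions), list(labels), base_dir=out)
    save_manifest(manifest, out / "manifest.tsv")
    return manifest


# ---------------------------------------------------------------------------
# Canonical study scenarios used by the test suite and the acceptance script.
# ---------------------------------------------------------------------------

def scenario_vocabulary() -> Vocabulary:
    """Small fixed vocabulary covering the scenario keywords."""
    return Vocabulary(
        ["ct", "mr", "pet", "nm", "us", "xray", "ultrasound", "tomography",
         "scan", "contrast", "axial", "doppler"]
    )


def well_separated_spec(n_per_class: int = 40, size: int = 64, seed: int = 0) -> SyntheticSpec:
    """Five classes separated on every channel (visual and textual)."""
    classes = [
        ClassSpec("CT", intensity_mean=60, intensity_std=4, texture_orientation=0,
                  texture_amplitude=35, noise_std=4, tint=(1.0, 1.0, 1.0),
                  keywords=("ct", "tomography")),
        ClassSpec("MR", intensity_mean=110, intensity_std=4, texture_orientation=45,
                  texture_amplitude=35, noise_std=10, tint=(0.9, 0.9, 1.0),
                  keywords=("mr", "axial")),
        ClassSpec("PET", intensity_mean=160, intensity_std=4, texture_orientation=90,
                  texture_amplitude=35, noise_std=18, tint=(1.0, 0.8, 0.7),
                  keywords=("pet", "scan")),
        ClassSpec("US", intensity_mean=90, intensity_std=4, texture_orientation=135,
                  texture_amplitude=25, noise_std=30, tint=(0.8, 1.0, 0.8),
                  keywords=("us", "doppler")),
        ClassSpec("XR", intensity_mean=200, intensity_std=4, texture_orientation=None,
                  texture_amplitude=0, noise_std=8, tint=(1.0, 1.0, 0.9),
                  keywords=("xray", "contrast")),
    ]
    return SyntheticSpec(classes, image_size=size, n_per_class=n_per_class, seed=seed)


def visual_twin_spec(n_per_class: int = 40, size: int = 64, seed: int = 0) -> SyntheticSpec:
    """Five classes, one pair (NM, PET) visually identical but caption-distinguishable."""
    classes = [
        ClassSpec("CT", intensity_mean=60, intensity_std=4, texture_orientation=0,
                  texture_amplitude=35, noise_std=5, keywords=("ct",), keyword_prob=0.9),
        ClassSpec("MR", intensity_mean=120, intensity_std=4, texture_orientation=60,
                  texture_amplitude=35, noise_std=12, tint=(0.9, 0.9, 1.0),
                  keywords=("mr",), keyword_prob=0.9),
        ClassSpec("NM", intensity_mean=160, intensity_std=4, texture_orientation=120,
                  texture_amplitude=30, noise_std=20, tint=(1.0, 0.85, 0.7),
                  keywords=("nm",), keyword_prob=0.9),
        ClassSpec("PET", keywords=("pet",), keyword_prob=0.9),  # visuals copied from NM
        ClassSpec("US", intensity_mean=210, intensity_std=4, texture_orientation=None,
                  noise_std=30, tint=(0.8, 1.0, 0.8), keywords=("us",), keyword_prob=0.9),
    ]
    return SyntheticSpec(
        classes,
        image_size=size,
        n_per_class=n_per_class,
        seed=seed,
        confusable_pairs=[("NM", "PET")],
    )


def weak_pair_spec(n_per_class: int = 30, size: int = 64, seed: int = 0) -> SyntheticSpec:
    """Four classes: (NM, PET) differ only weakly (noise std 20 vs 21), others far away.

    Captions carry no class signal (keyword_prob = 0), so separating the pair
    is a purely visual problem. The pair's contrast (one unit of noise std,
    plus a shared large base-level jitter that makes the gray histogram an
    unreliable guide) is tiny relative to the between-class distances that
    dominate the global mean-distance normalizers, so the globally-normalized
    kernels barely resolve it — the regime the confusion-group local
    classifiers, which recompute the normalizers on the pair subset, exist
    for.
    """
    classes = [
        ClassSpec("NM", intensity_mean=128, intensity_std=12, noise_std=20,
                  keywords=("nm",), keyword_prob=0.0),
        ClassSpec("PET", intensity_mean=128, intensity_std=12, noise_std=21,
                  keywords=("pet",), keyword_prob=0.0),
        ClassSpec("CT", intensity_mean=50, intensity_std=3, texture_orientation=30,
                  texture_amplitude=40, noise_std=2, keywords=("ct",), keyword_prob=0.0),
        ClassSpec("US", intensity_mean=210, intensity_std=3, texture_orientation=120,
                  texture_amplitude=30, noise_std=80, keywords=("us",), keyword_prob=0.0),
    ]
    return SyntheticSpec(classes, image_size=size, n_per_class=n_per_class, seed=seed)
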