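"""File formats: dataset manifests, images, feature/kernel matrices.

Manifest: tab-separated with header ``sample_id  image_path  caption  label``;
image paths are resolved relative to the manifest's directory; the label
column may be empty for unlabeled samples. Captions must not contain tabs
(the TSV dialect has no quoting).

Feature matrix: TSV with ``sample_id`` plus one column per dimension.
Kernel/distance matrix: TSV with a header row of sample identifiers;
values are written with 17 significant digits so round-trips are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

MANIFEST_COLUMNS = ("sample_id", "image_path", "caption", "label")


@dataclass
class DatasetManifest:
    sample_ids: list[str]
    image_paths: list[str]
    captions: list[str]
    labels: list[str]  # "" for unlabeled
    base_dir: Path

    def __len__(self) -> int:
        return len(self.sample_ids)

    def resolve_path(self, i: int) -> Path:
        return self.base_dir / self.image_paths[i]

    def load_images(self) -> list[np.ndarray]:
        """Decode every referenced image (PNG/JPEG) to an integer array."""
        out = []
        for i in range(len(self)):
            path = self.resolve_path(i)
            try:
                with Image.open(path) as im:
                    if im.mode not in ("L", "RGB"):
                        im = im.convert("RGB")
                    out.append(np.asarray(im).astype(np.int64))
            except Exception as exc:  # noqa: BLE001 - re-raise with row context
                raise OSError(
                    f"cannot read image for sample {self.sample_ids[i]!r}: {path} ({exc})"
                ) from exc
        return out


def load_manifest(path: str | Path, check_images: bool = False) -> DatasetManifest:
    """Parse and validate a manifest TSV; duplicate ids and malformed rows are rejected."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty manifest")
    header = tuple(lines[0].split("\t"))
    if header != MANIFEST_COLUMNS:
        raise ValueError(
            f"{path}: bad header {header}; expected {MANIFEST_COLUMNS} "
            "(missing column or stray tab)"
        )
    ids, paths, captions, labels = [], [], [], []
    seen: set[str] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(
                f"{path}:{ln}: expected 4 tab-separated fields, got {len(fields)} "
                "(captions must not contain tabs)"
            )
        sid, ipath, caption, label = fields
        if sid in seen:
            raise ValueError(f"{path}:{ln}: duplicate sample_id {sid!r}")
        seen.add(sid)
        ids.append(sid)
        paths.append(ipath)
        captions.append(caption)
        labels.append(label)
    manifest = DatasetManifest(ids, paths, captions, labels, base_dir=path.parent)
    if check_images:
        manifest.load_images()
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = ["\t".join(MANIFEST_COLUMNS)]
    for i in range(len(manifest)):
        caption = manifest.captions[i]
        if "\t" in caption:
            raise ValueError(f"caption for {manifest.sample_ids[i]!r} contains a tab")
        rows.append(
            "\t".join(
                (manifest.sample_ids[i], manifest.image_paths[i], caption, manifest.labels[i])
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image).astype(np.uint8)).save(path)


def write_feature_matrix(path: str | Path, sample_ids, matrix: np.ndarray) -> None:
    mat = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"d{i}" for i in range(mat.shape[1])) + "\n")
        for sid, row in zip(sample_ids, mat):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    n_dim = len(lines[0].split("\t")) - 1
    ids, rows = [], []
    for line in lines[1:]:
        fields = line.split("\t")
        ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    mat = np.asarray(rows, dtype=float) if rows else np.zeros((0, n_dim))
    return ids, mat


def write_matrix_tsv(path: str | Path, sample_ids, matrix: np.ndarray) -> None:
    """Square or rectangular kernel/distance matrix with sample-id header row."""
    mat = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t".join(str(s) for s in sample_ids) + "\n")
        for row in mat:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    ids = lines[0].split("\t")
    mat = np.asarray([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    return ids, mat
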