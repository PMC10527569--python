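"""Feature containers, flip augmentation and a deterministic toy extractor.

:class:`FeatureMatrix` is the in-memory unit passed between fusion,
selection and evaluation: an ``N x K`` sample-by-feature matrix with one
label per row and provenance-carrying feature names.  It round-trips to CSV
(first column ``label``, remaining columns features).

The extractor contract mirrors a deep-feature pipeline: any callable that
maps a list of images to a :class:`FeatureMatrix` row-per-image fits.  The
built-in "toy" extractor projects per-patch intensity statistics through a
fixed random projection, so it is fully deterministic and needs no trained
weights; real embeddings saved as CSV can be loaded with
:meth:`FeatureMatrix.from_csv` instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enhancement import validate_image

__all__ = [
    "FeatureMatrix",
    "ExtractorSpec",
    "augment_flips",
    "extract_features",
]


@dataclass
class FeatureMatrix:
    """N x K feature matrix with per-row labels and per-column names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("a FeatureMatrix needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must have one entry per row")
        if not self.feature_names:
            self.feature_names = [f"f{i:04d}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must have one entry per column")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, cols: Sequence[int]) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(
            values=self.values[:, cols],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[c] for c in cols],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must have a 'label' column")
        labels = df["label"].to_numpy()
        feats = df.drop(columns=["label"])
        return cls(
            values=feats.to_numpy(dtype=np.float64),
            labels=labels,
            feature_names=[str(c) for c in feats.columns],
        )


@dataclass(frozen=True)
class ExtractorSpec:
    """Identifies one feature extractor and its output width.

    ``name`` seeds the toy extractor's random projection, so differently
    named extractors give complementary views of the same images, the way
    different CNN backbones do.
    """

    name: str = "toy"
    embed_dim: int = 64
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError(f"embed_dim must be >= 1, got {self.embed_dim}")


def augment_flips(images: Sequence[np.ndarray], labels: Sequence):
    """Augment each image with its left-right flip, up-down flip and both.

    Returns 4 images per input (original, LR, UD, LR+UD), in input order,
    with labels replicated to match.
    """
    if len(images) == 0:
        raise ValueError("augment_flips requires at least one image")
    out_images: list[np.ndarray] = []
    out_labels: list = []
    for img, lab in zip(images, labels):
        img = np.asarray(img)
        out_images.extend(
            [img, img[:, ::-1].copy(), img[::-1, :].copy(), img[::-1, ::-1].copy()]
        )
        out_labels.extend([lab] * 4)
    return out_images, np.asarray(out_labels)


def _stable_seed(spec: ExtractorSpec) -> int:
    key = f"{spec.name}|{spec.embed_dim}|{spec.params!r}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _image_stats(img: np.ndarray, grid: int = 4, hist_bins: int = 8) -> np.ndarray:
    """Hand-crafted statistics: per-cell mean/std on a grid plus a global histogram."""
    img = validate_image(img)
    feats: list[np.ndarray] = []
    for c in range(3):
        chan = img[..., c]
        rows = np.array_split(chan, grid, axis=0)
        cells = [cell for row in rows for cell in np.array_split(row, grid, axis=1)]
        feats.append(np.array([cell.mean() for cell in cells]))
        feats.append(np.array([cell.std() for cell in cells]))
        hist, _ = np.histogram(chan, bins=hist_bins, range=(0.0, 1.0))
        feats.append(hist / chan.size)
    return np.concatenate(feats)


def extract_features(
    images: Sequence[np.ndarray],
    spec: ExtractorSpec = ExtractorSpec(),
    labels: Sequence | None = None,
) -> FeatureMatrix:
    """Run the toy extractor: grid statistics through a fixed random projection.

    Rows follow input order.  The projection matrix is seeded from the spec
    alone, so the mapping is a pure function of (image, spec): identical
    images give identical rows and repeated calls are bit-identical.
    """
    if len(images) == 0:
        raise ValueError("extract_features requires at least one image")
    stats = np.stack([_image_stats(img) for img in images])
    rng = np.random.default_rng(_stable_seed(spec))
    proj = rng.standard_normal((spec.embed_dim, stats.shape[1])) / np.sqrt(stats.shape[1])
    values = stats @ proj.T
    if labels is None:
        labels = np.zeros(len(images), dtype=int)
    names = [f"{spec.name}_{i:04d}" for i in range(spec.embed_dim)]
    return FeatureMatrix(values=values, labels=np.asarray(labels), feature_names=names)
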