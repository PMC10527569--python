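"""Synthetic data generators for every pipeline stage.

Two families of fixtures make the whole pipeline testable without any
dermoscopy download:

* hazy low-contrast lesion-like images, produced by drawing a class-colored
  elliptical blob on a skin-toned background and then applying the haze
  forward model ``I = J*T + A*(1 - T)`` with a smooth radial depth field
  (``T = exp(-beta * depth)``), so dehazing quality is measurable against
  the known clean image and transmission;
* labeled feature tables with a known informative / noise / redundant
  column structure, emulating multi-backbone deep-feature tables.

Informative features place class means on binary codes scaled by the class
separation; the codes are built so that (up to the code capacity) every
informative dimension is needed to distinguish at least one pair of
classes, which makes feature-selection recovery well-posed.  Redundant
columns are jittered copies of informative ones (pairwise r > 0.9 at the
default jitter).  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "ImageFixtureSpec",
    "HazyImageSet",
    "FeatureFixtureSpec",
    "FeatureTruth",
    "make_hazy_images",
    "make_feature_dataset",
    "split_multisource",
]


@dataclass(frozen=True)
class ImageFixtureSpec:
    """Conditions for the lesion-image generator."""

    size: tuple[int, int] = (64, 64)
    n_classes: int = 7
    images_per_class: int = 30
    haze_strength: float = 1.0
    noise_sigma: float = 0.01
    atmospheric_light: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.haze_strength < 0:
            raise ValueError("haze_strength must be >= 0")
        if not 0 < self.atmospheric_light <= 1:
            raise ValueError("atmospheric_light must be in (0, 1]")


@dataclass
class HazyImageSet:
    """Generated images plus the ground truth needed to score dehazing."""

    hazy: list[np.ndarray]
    clean: list[np.ndarray]
    labels: np.ndarray
    transmission: np.ndarray
    atmospheric_light: np.ndarray


def _radial_depth(h: int, w: int) -> np.ndarray:
    """Smooth depth field: base optical depth 0.5, rising radially to 1.

    The base offset models the veil covering the whole field of view (the
    low-contrast regime the enhancement targets); the radial term adds the
    smooth spatial gradient.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    return 0.5 + 0.5 * r / r.max()


def _class_colors(n_classes: int) -> np.ndarray:
    """Class-specific lesion colors: intensity and red/brown chroma ramps."""
    shades = np.linspace(0.15, 0.55, n_classes)
    colors = np.stack([
        shades + 0.10,                      # red channel slightly dominant
        shades * np.linspace(0.6, 1.0, n_classes),
        shades * np.linspace(0.4, 0.9, n_classes)[::-1],
    ], axis=1)
    return np.clip(colors, 0.0, 1.0)


def make_hazy_images(spec: ImageFixtureSpec = ImageFixtureSpec()) -> HazyImageSet:
    """Generate hazy lesion-like images with known clean truth and transmission.

    With ``haze_strength == 0`` the hazy images equal the clean ones
    exactly.  Noise is part of the clean image (applied before hazing), so
    the haze forward model is exact and invertible with the returned
    transmission and atmospheric light.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    depth = _radial_depth(h, w)
    t = np.exp(-spec.haze_strength * depth)
    a = np.full(3, spec.atmospheric_light)
    colors = _class_colors(spec.n_classes)
    background = np.array([0.80, 0.65, 0.55])

    yy, xx = np.mgrid[0:h, 0:w]
    hazy: list[np.ndarray] = []
    clean: list[np.ndarray] = []
    labels: list[int] = []
    for cls in range(spec.n_classes):
        for _ in range(spec.images_per_class):
            img = np.empty((h, w, 3))
            bg = np.clip(background + rng.normal(0, 0.02, 3), 0, 1)
            img[:] = bg
            cy = h / 2 + rng.uniform(-h / 8, h / 8)
            cx = w / 2 + rng.uniform(-w / 8, w / 8)
            ry = rng.uniform(h / 6, h / 3.5)
            rx = rng.uniform(w / 6, w / 3.5)
            dist = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
            blob = np.exp(-(dist**1.5))  # soft-edged ellipse
            color = np.clip(colors[cls] + rng.normal(0, 0.02, 3), 0, 1)
            img = img * (1 - blob[..., None]) + color[None, None, :] * blob[..., None]
            img = np.clip(img + rng.normal(0, spec.noise_sigma, img.shape), 0, 1)
            hazed = img * t[..., None] + a[None, None, :] * (1 - t[..., None])
            clean.append(img)
            hazy.append(np.clip(hazed, 0, 1))
            labels.append(cls)
    return HazyImageSet(
        hazy=hazy, clean=clean, labels=np.asarray(labels),
        transmission=t, atmospheric_light=a,
    )


@dataclass(frozen=True)
class FeatureFixtureSpec:
    """Conditions for the labeled feature-table generator.

    ``layout`` controls column order: ``grouped`` emits the informative
    block, then noise, then redundant copies; ``paired`` interleaves each
    informative column with its redundant copy (requires
    ``n_redundant == n_informative``), which lines the duplicates up as
    consecutive fusion pairs.
    """

    n_samples: int = 200
    n_classes: int = 7
    n_informative: int = 5
    n_noise: int = 40
    n_redundant: int = 5
    class_separation: float = 6.0
    jitter: float = 0.1
    layout: str = "grouped"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.layout not in ("grouped", "paired"):
            raise ValueError("layout must be 'grouped' or 'paired'")
        if self.layout == "paired" and self.n_redundant != self.n_informative:
            raise ValueError("paired layout requires n_redundant == n_informative")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise + self.n_redundant


@dataclass
class FeatureTruth:
    """Ground-truth column roles of a generated feature table."""

    informative: np.ndarray
    noise: np.ndarray
    redundant: np.ndarray


def _class_codes(n_classes: int, n_informative: int, rng: np.random.Generator) -> np.ndarray:
    """Binary class codes over the informative dimensions.

    The first codes are the zero vector and the unit vectors, so every
    dimension is critical for at least one class pair whenever
    ``n_classes > n_informative``; additional classes get distinct
    higher-weight codes.  When there are more classes than distinct codes
    (2^d), classes share codes cyclically after a seeded permutation, which
    models an extractor that can only resolve some class groups.
    """
    codes: list[tuple[int, ...]] = [tuple([0] * n_informative)]
    codes += [
        tuple(1 if i == j else 0 for i in range(n_informative))
        for j in range(n_informative)
    ]
    weight = 2
    while len(codes) < n_classes and weight <= n_informative:
        for idx in combinations(range(n_informative), weight):
            codes.append(tuple(1 if i in idx else 0 for i in range(n_informative)))
            if len(codes) >= n_classes:
                break
        weight += 1
    assignment = np.array([codes[c % len(codes)] for c in range(n_classes)], dtype=float)
    if n_classes > len(codes):
        perm = rng.permutation(n_classes)
        assignment = assignment[perm]
    return assignment


def make_feature_dataset(
    spec: FeatureFixtureSpec = FeatureFixtureSpec(),
) -> tuple[FeatureMatrix, FeatureTruth]:
    """Generate a labeled feature table with known column roles.

    Informative columns are unit-variance Gaussians whose class means are
    binary codes scaled by ``class_separation``; noise columns are
    class-independent standard normals; redundant columns copy an
    informative column plus ``N(0, jitter^2)``.  Labels are balanced and
    deterministic (sample i gets class ``i mod n_classes``), so tables
    generated with different seeds but equal shapes align row-wise.
    """
    rng = np.random.default_rng(spec.seed)
    n, ni, nn, nr = spec.n_samples, spec.n_informative, spec.n_noise, spec.n_redundant
    labels = np.arange(n) % spec.n_classes
    codes = _class_codes(spec.n_classes, ni, rng)
    centers = spec.class_separation * codes

    informative = centers[labels] + rng.standard_normal((n, ni))
    noise = rng.standard_normal((n, nn))
    redundant = np.empty((n, nr))
    source = np.empty(nr, dtype=int)
    for j in range(nr):
        source[j] = j % ni
        redundant[:, j] = informative[:, source[j]] + rng.normal(0, spec.jitter, n)

    if spec.layout == "grouped":
        values = np.hstack([informative, noise, redundant])
        names = (
            [f"inf_{j:03d}" for j in range(ni)]
            + [f"noise_{j:03d}" for j in range(nn)]
            + [f"red_{j:03d}" for j in range(nr)]
        )
        truth = FeatureTruth(
            informative=np.arange(ni),
            noise=np.arange(ni, ni + nn),
            redundant=np.arange(ni + nn, ni + nn + nr),
        )
    else:  # paired: (inf_j, red_j) side by side, then noise
        cols = []
        names = []
        info_idx = []
        red_idx = []
        for j in range(ni):
            info_idx.append(len(cols))
            cols.append(informative[:, j])
            names.append(f"inf_{j:03d}")
            red_idx.append(len(cols))
            cols.append(redundant[:, j])
            names.append(f"red_{j:03d}")
        noise_idx = list(range(len(cols), len(cols) + nn))
        cols.extend(noise.T)
        names += [f"noise_{j:03d}" for j in range(nn)]
        values = np.column_stack(cols)
        truth = FeatureTruth(
            informative=np.asarray(info_idx),
            noise=np.asarray(noise_idx),
            redundant=np.asarray(red_idx),
        )
    mat = FeatureMatrix(values=values, labels=labels, feature_names=names)
    return mat, truth


def split_multisource(mat: FeatureMatrix, widths) -> list[FeatureMatrix]:
    """Split a table into column-contiguous blocks emulating separate extractors.

    ``serial_fuse`` of the output reconstructs the input exactly.
    """
    widths = list(widths)
    if sum(widths) != mat.n_features:
        raise ValueError(
            f"widths sum to {sum(widths)} but the matrix has {mat.n_features} columns"
        )
    out = []
    start = 0
    for wdt in widths:
        out.append(mat.select_columns(range(start, start + wdt)))
        start += wdt
    return out
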