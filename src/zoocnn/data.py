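"""Synthetic grayscale image corpora and point clouds for testing the pipeline.

The image generator emulates a three-class chest-radiograph corpus at desk
scale: every image shares a procedural "lung field" background (low-amplitude
horizontal rib banding plus a smooth vignette), on top of which each class
receives its characteristic texture:

* class 0 (``BP``, bacterial pneumonia): 1-3 bright focal elliptical
  consolidation blobs;
* class 1 (``NL``, normal lungs): the clear background only;
* class 2 (``VP``, viral pneumonia): diffuse mid-amplitude spatially
  correlated noise, mimicking an interstitial pattern.

The textures are procedural, not learned: they give a 1-nearest-neighbour
classifier enough signal to separate the classes, which is all the
optimization pipeline needs to be exercised end to end without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabeledImageSet",
    "ClusterSet",
    "DEFAULT_CLASS_NAMES",
    "generate_images",
    "generate_clusters",
    "stratified_split",
    "save_png_tree",
    "load_png_tree",
    "save_bundle",
    "load_bundle",
]

#: Class order follows the corpus convention: majority first.
DEFAULT_CLASS_NAMES = ("BP", "NL", "VP")


@dataclass
class LabeledImageSet:
    """A set of equally sized 2-D grayscale images with integer labels.

    ``provenance[i]`` is ``"real"`` for original samples and ``"synthetic"``
    for oversampled ones.  Pixel values live in ``[0, 1]``.
    """

    images: np.ndarray  # (n, h, w) float64 in [0, 1]
    labels: np.ndarray  # (n,) int
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim == 2:  # a single image
            self.images = self.images[None]
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"images ({len(self.images)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        if self.images.size and (
            self.images.min() < 0.0 or self.images.max() > 1.0
        ):
            raise ValueError("pixel values must lie in [0, 1]")
        if not self.provenance:
            self.provenance = ["real"] * len(self.labels)
        if len(self.provenance) != len(self.labels):
            raise ValueError("provenance must have one entry per sample")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def side(self) -> int:
        return self.images.shape[1] if len(self) else 0

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def flattened(self) -> np.ndarray:
        """Images as an (n, h*w) float matrix (the ADASYN feature space)."""
        return self.images.reshape(len(self), -1)

    def subset(self, indices: Sequence[int]) -> "LabeledImageSet":
        idx = np.asarray(indices, dtype=int)
        return LabeledImageSet(
            self.images[idx],
            self.labels[idx],
            self.class_names,
            [self.provenance[i] for i in idx],
        )


@dataclass
class ClusterSet:
    """Low-dimensional labelled point cloud (feature-space testbed)."""

    points: np.ndarray  # (n, D)
    labels: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")

    @property
    def D(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _background(side: int, rng: np.random.Generator) -> np.ndarray:
    """Clear lung-field background: rib bands + vignette + faint grain."""
    y, x = np.mgrid[0:side, 0:side] / side
    phase = rng.uniform(0, 2 * np.pi)
    n_bands = rng.uniform(5.0, 7.0)
    ribs = 0.06 * np.sin(2 * np.pi * n_bands * y + phase)
    # smooth radial vignette, brighter centre like an illuminated field
    cy, cx = rng.uniform(0.4, 0.6, size=2)
    r2 = (y - cy) ** 2 + (x - cx) ** 2
    vignette = 0.25 * np.exp(-3.0 * r2)
    grain = 0.02 * rng.standard_normal((side, side))
    return 0.35 + ribs + vignette + grain


def _add_blobs(img: np.ndarray, rng: np.random.Generator) -> None:
    """Focal consolidation: 1-3 bright elliptical opacities."""
    side = img.shape[0]
    y, x = np.mgrid[0:side, 0:side] / side
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(0.2, 0.8, size=2)
        ay = rng.uniform(0.08, 0.2)
        ax = rng.uniform(0.08, 0.2)
        theta = rng.uniform(0, np.pi)
        dy, dx = y - cy, x - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        blob = np.exp(-((u / ay) ** 2 + (v / ax) ** 2))
        img += rng.uniform(0.35, 0.5) * blob


def _add_interstitial(img: np.ndarray, rng: np.random.Generator) -> None:
    """Diffuse pattern: ground-glass haze + correlated interstitial noise."""
    side = img.shape[0]
    img += rng.uniform(0.10, 0.16)  # diffuse haze over the whole field
    noise = rng.standard_normal((side, side))
    noise = ndimage.gaussian_filter(noise, sigma=side / 32.0)
    scale = noise.std()
    if scale > 0:
        noise /= scale
    img += 0.10 * noise


def generate_images(
    class_counts: Mapping[int, int],
    side: int = 64,
    seed: int = 0,
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES,
) -> LabeledImageSet:
    """Generate a seeded three-class grayscale corpus.

    Parameters
    ----------
    class_counts
        Map label -> number of images (labels in {0, 1, 2}).
    side
        Image side in pixels (>= 16).
    seed
        Integer seed; identical arguments give bit-identical output.
    """
    if side < 16:
        raise ValueError(f"side must be >= 16, got {side}")
    for label, count in class_counts.items():
        if count < 0:
            raise ValueError(f"negative count {count} for class {label}")
        if label not in (0, 1, 2):
            raise ValueError(f"labels must be in {{0,1,2}}, got {label}")

    images: list[np.ndarray] = []
    labels: list[int] = []
    root = np.random.SeedSequence(seed)
    # one child stream per image, ordered by (label, index): the pixel
    # content of image i of class c never depends on the other counts
    for label in sorted(class_counts):
        children = root.spawn(3)[label].spawn(class_counts[label])
        for child in children:
            rng = np.random.default_rng(child)
            img = _background(side, rng)
            if label == 0:
                _add_blobs(img, rng)
            elif label == 2:
                _add_interstitial(img, rng)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(label)

    if images:
        stack = np.stack(images)
    else:
        stack = np.empty((0, side, side))
    return LabeledImageSet(stack, np.asarray(labels, dtype=np.int64), class_names)


def generate_clusters(
    n_per_class: Mapping[int, int],
    D: int,
    class_means: Mapping[int, Sequence[float]],
    spread: float = 1.0,
    seed: int = 0,
) -> ClusterSet:
    """Isotropic Gaussian clusters at the given means (seeded)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if spread <= 0:
        raise ValueError("spread must be positive")
    for label, mean in class_means.items():
        if len(mean) != D:
            raise ValueError(
                f"mean for class {label} has dimension {len(mean)}, expected {D}"
            )
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    labels: list[int] = []
    for label in sorted(n_per_class):
        n = n_per_class[label]
        if n < 0:
            raise ValueError(f"negative count for class {label}")
        mean = np.asarray(class_means[label], dtype=float)
        points.append(mean + spread * rng.standard_normal((n, D)))
        labels.extend([label] * n)
    stacked = np.vstack(points) if points else np.empty((0, D))
    return ClusterSet(stacked, np.asarray(labels, dtype=np.int64))


def stratified_split(
    dataset: LabeledImageSet,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Per-class shuffled train/validation/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for label in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == label)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train : n_train + n_val])
        test_idx.extend(idx[n_train + n_val :])
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )


# ---------------------------------------------------------------------------
# I/O: class-per-directory PNG trees and HDF5 bundles
# ---------------------------------------------------------------------------


def save_png_tree(dataset: LabeledImageSet, root: str | Path) -> None:
    """Write ``root/<class_name>/NNNNN.png`` (8-bit grayscale)."""
    root = Path(root)
    counters = {name: 0 for name in dataset.class_names}
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[label]
        cls_dir = root / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        arr = np.round(img * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(cls_dir / f"{counters[name]:05d}.png")
        counters[name] += 1


def load_png_tree(
    root: str | Path, class_names: Sequence[str] | None = None
) -> LabeledImageSet:
    """Read a class-per-directory PNG tree (directory name = class name)."""
    root = Path(root)
    if class_names is None:
        class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
    images: list[np.ndarray] = []
    labels: list[int] = []
    for label, name in enumerate(class_names):
        for png in sorted((root / name).glob("*.png")):
            arr = np.asarray(Image.open(png).convert("L"), dtype=np.float64)
            images.append(arr / 255.0)
            labels.append(label)
    if not images:
        raise ValueError(f"no PNG files found under {root}")
    return LabeledImageSet(
        np.stack(images), np.asarray(labels), tuple(class_names)
    )


def save_bundle(dataset: LabeledImageSet, path: str | Path) -> None:
    """Write a single self-contained HDF5 bundle."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=dataset.images, compression="gzip")
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset(
            "class_names",
            data=np.array(dataset.class_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "provenance",
            data=np.array(dataset.provenance, dtype=h5py.string_dtype()),
        )


def load_bundle(path: str | Path) -> LabeledImageSet:
    with h5py.File(path, "r") as f:
        return LabeledImageSet(
            f["images"][...],
            f["labels"][...],
            tuple(s.decode() for s in f["class_names"][...]),
            [s.decode() for s in f["provenance"][...]],
        )
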