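"""Dataset access: benchmark readers and a procedural synthetic generator.

All datasets are collections of 3x32x32 float images normalized to [-1, 1]
(the generator's tanh output range) with integer class labels.  The synthetic
generator renders one geometric shape per class with per-sample color,
position and scale jitter on a noisy background, so every training and
evaluation path can run without downloading anything.  Benchmark files are
never fetched automatically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledImageDataset",
    "load_cifar10",
    "load_svhn",
    "generate_synthetic",
    "batch_iterator",
    "normalize_pixels",
    "denormalize_pixels",
]

IMG_SHAPE = (3, 32, 32)


@dataclass
class LabeledImageDataset:
    """Images (N, 3, 32, 32) in [-1, 1] with integer labels in [0, num_classes)."""

    images: np.ndarray
    labels: np.ndarray
    split: str = "train"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[1:] != IMG_SHAPE:
            raise ValueError(f"expected images (N, 3, 32, 32), got {self.images.shape}")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels counts differ")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def num_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def normalize_pixels(raw: np.ndarray) -> np.ndarray:
    """Map [0, 255] pixel values to [-1, 1]."""
    return np.asarray(raw, dtype=np.float64) / 255.0 * 2.0 - 1.0


def denormalize_pixels(x: np.ndarray) -> np.ndarray:
    """Map [-1, 1] values back to [0, 255]."""
    return (np.asarray(x, dtype=np.float64) + 1.0) / 2.0 * 255.0


# -- benchmark readers --------------------------------------------------------

_CIFAR_TRAIN = [f"data_batch_{i}.bin" for i in range(1, 6)]
_CIFAR_TEST = ["test_batch.bin"]
_CIFAR_RECORD = 1 + 3072


def load_cifar10(root_path: str, split: str = "train") -> LabeledImageDataset:
    """Parse the CIFAR-10 binary batch format (never downloads).

    ``root_path`` is either the directory containing the ``*.bin`` files or its
    parent holding ``cifar-10-batches-bin/``.
    """
    if split not in ("train", "test"):
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    base = root_path
    if not os.path.exists(os.path.join(base, "data_batch_1.bin")):
        candidate = os.path.join(root_path, "cifar-10-batches-bin")
        if os.path.exists(os.path.join(candidate, "data_batch_1.bin")):
            base = candidate
    names = _CIFAR_TRAIN if split == "train" else _CIFAR_TEST
    images, labels = [], []
    for name in names:
        path = os.path.join(base, name)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"CIFAR-10 batch file missing: {path} (expected files: "
                f"{', '.join(names)})")
        raw = np.fromfile(path, dtype=np.uint8)
        if raw.size % _CIFAR_RECORD != 0:
            raise IOError(f"corrupt CIFAR-10 batch file (size {raw.size}): {path}")
        records = raw.reshape(-1, _CIFAR_RECORD)
        labels.append(records[:, 0].astype(np.int64))
        images.append(records[:, 1:].reshape(-1, 3, 32, 32))
    return LabeledImageDataset(normalize_pixels(np.concatenate(images)),
                               np.concatenate(labels), split=split)


def load_svhn(root_path: str, split: str = "train") -> LabeledImageDataset:
    """Parse the SVHN cropped-digits MAT format; label 10 is remapped to 0."""
    from scipy.io import loadmat

    if split not in ("train", "test"):
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    path = os.path.join(root_path, f"{split}_32x32.mat")
    if not os.path.exists(path):
        raise FileNotFoundError(f"SVHN file missing: {path}")
    mat = loadmat(path)
    x = mat["X"]  # (32, 32, 3, N)
    y = mat["y"].ravel().astype(np.int64) % 10
    images = np.transpose(x, (3, 2, 0, 1))
    return LabeledImageDataset(normalize_pixels(images), y, split=split)


# -- synthetic generator ------------------------------------------------------

def _shape_mask(kind: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:32, 0:32].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    if kind == 0:      # filled disk
        return dy * dy + dx * dx <= r * r
    if kind == 1:      # filled square
        return np.maximum(np.abs(dy), np.abs(dx)) <= r
    if kind == 2:      # upward triangle
        return (dy >= -r) & (dy <= r) & (np.abs(dx) <= 0.7 * (dy + r))
    if kind == 3:      # plus sign
        arm = max(r / 3.0, 1.0)
        return ((np.abs(dx) <= arm) & (np.abs(dy) <= r)) | \
               ((np.abs(dy) <= arm) & (np.abs(dx) <= r))
    if kind == 4:      # ring
        d2 = dy * dy + dx * dx
        return (d2 <= r * r) & (d2 >= (0.55 * r) ** 2)
    if kind == 5:      # diamond
        return np.abs(dy) + np.abs(dx) <= r
    if kind == 6:      # horizontal bars
        return (np.maximum(np.abs(dy), np.abs(dx)) <= r) & (np.mod(dy, 4) < 2)
    if kind == 7:      # frame (hollow square)
        m = np.maximum(np.abs(dy), np.abs(dx))
        return (m <= r) & (m >= 0.55 * r)
    raise ValueError(f"no shape template for class {kind}")


def generate_synthetic(num_classes: int = 4, n_per_class: int = 200,
                       jitter: float = 5.0, noise_std: float = 0.1,
                       seed: int = 0, split: str = "train",
                       background: float = 0.3) -> LabeledImageDataset:
    """Render a labeled shape dataset: class = shape, color is a per-sample
    nuisance variable.

    Each image is one geometric template (disk, square, triangle, ...) with a
    random color, center jittered by +-`jitter` pixels and radius jittered by
    +-20%, drawn on a gray background with additive Gaussian pixel noise.
    The background level is slightly off mid-gray so that patch occlusion
    (fill value 0 in [-1,1] coding) is a visible perturbation, as it is for
    natural images.  Deterministic given (seed, split); the train and test
    streams are disjoint.
    """
    if not 0.0 <= background <= 1.0:
        raise ValueError("background must be in [0, 1]")
    if num_classes < 2 or num_classes > 8:
        raise ValueError("num_classes must be in [2, 8]")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if split not in ("train", "test"):
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    rng = np.random.default_rng([seed, 0 if split == "train" else 1])
    n = num_classes * n_per_class
    images = np.empty((n, 3, 32, 32), dtype=np.float64)
    labels = np.repeat(np.arange(num_classes), n_per_class)
    base_radius = 9.0
    # color is a per-sample nuisance variable (prevents a pixel-space color
    # shortcut); the fully degenerate generator uses a fixed per-class palette
    degenerate = jitter == 0 and noise_std == 0
    palette = np.linspace(0.4, 1.0, num_classes)
    for i, cls in enumerate(labels):
        cy = 16.0 + rng.uniform(-jitter, jitter)
        cx = 16.0 + rng.uniform(-jitter, jitter)
        r = base_radius if degenerate else base_radius * rng.uniform(0.8, 1.2)
        color = np.full(3, palette[cls]) if degenerate else \
            rng.uniform(0.35, 1.0, size=3)
        mask = _shape_mask(int(cls), cy, cx, r)
        img = np.full((3, 32, 32), background)
        img[:, mask] = color[:, None]
        img += rng.normal(0.0, noise_std, size=(3, 32, 32))
        images[i] = np.clip(img * 2.0 - 1.0, -1.0, 1.0)
    return LabeledImageDataset(images, labels, split=split)


def batch_iterator(dataset: LabeledImageDataset, batch_size: int = 64,
                   shuffle_seed: int | None = 0):
    """Yield (images, labels) mini-batches over one epoch.

    The sample order is a seeded shuffle (or sequential when ``shuffle_seed``
    is None); the final short batch is dropped so every batch has exactly
    ``batch_size`` samples.
    """
    n = len(dataset)
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if batch_size > n:
        raise ValueError(f"batch_size {batch_size} exceeds dataset size {n}")
    order = np.arange(n)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)
    for start in range(0, n - batch_size + 1, batch_size):
        idx = order[start : start + batch_size]
        yield dataset.images[idx], dataset.labels[idx]
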