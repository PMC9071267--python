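"""Binary patch-occlusion masks for NREM training and robustness evaluation.

The image plane is tiled into square patches anchored at the top-left (the
right/bottom remainder patches are truncated rectangles when the size does not
divide the image side); each patch is independently zeroed with the given
probability.  Occluded pixels take value 0, i.e. mid-gray in [-1, 1] coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OcclusionSpec",
    "sample_occlusion_spec",
    "build_mask",
    "apply_mask",
    "occlude_batch",
]

MAX_TRAIN_SQUARE = 8


@dataclass(frozen=True)
class OcclusionSpec:
    probability: float
    square_size: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.square_size < 1:
            raise ValueError(f"square_size must be >= 1, got {self.square_size}")


def sample_occlusion_spec(rng: np.random.Generator) -> OcclusionSpec:
    """Draw probability ~ U[0,1] and square size ~ U{1,...,8} (one per mini-batch)."""
    return OcclusionSpec(probability=float(rng.uniform(0.0, 1.0)),
                         square_size=int(rng.integers(1, MAX_TRAIN_SQUARE + 1)))


def build_mask(spec: OcclusionSpec, height: int, width: int,
               rng: np.random.Generator) -> np.ndarray:
    """Sample one binary (height, width) mask: 0 = occluded patch, 1 = kept."""
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    s = spec.square_size
    ny = -(-height // s)
    nx = -(-width // s)
    keep = (rng.random((ny, nx)) >= spec.probability).astype(np.float64)
    mask = np.repeat(np.repeat(keep, s, axis=0), s, axis=1)
    return mask[:height, :width]


def apply_mask(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product, mask broadcast over batch and channel axes."""
    x = np.asarray(x)
    mask = np.asarray(mask)
    if x.shape[-2:] != mask.shape:
        raise ValueError(f"mask plane {mask.shape} does not match image plane "
                         f"{x.shape[-2:]}")
    return x * mask


def occlude_batch(x: np.ndarray, spec: OcclusionSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Occlude each sample of (b, c, h, w) with an independent mask realization."""
    x = np.asarray(x)
    b, _, h, w = x.shape
    out = np.empty_like(x)
    for i in range(b):
        out[i] = x[i] * build_mask(spec, h, w, rng)
    return out
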