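"""Representation-quality measurements on frozen encoder/generator networks.

Includes the linear softmax readout trained by SGD on frozen latents, test
separability (plain and under patch occlusion), a two-component PCA
projection, latent-space distance ratios, and the Frechet distance between
feature statistics of real and generated images with a pluggable feature
extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigvalsh

from .networks import NetworkParameters, encode_batched, generate_batched
from .objectives import MixingCoefficients, mix_memories
from .occlusion import OcclusionSpec, occlude_batch

__all__ = [
    "LinearReadout",
    "MetricsReport",
    "train_linear_readout",
    "linear_separability",
    "occlusion_robustness_curve",
    "pca_projection",
    "intra_inter_ratio",
    "clean_occluded_ratio",
    "frechet_distance",
    "pixel_features",
    "random_projection_features",
    "majority_baseline",
    "nrem_dream_images",
    "rem_dream_images",
    "evaluate_model",
]

EVAL_SQUARE_SIZE = 4  # evaluation occlusions always use size-4 squares


@dataclass
class LinearReadout:
    """y = W z softmax classifier over frozen latent codes (no bias)."""

    weights: np.ndarray  # (num_classes, n_z)

    def logits(self, latents: np.ndarray) -> np.ndarray:
        return latents @ self.weights.T

    def predict(self, latents: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest index
        return np.argmax(self.logits(latents), axis=1)


@dataclass
class MetricsReport:
    separability: float = np.nan
    occlusion_curve: dict = field(default_factory=dict)
    intra_inter_ratio: float = np.nan
    clean_occluded_ratio: float = np.nan
    fid_nrem: float = np.nan
    fid_rem: float = np.nan
    naive_baseline: float = np.nan
    pca_coordinates: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "separability": self.separability,
            "occlusion_curve": {str(k): v for k, v in self.occlusion_curve.items()},
            "intra_inter_ratio": self.intra_inter_ratio,
            "clean_occluded_ratio": self.clean_occluded_ratio,
            "fid_nrem": self.fid_nrem,
            "fid_rem": self.fid_rem,
            "naive_baseline": self.naive_baseline,
        }
        return out


def _softmax(y: np.ndarray) -> np.ndarray:
    y = y - y.max(axis=1, keepdims=True)
    e = np.exp(y)
    return e / e.sum(axis=1, keepdims=True)


def train_linear_readout(latents: np.ndarray, labels: np.ndarray,
                         num_classes: int = 10, learning_rate: float = 0.2,
                         epochs: int = 20, batch_size: int = 64,
                         seed: int = 0) -> LinearReadout:
    """Train W by mini-batch SGD on the multiclass cross-entropy loss.

    The encoder stays frozen: only the latent codes are consumed here.
    Plain SGD (no momentum), learning rate 0.2, 20 epochs, batch size 64.
    """
    latents = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("label out of range")
    n, n_z = latents.shape
    w = np.zeros((num_classes, n_z))
    rng = np.random.default_rng(seed)
    bsz = min(batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n - bsz + 1, bsz):
            idx = order[start : start + bsz]
            zb, tb = latents[idx], labels[idx]
            p = _softmax(zb @ w.T)              # (b, K)
            p[np.arange(len(idx)), tb] -= 1.0
            grad = p.T @ zb / len(idx)          # (K, n_z)
            w -= learning_rate * grad
    return LinearReadout(weights=w)


def readout_loss(readout: LinearReadout, latents: np.ndarray,
                 labels: np.ndarray) -> float:
    """Mean per-sample cross-entropy -log p(Y = t | z)."""
    p = _softmax(readout.logits(np.asarray(latents, dtype=np.float64)))
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels])))


def linear_separability(readout: LinearReadout, latents: np.ndarray,
                        labels: np.ndarray) -> float:
    """Fraction of samples whose argmax readout activity matches the label."""
    return float(np.mean(readout.predict(np.asarray(latents)) ==
                         np.asarray(labels)))


def occlusion_robustness_curve(readout: LinearReadout,
                               encoder_params: NetworkParameters,
                               images: np.ndarray, labels: np.ndarray,
                               intensities=tuple(range(0, 101, 10)),
                               square_size: int = EVAL_SQUARE_SIZE,
                               rng: np.random.Generator | None = None) -> dict:
    """Accuracy vs occlusion intensity (%); one independent mask per sample."""
    rng = rng if rng is not None else np.random.default_rng(0)
    images = np.asarray(images)
    curve = {}
    for q in intensities:
        spec = OcclusionSpec(probability=q / 100.0, square_size=square_size)
        occluded = occlude_batch(images, spec, rng) if q > 0 else images
        z = encode_batched(encoder_params, occluded)
        curve[int(q)] = linear_separability(readout, z, labels)
    return curve


def pca_projection(latents: np.ndarray) -> np.ndarray:
    """Coordinates of each sample on the top-2 principal components."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or latents.shape[0] < 3:
        raise ValueError("pca_projection needs a (n >= 3, n_z) latent array")
    centered = latents - latents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def _pair_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=1)


def _mean_inter_class_distance(latents: np.ndarray, labels: np.ndarray,
                               rng: np.random.Generator,
                               n_pairs: int = 10_000) -> float:
    if len(np.unique(labels)) < 2:
        raise ValueError("inter-class distance needs at least 2 classes")
    n = len(latents)
    dists = []
    while len(dists) < n_pairs:
        i = rng.integers(0, n, size=n_pairs)
        j = rng.integers(0, n, size=n_pairs)
        keep = labels[i] != labels[j]
        dists.extend(_pair_distances(latents[i[keep]], latents[j[keep]]))
    return float(np.mean(dists[:n_pairs]))


def intra_inter_ratio(encoder_params: NetworkParameters, images: np.ndarray,
                      labels: np.ndarray, rng: np.random.Generator,
                      n_intra_pairs: int = 1000,
                      n_inter_pairs: int = 10_000) -> float:
    """Mean same-class latent distance over mean different-class distance.

    Intra: ``n_intra_pairs`` random same-class pairs per class (sampled with
    replacement), averaged over classes.  Inter: ``n_inter_pairs`` random
    different-class pairs.
    """
    labels = np.asarray(labels)
    latents = encode_batched(encoder_params, np.asarray(images))
    intra_means = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        i = rng.choice(idx, size=n_intra_pairs)
        j = rng.choice(idx, size=n_intra_pairs)
        intra_means.append(_pair_distances(latents[i], latents[j]).mean())
    inter = _mean_inter_class_distance(latents, labels, rng, n_inter_pairs)
    return float(np.mean(intra_means) / inter)


def clean_occluded_ratio(encoder_params: NetworkParameters, images: np.ndarray,
                         labels: np.ndarray, rng: np.random.Generator,
                         occlusion_probability: float = 0.3,
                         n_pairs: int = 10_000) -> float:
    """Mean clean-vs-occluded latent distance over mean inter-class distance.

    Occlusion uses 30%-intensity size-4 squares by default; labels are needed
    only for the inter-class denominator.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    idx = rng.integers(0, len(images), size=n_pairs)
    clean = images[idx]
    spec = OcclusionSpec(probability=occlusion_probability,
                         square_size=EVAL_SQUARE_SIZE)
    occluded = occlude_batch(clean, spec, rng) if occlusion_probability > 0 \
        else clean
    z_clean = encode_batched(encoder_params, clean)
    z_occ = encode_batched(encoder_params, occluded)
    numer = _pair_distances(z_clean, z_occ).mean()
    latents = encode_batched(encoder_params, images)
    inter = _mean_inter_class_distance(latents, labels, rng, n_pairs)
    return float(numer / inter)


# -- Frechet distance ---------------------------------------------------------

def frechet_distance(features_real: np.ndarray,
                     features_gen: np.ndarray) -> float:
    """||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}).

    The trace of the matrix square root is computed from the eigenvalues of
    the symmetrized product, with small negative eigenvalues clipped to 0.
    """
    a = np.asarray(features_real, dtype=np.float64)
    b = np.asarray(features_gen, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimensionality mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per feature set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.atleast_2d(np.cov(a, rowvar=False))
    cov_b = np.atleast_2d(np.cov(b, rowvar=False))
    prod = cov_a @ cov_b
    eig = eigvalsh((prod + prod.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(eig, 0.0, None)).sum()
    diff = mu_a - mu_b
    fd = diff @ diff + np.trace(cov_a) + np.trace(cov_b) - 2.0 * tr_sqrt
    return float(max(fd, 0.0))


def pixel_features(images: np.ndarray, pool: int = 4) -> np.ndarray:
    """Desk-scale feature extractor: block-averaged pixels, flattened."""
    x = np.asarray(images, dtype=np.float64)
    b, c, h, w = x.shape
    x = x.reshape(b, c, h // pool, pool, w // pool, pool).mean(axis=(3, 5))
    return x.reshape(b, -1)


def random_projection_features(images: np.ndarray, dim: int = 64,
                               seed: int = 0) -> np.ndarray:
    """Fixed seeded random linear embedding of flattened pixels."""
    x = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((x.shape[1], dim)) / np.sqrt(x.shape[1])
    return x @ proj


def majority_baseline(labels: np.ndarray) -> float:
    """Accuracy of the best constant (majority-class) classifier."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / len(labels))


# -- dream sampling and the full report ---------------------------------------

def nrem_dream_images(params: NetworkParameters, images: np.ndarray) -> np.ndarray:
    """NREM-style dreams: direct generation from the encoded latents."""
    return generate_batched(params, encode_batched(params, images))


def rem_dream_images(params: NetworkParameters, images: np.ndarray,
                     rng: np.random.Generator,
                     coeffs: MixingCoefficients = MixingCoefficients()) -> np.ndarray:
    """REM-style dreams: generation from two mixed latent memories plus noise."""
    z = encode_batched(params, images)
    z_old = z[rng.permutation(len(z))]
    eps = rng.standard_normal(z.shape)
    return generate_batched(params, mix_memories(z, z_old, eps, coeffs))


def evaluate_model(params: NetworkParameters, train_dataset, test_dataset, *,
                   seed: int = 0, intensities=tuple(range(0, 101, 10)),
                   n_intra_pairs: int = 1000, n_inter_pairs: int = 10_000,
                   n_clean_occ_pairs: int = 10_000, readout_epochs: int = 20,
                   fid_samples: int = 2000,
                   feature_fn=pixel_features) -> MetricsReport:
    """Run the complete representation-quality suite on frozen networks.

    The readout is trained on latents of the training split and evaluated on
    the test split; dream realism compares generated samples against real
    training images under the injected ``feature_fn`` extractor.
    """
    rng = np.random.default_rng([seed, 11])
    num_classes = int(max(train_dataset.labels.max(),
                          test_dataset.labels.max())) + 1
    z_train = encode_batched(params, train_dataset.images)
    readout = train_linear_readout(z_train, train_dataset.labels,
                                   num_classes=num_classes,
                                   epochs=readout_epochs, seed=seed)
    z_test = encode_batched(params, test_dataset.images)
    report = MetricsReport()
    report.separability = linear_separability(readout, z_test,
                                              test_dataset.labels)
    report.naive_baseline = majority_baseline(test_dataset.labels)
    report.occlusion_curve = occlusion_robustness_curve(
        readout, params, test_dataset.images, test_dataset.labels,
        intensities=intensities, rng=np.random.default_rng([seed, 12]))
    report.intra_inter_ratio = intra_inter_ratio(
        params, test_dataset.images, test_dataset.labels,
        np.random.default_rng([seed, 13]), n_intra_pairs=n_intra_pairs,
        n_inter_pairs=n_inter_pairs)
    report.clean_occluded_ratio = clean_occluded_ratio(
        params, test_dataset.images, test_dataset.labels,
        np.random.default_rng([seed, 14]), n_pairs=n_clean_occ_pairs)
    report.pca_coordinates = pca_projection(z_test)
    n_fid = min(fid_samples, len(train_dataset))
    idx = rng.choice(len(train_dataset), size=n_fid, replace=False)
    real = train_dataset.images[idx]
    report.fid_nrem = frechet_distance(
        feature_fn(real), feature_fn(nrem_dream_images(params, real)))
    report.fid_rem = frechet_distance(
        feature_fn(real), feature_fn(rem_dream_images(params, real, rng)))
    return report
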