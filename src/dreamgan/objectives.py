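"""Phase-specific loss functions and the REM latent mixing rule.

All losses take/return :class:`~dreamgan.autograd.Tensor` (plain arrays are
wrapped), so they can sit inside a training graph or be evaluated standalone
via ``.item()``.  Discriminator scores are clamped to [1e-7, 1 - 1e-7] inside
log terms; the empirical standard deviation of the KL term is the uncorrected
(population) one, with a 1e-8 floor on the variance before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .networks import NetworkParameters, encode, generate

__all__ = [
    "MixingCoefficients",
    "image_reconstruction_loss",
    "kl_batch_loss",
    "discriminator_real_loss",
    "nrem_loss",
    "mix_memories",
    "rem_loss",
    "noisy_reconstruction_loss",
]

SCORE_EPS = 1e-7
VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class MixingCoefficients:
    """Convex-combination weights for REM latent mixing.

    ``lam`` weighs current vs previous memories; ``lam_prime`` weighs the
    memory mixture vs fresh Gaussian noise.  Defaults are 0.5 / 0.5.
    """

    lam: float = 0.5
    lam_prime: float = 0.5

    def __post_init__(self):
        for name in ("lam", "lam_prime"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def image_reconstruction_loss(x, x_recon) -> Tensor:
    """Mean over the batch of the squared Euclidean distance between images."""
    x, x_recon = _as_tensor(x), _as_tensor(x_recon)
    _check_same_shape(x, x_recon)
    b = x.shape[0]
    diff = x - x_recon
    return (diff * diff).sum() * (1.0 / b)


def kl_batch_loss(z) -> Tensor:
    """KL of the batch-empirical latent Gaussian against N(0, I).

    Uses per-dimension empirical mean and (population) standard deviation of
    the latent batch: (1 / 2 n_z) * sum_j (mu_j^2 + s_j^2 - 1 - log s_j^2).
    """
    z = _as_tensor(z)
    if z.ndim != 2:
        raise ValueError(f"expected latent batch (b, n_z), got {z.shape}")
    b, n_z = z.shape
    if b < 2:
        raise ValueError("kl_batch_loss needs batch size >= 2")
    mu = z.mean(axis=0)
    centered = z - mu.reshape(1, n_z)
    var = (centered * centered).mean(axis=0)
    term = mu * mu + var - 1.0 - var.clip(lo=VAR_FLOOR).log()
    return term.sum() * (1.0 / (2.0 * n_z))


def _clamped(d: Tensor) -> Tensor:
    return d.clip(SCORE_EPS, 1.0 - SCORE_EPS)


def discriminator_real_loss(d) -> Tensor:
    """Binary cross-entropy against target 1: -(1/b) sum_i log d_i."""
    d = _as_tensor(d)
    return -(_clamped(d).log().mean())


def rem_loss(d_fake) -> Tensor:
    """Binary cross-entropy against target 0: -(1/b) sum_i log(1 - d_i)."""
    d = _as_tensor(d_fake)
    return -((1.0 - _clamped(d)).log().mean())


def nrem_loss(z_target, z_recon) -> Tensor:
    """Mean squared Euclidean distance between stored and re-inferred latents.

    ``z_target`` is detached: no gradient flows into the stored memory.
    """
    z_target = _as_tensor(z_target).detach()
    z_recon = _as_tensor(z_recon)
    _check_same_shape(z_target, z_recon)
    b = z_target.shape[0]
    diff = z_recon - z_target
    return (diff * diff).sum() * (1.0 / b)


def mix_memories(z: np.ndarray, z_old: np.ndarray, eps: np.ndarray,
                 coeffs: MixingCoefficients = MixingCoefficients()) -> np.ndarray:
    """lam' * (lam * z + (1 - lam) * z_old) + (1 - lam') * eps, elementwise."""
    z, z_old, eps = (np.asarray(a) for a in (z, z_old, eps))
    if not (z.shape == z_old.shape == eps.shape):
        raise ValueError(
            f"shape mismatch: {z.shape}, {z_old.shape}, {eps.shape}")
    lam, lp = coeffs.lam, coeffs.lam_prime
    return lp * (lam * z + (1.0 - lam) * z_old) + (1.0 - lp) * eps


def noisy_reconstruction_loss(x, params: NetworkParameters, noise_std: float,
                              rng: np.random.Generator) -> Tensor:
    """Reconstruction loss with Gaussian noise injected into the latent code.

    Used as the Wake image loss in the no-REM ablation; the default noise has
    covariance 0.5 * I, i.e. ``noise_std = sqrt(0.5)``.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    x = _as_tensor(x)
    z = encode(params, x)
    eps = rng.normal(0.0, noise_std, size=z.shape)
    x_recon = generate(params, z + Tensor(eps))
    return image_reconstruction_loss(x, x_recon)
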