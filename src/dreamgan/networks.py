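"""Encoder/discriminator and generator architectures.

The encoder ``E`` maps 3x32x32 images through four stride-2 convolutions
(4x4 kernels, padding 1 except 0 for the last layer) to a flat latent vector;
a scalar sigmoid discriminator head branches off the third (second-to-last)
convolutional feature map, so the latent head and the discriminator head share
the same three-layer trunk.  The generator ``G`` mirrors the encoder with four
stride-2 transposed convolutions ending in tanh.  No normalization layers are
used anywhere.  All nonlinearities between layers are LeakyReLU(0.2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d, no_grad

__all__ = [
    "NetworkParameters",
    "init_parameters",
    "encode",
    "discriminate",
    "generate",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.2
KERNEL = 4
STRIDE = 2
IMG_CHANNELS = 3
IMG_SIZE = 32
DEFAULT_TRUNK = (64, 128, 256)
DEFAULT_LATENT = 256
INIT_STD = 0.02


@dataclass
class NetworkParameters:
    """Named parameter tensors for encoder (trunk + two heads) and generator.

    ``trunk`` holds the three shared convolutions, ``latent_head`` the final
    convolution producing z, ``disc_head`` the scalar discriminator branch, and
    ``generator`` the four transposed convolutions.
    """

    trunk: dict = field(default_factory=dict)
    latent_head: dict = field(default_factory=dict)
    disc_head: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    latent_dim: int = DEFAULT_LATENT
    trunk_channels: tuple = DEFAULT_TRUNK

    def encoder_parameters(self) -> dict:
        """All parameters updated by encoder-side descent (trunk + both heads)."""
        out = {}
        for prefix, group in (("trunk", self.trunk), ("latent", self.latent_head),
                              ("disc", self.disc_head)):
            out.update({f"{prefix}.{k}": v for k, v in group.items()})
        return out

    def generator_parameters(self) -> dict:
        return {f"gen.{k}": v for k, v in self.generator.items()}

    @property
    def dtype(self):
        return self.trunk["conv1.w"].data.dtype

    def all_parameters(self) -> dict:
        out = self.encoder_parameters()
        out.update(self.generator_parameters())
        return out


def init_parameters(latent_dim: int = DEFAULT_LATENT, seed: int = 0,
                    trunk_channels: tuple = DEFAULT_TRUNK,
                    init_std: float = INIT_STD,
                    dtype=np.float32) -> NetworkParameters:
    """Initialize all weights from N(0, init_std^2) with zero biases, seeded.

    `trunk_channels` sets the widths of the three shared convolutions (paper
    scale: 64, 128, 256); reduced widths give desk-scale models.  The default
    ``init_std`` of 0.02 matches the DCGAN convention at paper widths; narrow
    desk-scale stacks need a larger value to keep unit-order activations
    (signal scale goes like ``(init_std * sqrt(fan_in))^depth``).
    """
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    c1, c2, c3 = trunk_channels
    rng = np.random.default_rng(seed)

    def w(shape):
        return Tensor(rng.normal(0.0, init_std, size=shape).astype(dtype),
                      requires_grad=True)

    def b(n):
        return Tensor(np.zeros(n, dtype=dtype), requires_grad=True)

    params = NetworkParameters(latent_dim=latent_dim, trunk_channels=(c1, c2, c3))
    enc_specs = [(c1, IMG_CHANNELS), (c2, c1), (c3, c2)]
    for i, (o, c) in enumerate(enc_specs, start=1):
        params.trunk[f"conv{i}.w"] = w((o, c, KERNEL, KERNEL))
        params.trunk[f"conv{i}.b"] = b(o)
    params.latent_head["conv4.w"] = w((latent_dim, c3, KERNEL, KERNEL))
    params.latent_head["conv4.b"] = b(latent_dim)
    params.disc_head["conv.w"] = w((1, c3, KERNEL, KERNEL))
    params.disc_head["conv.b"] = b(1)
    gen_specs = [(latent_dim, c3), (c3, c2), (c2, c1), (c1, IMG_CHANNELS)]
    for i, (c, o) in enumerate(gen_specs, start=1):
        params.generator[f"deconv{i}.w"] = w((c, o, KERNEL, KERNEL))
        params.generator[f"deconv{i}.b"] = b(o)
    return params


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _check_image(x: Tensor) -> None:
    if x.ndim != 4 or x.shape[1] != IMG_CHANNELS or x.shape[2] != IMG_SIZE \
            or x.shape[3] != IMG_SIZE:
        raise ValueError(f"expected image batch (b, 3, 32, 32), got {x.shape}")


def _trunk_forward(params: NetworkParameters, x: Tensor) -> Tensor:
    h = x
    for i in (1, 2, 3):
        h = conv2d(h, params.trunk[f"conv{i}.w"], params.trunk[f"conv{i}.b"],
                   stride=STRIDE, padding=1)
        h = h.leaky_relu(LEAKY_SLOPE)
    return h  # (b, c3, 4, 4)


def encode(params: NetworkParameters, x) -> Tensor:
    """z = E_z(x): shared trunk plus the latent-head convolution (no final
    nonlinearity), flattened to (b, latent_dim)."""
    x = _as_tensor(x)
    _check_image(x)
    h = _trunk_forward(params, x)
    z = conv2d(h, params.latent_head["conv4.w"], params.latent_head["conv4.b"],
               stride=STRIDE, padding=0)
    return z.reshape(z.shape[0], params.latent_dim)


def discriminate(params: NetworkParameters, x) -> Tensor:
    """d = E_d(x) in (0,1): shared trunk, one extra convolution, sigmoid."""
    x = _as_tensor(x)
    _check_image(x)
    h = _trunk_forward(params, x)
    d = conv2d(h, params.disc_head["conv.w"], params.disc_head["conv.b"],
               stride=1, padding=0)
    return d.sigmoid().reshape(d.shape[0])


def generate(params: NetworkParameters, z) -> Tensor:
    """x' = G(z) in (-1,1): four stride-2 transposed convolutions, tanh output."""
    z = _as_tensor(z)
    if z.ndim != 2 or z.shape[1] != params.latent_dim:
        raise ValueError(
            f"expected latent batch (b, {params.latent_dim}), got {z.shape}")
    h = z.reshape(z.shape[0], params.latent_dim, 1, 1)
    for i in (1, 2, 3, 4):
        pad = 0 if i == 1 else 1
        h = conv_transpose2d(h, params.generator[f"deconv{i}.w"],
                             params.generator[f"deconv{i}.b"],
                             stride=STRIDE, padding=pad)
        h = h.tanh() if i == 4 else h.leaky_relu(LEAKY_SLOPE)
    return h


def encode_batched(params: NetworkParameters, images: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    """Forward-only encoding of a large image array in chunks; returns ndarray."""
    images = np.asarray(images, dtype=params.dtype)
    outs = []
    with no_grad():
        for i in range(0, len(images), chunk):
            outs.append(encode(params, images[i : i + chunk]).numpy())
    return np.concatenate(outs, axis=0).astype(np.float64)


def generate_batched(params: NetworkParameters, latents: np.ndarray,
                     chunk: int = 256) -> np.ndarray:
    """Forward-only generation from a large latent array in chunks."""
    latents = np.asarray(latents, dtype=params.dtype)
    outs = []
    with no_grad():
        for i in range(0, len(latents), chunk):
            outs.append(generate(params, latents[i : i + chunk]).numpy())
    return np.concatenate(outs, axis=0).astype(np.float64)


# -- checkpoint I/O -----------------------------------------------------------

def save_checkpoint(params: NetworkParameters, path) -> None:
    """Serialize all named tensors plus architecture metadata to an .npz."""
    arrays = {k: v.numpy() for k, v in params.all_parameters().items()}
    meta = json.dumps({"latent_dim": params.latent_dim,
                       "trunk_channels": list(params.trunk_channels)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> NetworkParameters:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = init_parameters(latent_dim=meta["latent_dim"], seed=0,
                                 trunk_channels=tuple(meta["trunk_channels"]))
        for key, tensor in params.all_parameters().items():
            tensor.data = np.array(archive[key])
    return params
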