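"""Three-phase Wake -> NREM -> REM training loop with Adam updates.

Each mini-batch drives one full cycle: Wake reconstructs external images and
trains the discriminator on them (descent on img + KL + real for the encoder,
img only for the generator), NREM replays the stored latent batch through the
generator, occludes the result and trains only the encoder to recover the
latents, and REM generates from mixed episodic memories plus noise and plays
the adversarial game — encoder/discriminator descends the fake-classification
loss while the generator ascends it (sign switch).

One Adam state per network (encoder incl. both heads; generator) is shared
across phases.  All randomness derives from ``TrainingConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, no_grad
from .datasets import LabeledImageDataset, batch_iterator
from .memory import EpisodicBuffer
from .networks import (NetworkParameters, DEFAULT_LATENT, DEFAULT_TRUNK,
                       discriminate, encode, generate, init_parameters)
from .objectives import (MixingCoefficients, discriminator_real_loss,
                         image_reconstruction_loss, kl_batch_loss, nrem_loss,
                         rem_loss)
from .occlusion import occlude_batch, sample_occlusion_spec

__all__ = [
    "TrainingConfig",
    "CycleState",
    "Adam",
    "wake_phase",
    "nrem_phase",
    "rem_phase",
    "run_training",
    "configure_pathology",
    "PATHOLOGIES",
]

PATHOLOGIES = ("full", "wo_rem", "wo_nrem", "wo_mix", "noise_only_rem",
               "swapped_order")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 1
    lam: float = 0.5
    lam_prime: float = 0.5
    enable_nrem: bool = True
    enable_rem: bool = True
    memory_mix_mode: str = "mix"  # mix | single | noise_only
    nrem_loss_scale: float = 1.0
    wake_latent_noise_var: float = 0.0  # 0.5 in the no-REM pathology
    phase_order: str = "nrem_first"  # nrem_first | rem_first
    seed: int = 0
    latent_dim: int = DEFAULT_LATENT
    trunk_channels: tuple = DEFAULT_TRUNK
    init_std: float = 0.02

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.adam_beta1 < 1 and 0 <= self.adam_beta2 < 1):
            raise ValueError("Adam betas must be in [0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.nrem_loss_scale < 0 or self.wake_latent_noise_var < 0:
            raise ValueError("scales must be >= 0")
        if self.memory_mix_mode not in ("mix", "single", "noise_only"):
            raise ValueError(f"unknown memory_mix_mode {self.memory_mix_mode!r}")
        if self.phase_order not in ("nrem_first", "rem_first"):
            raise ValueError(f"unknown phase_order {self.phase_order!r}")

    @property
    def mixing(self) -> MixingCoefficients:
        return MixingCoefficients(self.lam, self.lam_prime)


def configure_pathology(name: str, base: TrainingConfig | None = None,
                        **overrides) -> TrainingConfig:
    """Return the training configuration for a named sleep-pathology ablation."""
    cfg = base if base is not None else TrainingConfig()
    if name == "full":
        pass
    elif name == "wo_rem":
        # no adversarial dreaming; noisy wake reconstruction and halved NREM
        cfg = replace(cfg, enable_rem=False, wake_latent_noise_var=0.5,
                      nrem_loss_scale=0.5)
    elif name == "wo_nrem":
        cfg = replace(cfg, enable_nrem=False)
    elif name == "wo_mix":
        cfg = replace(cfg, memory_mix_mode="single")
    elif name == "noise_only_rem":
        cfg = replace(cfg, memory_mix_mode="noise_only")
    elif name == "swapped_order":
        cfg = replace(cfg, phase_order="rem_first")
    else:
        raise ValueError(f"unknown pathology {name!r}; choose from {PATHOLOGIES}")
    return replace(cfg, **overrides) if overrides else cfg


class Adam(object):
    """Adam over a named parameter dict, with optional per-step sign flip."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, ascend: bool = False) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            if ascend:
                g = -g
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class CycleState:
    parameters: NetworkParameters
    buffer: EpisodicBuffer
    enc_opt: Adam
    gen_opt: Adam
    iteration: int = 0
    epoch: int = 0
    trace: list = field(default_factory=list)
    rng_occlusion: np.random.Generator = None
    rng_mix: np.random.Generator = None
    rng_wake_noise: np.random.Generator = None

    @classmethod
    def initialize(cls, config: TrainingConfig) -> "CycleState":
        params = init_parameters(config.latent_dim, seed=config.seed,
                                 trunk_channels=config.trunk_channels,
                                 init_std=config.init_std)
        lr = config.learning_rate
        return cls(
            parameters=params,
            buffer=EpisodicBuffer(),
            enc_opt=Adam(params.encoder_parameters(), lr,
                         config.adam_beta1, config.adam_beta2),
            gen_opt=Adam(params.generator_parameters(), lr,
                         config.adam_beta1, config.adam_beta2),
            rng_occlusion=np.random.default_rng([config.seed, 101]),
            rng_mix=np.random.default_rng([config.seed, 102]),
            rng_wake_noise=np.random.default_rng([config.seed, 103]),
        )

    def _zero_all(self) -> None:
        self.enc_opt.zero_grad()
        self.gen_opt.zero_grad()

    def log(self, phase: str, **losses) -> None:
        row = {"iteration": self.iteration, "epoch": self.epoch, "phase": phase}
        row.update(losses)
        self.trace.append(row)


def wake_phase(state: CycleState, x: np.ndarray,
               config: TrainingConfig) -> CycleState:
    """Reconstruct a real mini-batch, regularize latents, classify as real."""
    params = state.parameters
    xt = Tensor(np.asarray(x, dtype=params.dtype))
    z = encode(params, xt)
    d = discriminate(params, xt)
    if config.wake_latent_noise_var > 0:
        eps = state.rng_wake_noise.normal(
            0.0, np.sqrt(config.wake_latent_noise_var),
            size=z.shape).astype(params.dtype)
        x_recon = generate(params, z + Tensor(eps))
    else:
        x_recon = generate(params, z)
    l_img = image_reconstruction_loss(xt, x_recon)
    l_kl = kl_batch_loss(z)
    l_real = discriminator_real_loss(d)
    total = l_img + l_kl + l_real
    state._zero_all()
    total.backward()
    # KL and real terms do not touch generator parameters, so the generator
    # gradient of `total` is exactly the gradient of the image loss
    state.enc_opt.step()
    state.gen_opt.step()
    state.buffer.store(z.detach().numpy())
    state.log("wake", img_loss=l_img.item(), kl_loss=l_kl.item(),
              real_loss=l_real.item())
    return state


def nrem_phase(state: CycleState, config: TrainingConfig) -> CycleState:
    """Replay stored latents through G, occlude, train the encoder only."""
    if not config.enable_nrem:
        return state
    params = state.parameters
    z_target = state.buffer.recall_for_nrem()
    with no_grad():
        x_gen = generate(params, z_target).numpy()
    spec = sample_occlusion_spec(state.rng_occlusion)
    x_occ = occlude_batch(x_gen, spec, state.rng_occlusion)
    z_recon = encode(params, Tensor(x_occ.astype(params.dtype)))
    loss = nrem_loss(z_target, z_recon)
    state.log("nrem", nrem_loss=loss.item())
    if config.nrem_loss_scale == 0:
        return state
    scaled = loss * config.nrem_loss_scale
    state._zero_all()
    scaled.backward()
    state.enc_opt.step()
    return state


def rem_phase(state: CycleState, config: TrainingConfig) -> CycleState:
    """Adversarial dreaming: E_d descends, G ascends the fake loss."""
    if not config.enable_rem:
        return state
    params = state.parameters
    buf = state.buffer
    if config.memory_mix_mode == "mix":
        z_mix = buf.recall_for_rem(config.mixing, state.rng_mix)
    elif config.memory_mix_mode == "single":
        z_mix = buf.recall_for_nrem()
    else:  # noise_only: pure spontaneous activity
        if buf.current is None:
            raise RuntimeError("episodic buffer is empty")
        z_mix = state.rng_mix.standard_normal(buf.current.shape)
    x_gen = generate(params, Tensor(np.asarray(z_mix, dtype=params.dtype)))
    d = discriminate(params, x_gen)
    loss = rem_loss(d)
    state._zero_all()
    loss.backward()
    state.enc_opt.step()
    state.gen_opt.step(ascend=True)  # sign switch: gradient ascent in G
    if buf.current is not None:
        buf.commit_old()
    state.log("rem", rem_loss=loss.item())
    return state


def run_training(dataset: LabeledImageDataset, config: TrainingConfig,
                 epoch_callback=None):
    """Run the full wake-sleep loop; returns (parameters, loss trace).

    ``epoch_callback(epoch, state)``, if given, is invoked after every epoch
    (e.g. to snapshot parameters or compute periodic metrics).  Labels are
    never used.  Fully reproducible given ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    state = CycleState.initialize(config)
    for epoch in range(config.epochs):
        state.epoch = epoch
        for x, _ in batch_iterator(dataset, config.batch_size,
                                   shuffle_seed=[config.seed, 7, epoch]):
            wake_phase(state, x, config)
            if config.phase_order == "nrem_first":
                nrem_phase(state, config)
                rem_phase(state, config)
            else:
                rem_phase(state, config)
                nrem_phase(state, config)
            state.iteration += 1
        if epoch_callback is not None:
            epoch_callback(epoch, state)
    return state.parameters, state.trace
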