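"""Desk-scale ablation experiment: train pathologies on synthetic shapes and
measure the representation-quality metrics used for model comparison.

This is a CPU-sized analogue of the full benchmark protocol: a small-width
network trained for a few hundred wake-sleep cycles on the procedural shape
dataset, evaluated with the linear readout, occlusion robustness, latent
distance ratios, and the Frechet distance (pixel-feature extractor).
"""

from __future__ import annotations

import copy

import numpy as np

from .datasets import generate_synthetic
from .evaluation import (clean_occluded_ratio, frechet_distance,
                         intra_inter_ratio, linear_separability,
                         nrem_dream_images, occlusion_robustness_curve,
                         pixel_features, rem_dream_images,
                         train_linear_readout)
from .networks import NetworkParameters, encode_batched
from .training import TrainingConfig, configure_pathology, run_training

__all__ = ["DeskScaleSettings", "run_condition", "desk_scale_ablation"]


class DeskScaleSettings:
    """Default sizes for the CPU-scale experiment (reduced widths/epochs)."""

    num_classes = 3
    n_per_class_train = 400
    n_per_class_test = 150
    jitter = 5.0
    noise_std = 0.1
    background = 0.3
    data_seed = 0
    trunk_channels = (8, 16, 32)
    latent_dim = 32
    init_std = 0.15  # width-aware init: keeps unit-order latents at this scale
    learning_rate = 1e-4  # keeps the narrow-net NREM gain loop in its stable basin
    batch_size = 64
    epochs = 30
    intensities = (0, 30, 50, 70)
    n_mask_draws = 3
    n_intra_pairs = 500
    n_inter_pairs = 2000
    n_clean_occ_pairs = 1000
    fid_samples = 600


def _datasets(s: DeskScaleSettings):
    train = generate_synthetic(s.num_classes, s.n_per_class_train,
                               jitter=s.jitter, noise_std=s.noise_std,
                               seed=s.data_seed, split="train",
                               background=s.background)
    test = generate_synthetic(s.num_classes, s.n_per_class_test,
                              jitter=s.jitter, noise_std=s.noise_std,
                              seed=s.data_seed, split="test",
                              background=s.background)
    return train, test


def run_condition(condition: str, seed: int,
                  settings: DeskScaleSettings | None = None) -> dict:
    """Train one pathology with one seed and return its metric dict.

    FID of REM dreams is recorded both after the first epoch and at the end
    of training (both against real training images, pixel features).
    """
    s = settings or DeskScaleSettings()
    train_ds, test_ds = _datasets(s)
    base = TrainingConfig(seed=seed, epochs=s.epochs, batch_size=s.batch_size,
                          learning_rate=s.learning_rate,
                          latent_dim=s.latent_dim, init_std=s.init_std,
                          trunk_channels=s.trunk_channels)
    config = configure_pathology(condition, base=base)

    snapshots = {}

    def on_epoch(epoch, state):
        if epoch == 0:
            snapshots["epoch1"] = {
                k: v.numpy().copy()
                for k, v in state.parameters.all_parameters().items()}

    params, trace = run_training(train_ds, config, epoch_callback=on_epoch)

    rng = np.random.default_rng([seed, 31])
    idx = rng.choice(len(train_ds), size=min(s.fid_samples, len(train_ds)),
                     replace=False)
    real = train_ds.images[idx]
    feats_real = pixel_features(real)

    def rem_fid(p: NetworkParameters) -> float:
        dreams = rem_dream_images(p, real, np.random.default_rng([seed, 32]))
        return frechet_distance(feats_real, pixel_features(dreams))

    fid_final = rem_fid(params)
    fid_first = np.nan
    if "epoch1" in snapshots:
        early = copy.deepcopy(params)
        for k, v in early.all_parameters().items():
            v.data = snapshots["epoch1"][k]
        fid_first = rem_fid(early)
    fid_nrem = frechet_distance(
        feats_real, pixel_features(nrem_dream_images(params, real)))

    z_train = encode_batched(params, train_ds.images)
    readout = train_linear_readout(z_train, train_ds.labels,
                                   num_classes=s.num_classes, seed=seed)
    z_test = encode_batched(params, test_ds.images)
    # average the occlusion curve over several independent mask draws to keep
    # accuracy differences above sampling noise
    draws = [occlusion_robustness_curve(
        readout, params, test_ds.images, test_ds.labels,
        intensities=s.intensities, rng=np.random.default_rng([seed, 33, k]))
        for k in range(s.n_mask_draws)]
    curve = {q: float(np.mean([d[q] for d in draws])) for q in s.intensities}
    return {
        "condition": condition,
        "seed": seed,
        "separability": linear_separability(readout, z_test, test_ds.labels),
        "occlusion_curve": curve,
        "intra_inter_ratio": intra_inter_ratio(
            params, test_ds.images, test_ds.labels,
            np.random.default_rng([seed, 34]),
            n_intra_pairs=s.n_intra_pairs, n_inter_pairs=s.n_inter_pairs),
        "clean_occluded_ratio": clean_occluded_ratio(
            params, test_ds.images, test_ds.labels,
            np.random.default_rng([seed, 35]), n_pairs=s.n_clean_occ_pairs),
        "fid_rem_first_epoch": fid_first,
        "fid_rem_final": fid_final,
        "fid_nrem_final": fid_nrem,
        "trace": trace,
    }


def desk_scale_ablation(conditions=("full", "wo_rem", "wo_nrem"),
                        seeds=(0, 1, 2),
                        settings: DeskScaleSettings | None = None) -> dict:
    """Run every (condition, seed) pair; returns {condition: [metrics...]}."""
    results: dict = {}
    for condition in conditions:
        results[condition] = [run_condition(condition, seed, settings)
                              for seed in seeds]
    return results


def summarize(results: dict, key: str) -> dict:
    """Mean and SEM over seeds of a scalar metric per condition."""
    out = {}
    for condition, runs in results.items():
        vals = np.array([r[key] for r in runs], dtype=np.float64)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out[condition] = {"mean": float(vals.mean()), "sem": float(sem)}
    return out
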