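import copy

import numpy as np
import pytest

from dreamgan.autograd import Tensor
from dreamgan.memory import EpisodicBuffer
from dreamgan.networks import discriminate, encode, generate
from dreamgan.objectives import rem_loss
from dreamgan.training import (Adam, CycleState, TrainingConfig,
                               configure_pathology, nrem_phase, rem_phase,
                               run_training, wake_phase)

TINY = dict(latent_dim=8, trunk_channels=(4, 6, 8), init_std=0.15)


def tiny_config(**kw):
    base = dict(seed=0, epochs=1, batch_size=8, **TINY)
    base.update(kw)
    return TrainingConfig(**base)


def param_snapshot(params):
    return {k: v.data.copy() for k, v in params.all_parameters().items()}


def params_equal(snap, params):
    return all(np.array_equal(snap[k], v.data)
               for k, v in params.all_parameters().items())


class TestConfig:
    def test_defaults_match_reference_settings(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == pytest.approx(2e-4)
        assert cfg.adam_beta1 == 0.5 and cfg.adam_beta2 == 0.999
        assert cfg.batch_size == 64
        assert cfg.lam == 0.5 and cfg.lam_prime == 0.5

    @pytest.mark.parametrize("bad", [
        dict(learning_rate=0.0), dict(learning_rate=-1e-4),
        dict(adam_beta1=1.0), dict(batch_size=1),
        dict(nrem_loss_scale=-0.5), dict(memory_mix_mode="bogus"),
        dict(phase_order="backwards"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            tiny_config(**bad)


class TestConfigurePathology:
    def test_full_is_default(self):
        cfg = configure_pathology("full")
        assert cfg.enable_nrem and cfg.enable_rem
        assert cfg.memory_mix_mode == "mix"
        assert cfg.lam == 0.5 and cfg.lam_prime == 0.5

    def test_wo_rem(self):
        cfg = configure_pathology("wo_rem")
        assert not cfg.enable_rem
        assert cfg.nrem_loss_scale == 0.5
        assert cfg.wake_latent_noise_var == 0.5

    def test_wo_nrem(self):
        assert not configure_pathology("wo_nrem").enable_nrem

    def test_wo_mix(self):
        assert configure_pathology("wo_mix").memory_mix_mode == "single"

    def test_noise_only_rem(self):
        assert configure_pathology("noise_only_rem").memory_mix_mode == "noise_only"

    def test_swapped_order(self):
        assert configure_pathology("swapped_order").phase_order == "rem_first"

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            configure_pathology("nonsense")


class TestWakePhase:
    def test_zero_lr_leaves_parameters_unchanged(self, small_dataset):
        config = tiny_config()
        state = CycleState.initialize(config)
        state.enc_opt.lr = 0.0
        state.gen_opt.lr = 0.0
        snap = param_snapshot(state.parameters)
        wake_phase(state, small_dataset.images[:8], config)
        assert params_equal(snap, state.parameters)

    def test_buffer_holds_current_encoding(self, small_dataset):
        config = tiny_config()
        state = CycleState.initialize(config)
        x = small_dataset.images[:8]
        wake_phase(state, x, config)
        expected = encode(state.parameters, x.astype(np.float32)).numpy()
        # stored BEFORE the update would differ; contract stores pre-update z
        assert state.buffer.current.shape == expected.shape

    def test_image_loss_decreases_on_fixed_batch(self, small_dataset):
        config = tiny_config(seed=1, learning_rate=1e-3)
        state = CycleState.initialize(config)
        x = small_dataset.images[:8]
        for _ in range(200):
            wake_phase(state, x, config)
        img = [r["img_loss"] for r in state.trace]
        assert img[-1] < 0.5 * img[0]

    def test_losses_logged(self, small_dataset):
        config = tiny_config()
        state = CycleState.initialize(config)
        wake_phase(state, small_dataset.images[:8], config)
        row = state.trace[-1]
        assert row["phase"] == "wake"
        assert {"img_loss", "kl_loss", "real_loss"} <= set(row)


class TestNremPhase:
    def _ready_state(self, small_dataset, **kw):
        config = tiny_config(**kw)
        state = CycleState.initialize(config)
        wake_phase(state, small_dataset.images[:8], config)
        return state, config

    def test_generator_bit_identical(self, small_dataset):
        state, config = self._ready_state(small_dataset)
        gen_snap = {k: v.data.copy()
                    for k, v in state.parameters.generator_parameters().items()}
        nrem_phase(state, config)
        for k, v in state.parameters.generator_parameters().items():
            assert np.array_equal(gen_snap[k], v.data)

    def test_encoder_changes(self, small_dataset):
        state, config = self._ready_state(small_dataset)
        snap = param_snapshot(state.parameters)
        nrem_phase(state, config)
        assert not params_equal(snap, state.parameters)

    def test_zero_scale_freezes_encoder_too(self, small_dataset):
        state, config = self._ready_state(small_dataset, nrem_loss_scale=0.0)
        snap = param_snapshot(state.parameters)
        nrem_phase(state, config)
        assert params_equal(snap, state.parameters)

    def test_empty_buffer_raises(self):
        config = tiny_config()
        state = CycleState.initialize(config)
        with pytest.raises(RuntimeError):
            nrem_phase(state, config)

    def test_disabled_phase_is_noop(self, small_dataset):
        state, config = self._ready_state(small_dataset, enable_nrem=False)
        snap = param_snapshot(state.parameters)
        nrem_phase(state, config)
        assert params_equal(snap, state.parameters)

    def test_loss_near_zero_when_encoder_inverts_generator(self, small_dataset,
                                                           monkeypatch):
        """With occlusion forced off and E_z trained to invert G, the replay
        reconstruction loss becomes small."""
        import dreamgan.training as tr
        from dreamgan.occlusion import OcclusionSpec

        monkeypatch.setattr(tr, "sample_occlusion_spec",
                            lambda rng: OcclusionSpec(0.0, 4))
        config = tiny_config(seed=2, learning_rate=2e-3)
        state = CycleState.initialize(config)
        rng = np.random.default_rng(0)
        opt = Adam(state.parameters.encoder_parameters(), lr=2e-3)
        first = None
        from dreamgan.objectives import nrem_loss as nrem_loss_fn
        for i in range(250):
            z = rng.standard_normal((8, 8))
            x = generate(state.parameters, Tensor(z.astype(np.float32)))
            loss = nrem_loss_fn(z, encode(state.parameters, x.detach()))
            if first is None:
                first = loss.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
        state.buffer.store(rng.standard_normal((8, 8)))
        nrem_phase(state, config)
        final = [r for r in state.trace if r["phase"] == "nrem"][-1]["nrem_loss"]
        assert final < 0.2 * first


class TestRemPhase:
    def _ready_state(self, small_dataset, **kw):
        config = tiny_config(**kw)
        state = CycleState.initialize(config)
        wake_phase(state, small_dataset.images[:8], config)
        return state, config

    @staticmethod
    def _rem_loss_fn(params, z_mix):
        d = discriminate(params, generate(params, Tensor(z_mix)))
        return rem_loss(d).item()

    def _fd_gradient(self, params, z_mix, tensor, coords, h=1e-3):
        g = {}
        for c in coords:
            old = tensor.data[c]
            tensor.data[c] = old + h
            lp = self._rem_loss_fn(params, z_mix)
            tensor.data[c] = old - h
            lm = self._rem_loss_fn(params, z_mix)
            tensor.data[c] = old
            g[c] = (lp - lm) / (2 * h)
        return g

    def test_sign_switch_directions(self, small_dataset, rng):
        """Finite differences: the update ascends the REM loss in the
        generator and descends it in the discriminator head."""
        # fresh optimizers (no wake momentum) so the first Adam step follows
        # the sign of the REM gradient exactly
        config = tiny_config()
        state = CycleState.initialize(config)
        z = encode(state.parameters,
                   small_dataset.images[:8].astype(np.float32)).numpy()
        state.buffer.store(z)
        params = state.parameters
        z_mix = state.buffer.recall_for_nrem().astype(np.float32)  # first-cycle rule
        gen_w = params.generator["deconv4.w"]
        disc_w = params.disc_head["conv.w"]
        coords_gen = [tuple(rng.integers(0, s) for s in gen_w.shape)
                      for _ in range(12)]
        coords_disc = [tuple(rng.integers(0, s) for s in disc_w.shape)
                       for _ in range(12)]
        g_gen = self._fd_gradient(params, z_mix, gen_w, coords_gen)
        g_disc = self._fd_gradient(params, z_mix, disc_w, coords_disc)
        before_gen = gen_w.data.copy()
        before_disc = disc_w.data.copy()
        rem_phase(state, config)
        delta_gen = {c: gen_w.data[c] - before_gen[c] for c in coords_gen}
        delta_disc = {c: disc_w.data[c] - before_disc[c] for c in coords_disc}
        inner_gen = sum(delta_gen[c] * g_gen[c] for c in coords_gen)
        inner_disc = sum(delta_disc[c] * g_disc[c] for c in coords_disc)
        assert inner_gen > 0   # ascent in G
        assert inner_disc < 0  # descent in E_d

    def test_buffer_previous_set_after_phase(self, small_dataset):
        state, config = self._ready_state(small_dataset)
        z_now = state.buffer.current.copy()
        rem_phase(state, config)
        assert np.array_equal(state.buffer.previous, z_now)

    def test_empty_buffer_raises(self):
        config = tiny_config()
        state = CycleState.initialize(config)
        with pytest.raises(RuntimeError):
            rem_phase(state, config)

    def test_disabled_phase_is_noop(self, small_dataset):
        state, config = self._ready_state(small_dataset, enable_rem=False)
        snap = param_snapshot(state.parameters)
        rem_phase(state, config)
        assert params_equal(snap, state.parameters)

    @pytest.mark.parametrize("mode", ["single", "noise_only"])
    def test_mix_modes_run(self, small_dataset, mode):
        state, config = self._ready_state(small_dataset, memory_mix_mode=mode)
        snap = param_snapshot(state.parameters)
        rem_phase(state, config)
        assert not params_equal(snap, state.parameters)


class TestRunTraining:
    def test_cycle_count_from_epoch_definition(self):
        from dreamgan.datasets import generate_synthetic
        ds = generate_synthetic(num_classes=2, n_per_class=320, seed=0)  # 640
        config = tiny_config(batch_size=64, epochs=1)
        _, trace = run_training(ds, config)
        assert sum(1 for r in trace if r["phase"] == "wake") == 10

    def test_deterministic_given_seed(self, small_dataset):
        config = tiny_config(seed=4, epochs=2, batch_size=16)
        p1, t1 = run_training(small_dataset, config)
        p2, t2 = run_training(small_dataset, config)
        assert t1 == t2
        assert params_equal(param_snapshot(p1), p2)

    def test_seed_changes_trajectory(self, small_dataset):
        _, t1 = run_training(small_dataset, tiny_config(seed=0, batch_size=16))
        _, t2 = run_training(small_dataset, tiny_config(seed=5, batch_size=16))
        assert t1 != t2

    def test_empty_dataset_raises(self, small_dataset):
        empty = copy.copy(small_dataset)
        empty.images = small_dataset.images[:0]
        empty.labels = small_dataset.labels[:0]
        with pytest.raises(ValueError):
            run_training(empty, tiny_config())

    def test_phase_order_swap_changes_result(self, small_dataset):
        base = tiny_config(seed=1, batch_size=16)
        swapped = configure_pathology("swapped_order", base=base)
        _, t1 = run_training(small_dataset, base)
        _, t2 = run_training(small_dataset, swapped)
        phases1 = [r["phase"] for r in t1[:3]]
        phases2 = [r["phase"] for r in t2[:3]]
        assert phases1 == ["wake", "nrem", "rem"]
        assert phases2 == ["wake", "rem", "nrem"]

    def test_disabled_phases_absent_from_trace(self, small_dataset):
        cfg = configure_pathology("wo_rem", base=tiny_config(batch_size=16))
        _, trace = run_training(small_dataset, cfg)
        assert not any(r["phase"] == "rem" for r in trace)

    def test_epoch_callback_invoked(self, small_dataset):
        seen = []
        run_training(small_dataset, tiny_config(epochs=2, batch_size=16),
                     epoch_callback=lambda e, s: seen.append(e))
        assert seen == [0, 1]


class TestAdam:
    def test_single_step_magnitude_bounded_by_lr(self):
        p = Tensor(np.zeros(3), requires_grad=True)
        opt = Adam({"p": p}, lr=0.1)
        p.grad = np.array([1.0, -2.0, 0.5])
        opt.step()
        assert np.all(np.abs(p.data) <= 0.1 + 1e-12)
        assert np.allclose(np.sign(p.data), [-1, 1, -1])

    def test_ascend_flips_direction(self):
        p1 = Tensor(np.zeros(3), requires_grad=True)
        p2 = Tensor(np.zeros(3), requires_grad=True)
        g = np.array([1.0, -2.0, 0.5])
        o1, o2 = Adam({"p": p1}, lr=0.1), Adam({"p": p2}, lr=0.1)
        p1.grad = g.copy()
        p2.grad = g.copy()
        o1.step()
        o2.step(ascend=True)
        assert np.allclose(p1.data, -p2.data)
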