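import math

import numpy as np
import pytest

import mapgan.gan_core as gc
from mapgan.errors import ConfigError
from mapgan.gan_core import (
    Checkpoint,
    GanConfig,
    adversarial_loss,
    build_discriminator,
    build_generator,
    count_parameters,
    discriminator_loss,
    generate_map,
    generator_loss,
    smooth_l1,
    toy_config,
    train,
)
from mapgan.nn.autograd import Tensor

from .conftest import make_model


def tiny_config(**overrides):
    """Very small net on 16³ volumes for fast unit tests."""
    defaults = dict(
        generator_widths=(2, 4),
        convs_per_block=1,
        discriminator_widths=(2, 4, 8, 8),
        fc_widths=(8, 8, 4, 1),
        batch_size=4,
        epochs=2,
        seed=0,
        tile_size=16,
    )
    defaults.update(overrides)
    return GanConfig(**defaults)


def tiny_dataset(rng, n=16, size=16, target="blur"):
    sims = rng.random((n, size, size, size)).astype(np.float32)
    if target == "identity":
        exps = sims.copy()
    else:
        from scipy.ndimage import gaussian_filter

        exps = np.stack([gaussian_filter(s, 1.5) for s in sims]).astype(np.float32)
    return sims, exps


class TestArchitectureBudgets:
    def test_generator_parameter_count_10_3_million(self):
        gen = build_generator(GanConfig(), np.random.default_rng(0))
        assert round(count_parameters(gen) / 1e6, 1) == 10.3

    def test_discriminator_parameter_count_1_2_million(self):
        disc = build_discriminator(GanConfig(), np.random.default_rng(0))
        assert round(count_parameters(disc) / 1e6, 1) == 1.2

    def test_parameter_count_monotone_in_width(self):
        counts = []
        for w0 in (2, 4, 8):
            cfg = GanConfig(
                generator_widths=(w0, 2 * w0, 4 * w0), convs_per_block=1
            )
            counts.append(count_parameters(build_generator(cfg)))
        assert counts[0] < counts[1] < counts[2]

    def test_too_deep_config_rejected(self):
        with pytest.raises(ConfigError):
            GanConfig(generator_widths=(2, 4, 8, 16, 32, 64))  # depth 5 on 32³

    def test_negative_alpha_rejected(self):
        with pytest.raises(ConfigError):
            GanConfig(alpha=-0.1)


class TestNetworkContracts:
    def test_generator_shape_contract(self, rng):
        gen = build_generator(toy_config(), np.random.default_rng(1))
        x = Tensor(rng.random((1, 1, 32, 32, 32)).astype(np.float32))
        assert gen(x).shape == (1, 1, 32, 32, 32)

    def test_discriminator_scalar_in_unit_interval(self, rng):
        disc = build_discriminator(toy_config(), np.random.default_rng(2))
        out = disc(Tensor(rng.random((3, 1, 32, 32, 32)).astype(np.float32)))
        assert out.shape == (3, 1)
        assert np.all(out.data > 0.0) and np.all(out.data < 1.0)

    def test_discriminator_not_degenerate(self):
        # constant-zero vs constant-one inputs must score differently
        disc = build_discriminator(toy_config(), np.random.default_rng(3))
        zeros = disc(Tensor(np.zeros((1, 1, 32, 32, 32), np.float32))).item()
        ones = disc(Tensor(np.ones((1, 1, 32, 32, 32), np.float32))).item()
        assert zeros != pytest.approx(ones, abs=1e-9)


class TestLossClosedForms:
    def test_smooth_l1_zero_difference(self):
        x = np.ones((4, 4))
        assert smooth_l1(x, x) == 0.0

    def test_smooth_l1_quadratic_branch(self):
        assert smooth_l1(np.array([0.5]), np.array([0.0])) == pytest.approx(0.125)

    def test_smooth_l1_linear_branch(self):
        assert smooth_l1(np.array([2.0]), np.array([0.0])) == pytest.approx(1.5)

    def test_smooth_l1_branch_continuity(self):
        at_one = smooth_l1(np.array([1.0]), np.array([0.0]))
        assert at_one == pytest.approx(0.5)
        just_below = smooth_l1(np.array([1.0 - 1e-9]), np.array([0.0]))
        assert just_below == pytest.approx(0.5, abs=1e-8)

    def test_adversarial_perfect_fooling(self):
        assert adversarial_loss(1.0 - 1e-7) == pytest.approx(0.0, abs=1e-6)

    def test_adversarial_at_half(self):
        assert adversarial_loss(0.5) == pytest.approx(math.log(2.0), rel=1e-9)

    def test_adversarial_monotone_decreasing(self):
        vals = [adversarial_loss(p) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_generator_composite(self):
        x = np.zeros((2, 2))
        assert generator_loss(x, x, 0.5, alpha=0.01) == pytest.approx(
            0.01 * math.log(2.0), rel=1e-6
        )
        assert 0.01 * math.log(2.0) == pytest.approx(0.006931, abs=1e-6)

    def test_generator_alpha_zero_reduces_to_smooth_l1(self, rng):
        x = rng.random((3, 3))
        y = rng.random((3, 3))
        assert generator_loss(x, y, 0.123, alpha=0.0) == pytest.approx(smooth_l1(x, y))

    def test_generator_without_l1_reduces_to_adversarial(self, rng):
        x = rng.random((3, 3))
        y = rng.random((3, 3))
        assert generator_loss(x, y, 0.3, alpha=1.0, use_smooth_l1=False) == (
            pytest.approx(adversarial_loss(0.3))
        )

    def test_generator_linear_in_alpha(self, rng):
        x = rng.random((3, 3))
        y = rng.random((3, 3))
        base = smooth_l1(x, y)
        l1 = generator_loss(x, y, 0.4, alpha=0.3) - base
        l2 = generator_loss(x, y, 0.4, alpha=0.7) - base
        l3 = generator_loss(x, y, 0.4, alpha=1.0) - base
        assert l1 + l2 == pytest.approx(l3, rel=1e-9)

    def test_discriminator_perfect(self):
        assert discriminator_loss(1.0 - 1e-7, 1e-7) == pytest.approx(0.0, abs=1e-5)

    def test_discriminator_at_half(self):
        assert discriminator_loss(0.5, 0.5) == pytest.approx(2 * math.log(2.0), rel=1e-9)

    def test_discriminator_swap_symmetry(self, rng):
        dr, df = 0.8, 0.3
        assert discriminator_loss(dr, df) == pytest.approx(
            discriminator_loss(1 - df, 1 - dr), rel=1e-9
        )

    def test_autograd_losses_match_closed_forms(self, rng):
        x = rng.random((2, 8)).astype(np.float32)
        y = rng.random((2, 8)).astype(np.float32)
        from mapgan.nn import autograd as ag

        auto = ag.smooth_l1_loss(Tensor(x), Tensor(y)).item()
        assert auto == pytest.approx(smooth_l1(x, y), abs=1e-6)
        d = rng.random((4, 1)).astype(np.float32) * 0.8 + 0.1
        assert gc._adv_loss_t(Tensor(d)).item() == pytest.approx(
            adversarial_loss(d), abs=1e-6
        )
        dr = rng.random((4, 1)).astype(np.float32) * 0.8 + 0.1
        assert gc._disc_loss_t(Tensor(dr), Tensor(d)).item() == pytest.approx(
            discriminator_loss(dr, d), abs=1e-5
        )


class TestTraining:
    def test_loss_history_lengths(self, rng):
        sims, exps = tiny_dataset(rng)
        ck = train((sims[:12], exps[:12]), (sims[12:], exps[12:]), tiny_config(epochs=2))
        assert len(ck.loss_history["generator"]) == 2
        assert len(ck.loss_history["discriminator"]) == 2
        assert ck.epoch == 2

    def test_seeded_determinism(self, rng):
        sims, exps = tiny_dataset(rng)
        cfg = tiny_config(epochs=2, seed=9)
        a = train((sims[:12], exps[:12]), (sims[12:], exps[12:]), cfg)
        b = train((sims[:12], exps[:12]), (sims[12:], exps[12:]), cfg)
        assert a.loss_history == b.loss_history
        for k in a.generator_state:
            np.testing.assert_array_equal(a.generator_state[k], b.generator_state[k])

    def test_empty_dataset_rejected(self, rng):
        sims, exps = tiny_dataset(rng, n=4)
        empty = (sims[:0], exps[:0])
        with pytest.raises(ValueError):
            train(empty, (sims, exps), tiny_config())
        with pytest.raises(ValueError):
            train((sims, exps), empty, tiny_config())

    def test_identity_task_learns(self, rng):
        # alpha=0 pure regression on Y == X must reduce validation SmoothL1
        sims, exps = tiny_dataset(rng, n=16, target="identity")
        cfg = tiny_config(epochs=20, seed=4, alpha=0.0, learning_rate=3e-3)
        ck = train((sims[:12], exps[:12]), (sims[12:], exps[12:]), cfg)
        hist = ck.loss_history["generator"]
        assert hist[-1] < hist[0]

    def test_alpha_zero_never_queries_discriminator_in_g_step(self, rng, monkeypatch):
        counts = {"n": 0}
        original = gc.build_discriminator

        def counting_build(config, rng_=None):
            disc = original(config, rng_)
            orig_forward = disc.forward

            def forward(x):
                counts["n"] += 1
                return orig_forward(x)

            disc.forward = forward
            return disc

        monkeypatch.setattr(gc, "build_discriminator", counting_build)
        sims, exps = tiny_dataset(rng, n=8)
        cfg = tiny_config(epochs=2, alpha=0.0, batch_size=4)
        train((sims[:4], exps[:4]), (sims[4:], exps[4:]), cfg)
        # per epoch: 1 train batch x 2 D-step calls + 1 val batch x 2 calls
        assert counts["n"] == 2 * (2 + 2)

    def test_nonfinite_loss_aborts(self, rng):
        sims, exps = tiny_dataset(rng, n=4)
        exps = exps * np.float32(np.inf)
        with pytest.raises(RuntimeError, match="diverged"):
            train((sims, exps), (sims, exps), tiny_config(epochs=1))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(11)
    sims, exps = tiny_dataset(rng, n=8)
    cfg = tiny_config(epochs=1, seed=5)
    return train((sims[:6], exps[:6]), (sims[6:], exps[6:]), cfg), sims


@pytest.fixture(scope="module")
def toy_checkpoint():
    rng = np.random.default_rng(13)
    sims = rng.random((8, 32, 32, 32)).astype(np.float32)
    exps = sims.copy()
    cfg = toy_config(
        generator_widths=(2, 4),
        convs_per_block=1,
        discriminator_widths=(2, 4, 8, 8),
        fc_widths=(8, 4, 2, 1),
        epochs=1,
        seed=6,
        batch_size=4,
    )
    return train((sims[:6], exps[:6]), (sims[6:], exps[6:]), cfg)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, trained):
        ck, _ = trained
        ck.save(tmp_path / "ckpt")
        back = Checkpoint.load(tmp_path / "ckpt")
        assert back.config == ck.config
        assert back.epoch == ck.epoch
        assert back.loss_history == ck.loss_history
        for k in ck.generator_state:
            np.testing.assert_array_equal(back.generator_state[k], ck.generator_state[k])
        assert back.optimizer_g_state["t"] == ck.optimizer_g_state["t"]

    def test_generate_bit_stable_across_reload(self, tmp_path, trained):
        ck, sims = trained
        ck.save(tmp_path / "ckpt")
        back = Checkpoint.load(tmp_path / "ckpt")
        gen_a = build_generator(ck.config)
        gen_a.load_state_dict(ck.generator_state)
        gen_b = build_generator(back.config)
        gen_b.load_state_dict(back.generator_state)
        out_a = gc.apply_generator(gen_a, sims[:2])
        out_b = gc.apply_generator(gen_b, sims[:2])
        np.testing.assert_array_equal(out_a, out_b)


class TestGenerateMap:
    def test_grid_contract_and_determinism(self, rng, toy_checkpoint):
        checkpoint = toy_checkpoint
        model = make_model(rng.uniform(0, 12, size=(8, 3)))
        out1 = generate_map(model, checkpoint, margin=4.0)
        out2 = generate_map(model, checkpoint, margin=4.0)
        from mapgan.simulator import grid_from_model

        grid = grid_from_model(model, voxel=1.0, margin=4.0)
        assert out1.shape == grid.shape
        np.testing.assert_array_equal(out1.voxel_size, grid.voxel_size)
        np.testing.assert_array_equal(out1.origin, grid.origin)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert out1.data.min() >= 0.0  # negatives clamped

    def test_incompatible_checkpoint_rejected(self, toy_checkpoint):
        bad = Checkpoint(
            config=GanConfig(generator_widths=(3, 6), convs_per_block=1),
            generator_state=toy_checkpoint.generator_state,
            discriminator_state=toy_checkpoint.discriminator_state,
        )
        from mapgan.volume_io import DensityMap

        sim = DensityMap(np.random.rand(24, 24, 24).astype(np.float32), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ConfigError):
            gc.translate_map(sim, bad)
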