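"""Schedules, sampling, augmentation and the optimisation step."""
import numpy as np
import pytest

from conftest import tiny_train_config
from vangan.training import (TrainConfig, Trainer, augment, learning_rate,
                             noise_sigma, sample_seg_volume, split_dataset)


class TestSchedules:
    def test_noise_variance_endpoints_and_midpoint(self):
        cfg = TrainConfig()
        assert noise_sigma(0, cfg) ** 2 == pytest.approx(0.1)
        assert noise_sigma(200, cfg) == 0.0
        assert noise_sigma(100, cfg) ** 2 == pytest.approx(0.05)

    def test_noise_variance_non_increasing(self):
        cfg = TrainConfig()
        sig = [noise_sigma(i, cfg) for i in range(0, 201, 10)]
        assert all(b <= a for a, b in zip(sig, sig[1:]))

    def test_learning_rate_plateau_then_linear_decay(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(2e-4)
        assert learning_rate(100, cfg) == pytest.approx(2e-4)
        assert learning_rate(150, cfg) == pytest.approx(1e-4)
        assert learning_rate(200, cfg) == 0.0

    def test_epoch_bounds_enforced(self):
        with pytest.raises(ValueError):
            noise_sigma(300, TrainConfig())


class TestSplit:
    def test_ten_volumes_split_1_7_2(self):
        train, val, test = split_dataset(10, seed=3)
        assert (len(test), len(train), len(val)) == (1, 7, 2)
        all_idx = np.concatenate([train, val, test])
        assert sorted(all_idx) == list(range(10))

    def test_split_deterministic_given_seed(self):
        a = split_dataset(50, seed=11)
        b = split_dataset(50, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSampler:
    def test_pool_of_foreground_patches_returns_first_draw(self, rng):
        pool = [np.ones((4, 4, 4))] * 5
        out = sample_seg_volume(pool, rng)
        assert out.sum() == 64

    def test_forced_bias_branch_redraws_empty_patches(self):
        pool = [np.zeros((2, 2, 2)), np.ones((2, 2, 2))]

        class ForcedRng:
            """First draw picks the empty patch, bias branch always fires."""

            def __init__(self):
                self.int_calls = 0

            def integers(self, n):
                self.int_calls += 1
                return 0 if self.int_calls == 1 else 1

            def random(self):
                return 0.0  # always below vessel_bias_prob -> redraw

        forced = ForcedRng()
        out = sample_seg_volume(pool, forced, vessel_bias_prob=0.9)
        assert out.sum() == 8
        assert forced.int_calls == 2

    def test_empirical_rate_matches_direct_simulation_of_the_rule(self):
        # pool half empty: the empty-return probability under the rule is
        # q = 0.1 * 0.5 / (1 - 0.9 * 0.5) by summing the geometric series
        p_empty, bias = 0.5, 0.9
        n = 100_000
        rng = np.random.default_rng(0)
        pool = [np.zeros((1, 1, 1)), np.ones((1, 1, 1))]
        empirical = 0
        for _ in range(n):
            if sample_seg_volume(pool, rng, bias).sum() == 0:
                empirical += 1
        sim_rng = np.random.default_rng(1)
        simulated = 0
        for _ in range(n):
            while True:
                empty = sim_rng.integers(2) == 0
                if not empty or sim_rng.random() >= bias:
                    simulated += empty
                    break
        assert abs(empirical / n - simulated / n) < 0.02


class TestAugment:
    def test_zero_rotation_possible_and_identity(self, rng):
        patch = rng.random((6, 6, 4))
        seen_identity = False
        for seed in range(20):
            out = augment(patch, np.random.default_rng(seed))
            if np.array_equal(out, patch):
                seen_identity = True
        assert seen_identity

    def test_four_quarter_turns_recover_the_patch(self, rng):
        patch = rng.random((6, 6, 4))
        out = patch
        for _ in range(4):
            out = np.rot90(out, k=1, axes=(0, 1))
        assert np.array_equal(out, patch)

    def test_rotation_preserves_foreground_count(self, rng):
        patch = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        for seed in range(10):
            out = augment(patch, np.random.default_rng(seed))
            assert out.sum() == patch.sum()

    def test_identity_twice_as_likely_as_each_rotation(self):
        counts = {k: 0 for k in range(4)}
        patch = np.arange(16, dtype=float).reshape(4, 4, 1)
        rotations = [np.rot90(patch, k=k, axes=(0, 1)) for k in range(4)]
        rng = np.random.default_rng(5)
        n = 20_000
        for _ in range(n):
            out = augment(patch, rng)
            for k, ref in enumerate(rotations):
                if np.array_equal(out, ref):
                    counts[k] += 1
                    break
        assert counts[0] / n == pytest.approx(0.4, abs=0.02)
        for k in (1, 2, 3):
            assert counts[k] / n == pytest.approx(0.2, abs=0.02)


class TestTrainStep:
    @pytest.fixture(scope="class")
    def tiny_data(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, size=(1, 16, 16, 16)).astype(np.float32)
        y = (rng.random((1, 16, 16, 16)) > 0.9).astype(np.float32)
        return x, y

    def test_all_logged_losses_finite(self, tiny_data):
        trainer = Trainer(tiny_train_config())
        record = trainer.train_step(*tiny_data, epoch=0)
        for key in ("d_x", "d_y", "g_adv", "f_adv", "cycle_l1",
                    "cycle_bce", "rec", "topo", "total_G", "total_F"):
            assert np.isfinite(record[key])

    def test_zero_learning_rate_freezes_parameters(self, tiny_data):
        cfg = tiny_train_config(lr0=0.0)
        trainer = Trainer(cfg)
        before = {n: p.data.copy()
                  for n, p in trainer.G.named_parameters()}
        trainer.train_step(*tiny_data, epoch=0)
        after = dict(trainer.G.named_parameters())
        assert all(np.array_equal(before[n], after[n].data)
                   for n in before)

    def test_ablation_flags_change_only_their_own_loss_terms(self, tiny_data):
        full = Trainer(tiny_train_config()).train_step(*tiny_data, epoch=0)
        no_topo = Trainer(tiny_train_config(use_topo_loss=False)) \
            .train_step(*tiny_data, epoch=0)
        assert no_topo["topo"] == 0.0 and full["topo"] > 0.0
        for key in ("d_x", "d_y", "cycle_l1", "cycle_bce", "rec"):
            assert no_topo[key] == pytest.approx(full[key], rel=1e-5), key
        no_rec = Trainer(tiny_train_config(use_rec_loss=False)) \
            .train_step(*tiny_data, epoch=0)
        assert no_rec["rec"] == 0.0 and full["rec"] > 0.0
        for key in ("d_x", "d_y", "cycle_l1", "cycle_bce", "topo"):
            assert no_rec[key] == pytest.approx(full[key], rel=1e-5), key

    def test_two_runs_same_seed_are_bit_identical(self, tiny_data):
        recs = []
        for _ in range(2):
            trainer = Trainer(tiny_train_config())
            r1 = trainer.train_step(*tiny_data, epoch=0)
            r2 = trainer.train_step(*tiny_data, epoch=1)
            recs.append((r1, r2))
        for a, b in zip(*recs):
            assert a == b

    def test_checkpoint_round_trip_restores_networks(self, tiny_data,
                                                     tmp_path):
        trainer = Trainer(tiny_train_config())
        trainer.train_step(*tiny_data, epoch=0)
        path = tmp_path / "ckpt.npz"
        trainer.save_checkpoint(path)
        fresh = Trainer(tiny_train_config())
        assert fresh.G.checksum() != trainer.G.checksum()
        fresh.load_checkpoint(path)
        assert fresh.G.checksum() == trainer.G.checksum()
        assert fresh.opt_g.t == trainer.opt_g.t

    def test_full_loop_writes_logs_and_checkpoints(self, tmp_path, rng):
        cfg = tiny_train_config()
        trainer = Trainer(cfg)
        imaging = [rng.uniform(-1, 1, (16, 16, 16)).astype(np.float32)]
        seg = [(rng.random((16, 16, 16)) > 0.9).astype(np.uint8)]
        history = trainer.train(imaging, seg, out_dir=tmp_path)
        assert len(history) == cfg.epochs * cfg.steps_per_epoch
        assert (tmp_path / "losses.jsonl").exists()
        assert (tmp_path / "last.npz").exists()
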