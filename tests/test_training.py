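"""Training orchestration: schedule, determinism, checkpointing, resume."""

import json

import numpy as np
import pytest

from hazecycle.losses import DivergenceError
from hazecycle.synthetic_scenes import DatasetSpec, build_unpaired_dataset
from hazecycle.training import (CheckpointError, TrainConfig, dehaze_image,
                                init_state, load_checkpoint, lr_schedule,
                                save_checkpoint, train, train_step)


def tiny_cfg(**kw):
    defaults = dict(total_iterations=8, warm_iterations=4, lr0=5e-4,
                    image_size=32, width_multiplier=0.125,
                    n_residual_blocks=1, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("tiny_ds")
    spec = DatasetSpec(n_clear_train=6, n_hazy_train=6, n_clear_test=2,
                       n_hazy_test=2, root=str(root), seed=21,
                       size=(32, 32), n_leaves=5)
    build_unpaired_dataset(spec)
    return root


@pytest.fixture
def batch_pair():
    rng = np.random.default_rng(33)
    return rng.uniform(0, 1, (32, 32, 3)), rng.uniform(0, 1, (32, 32, 3))


class TestLrSchedule:
    def test_warm_phase_holds_base_rate(self):
        assert lr_schedule(2500, TrainConfig()) == pytest.approx(1e-4)

    def test_linear_decay_midpoint(self):
        assert lr_schedule(7500, TrainConfig()) == pytest.approx(5e-5)

    def test_reaches_exactly_zero(self):
        assert lr_schedule(10000, TrainConfig()) == 0.0

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(10001, TrainConfig())

    def test_warm_longer_than_total_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(total_iterations=10, warm_iterations=20)


class TestTrainStep:
    def test_all_loss_terms_finite_and_nonnegative(self, batch_pair):
        cfg = tiny_cfg()
        state = init_state(cfg)
        record = train_step(state, *batch_pair, cfg)
        assert state.iteration == 1
        for value in record.terms.values():
            assert np.isfinite(value) and value >= 0.0
        assert record.d_loss_clear >= 0.0 and record.d_loss_hazy >= 0.0

    def test_zero_lr_leaves_generators_bitwise_unchanged(self, batch_pair):
        cfg = tiny_cfg(total_iterations=8, warm_iterations=0)
        state = init_state(cfg)
        state.iteration = cfg.total_iterations  # lr_schedule -> exactly 0
        before = [p.data.copy() for g in state.generators()
                  for p in g.parameters()]
        record = train_step(state, *batch_pair, cfg)
        assert record.lr == 0.0
        after = [p.data for g in state.generators()
                 for p in g.parameters()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_identical_seeds_give_identical_trajectories(self, batch_pair):
        cfg = tiny_cfg(total_iterations=3, warm_iterations=3)
        records = []
        for _ in range(2):
            state = init_state(cfg)
            run = [train_step(state, *batch_pair, cfg).terms
                   for _ in range(3)]
            records.append(run)
        assert records[0] == records[1]

    def test_nan_weights_raise_divergence_error_with_iteration(self,
                                                               batch_pair):
        cfg = tiny_cfg()
        state = init_state(cfg)
        poisoned = state.G_dehaze_fwd.parameters()[0]
        poisoned.data[:] = np.nan
        with pytest.raises(DivergenceError, match="iteration 0"):
            train_step(state, *batch_pair, cfg)


class TestCheckpointing:
    def test_roundtrip_preserves_forward_outputs(self, tmp_path, batch_pair):
        cfg = tiny_cfg()
        state = init_state(cfg)
        train_step(state, *batch_pair, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state, cfg)
        loaded, cfg2, _ = load_checkpoint(path)
        assert loaded.iteration == state.iteration
        j1, t1 = dehaze_image((state, cfg), batch_pair[0])
        j2, t2 = dehaze_image((loaded, cfg2), batch_pair[0])
        np.testing.assert_array_equal(j1, j2)
        np.testing.assert_array_equal(t1, t2)

    def test_missing_checkpoint_rejected(self, tmp_path):
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "nope.npz")

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            TrainConfig.from_dict({"total_iterations": 5, "bogus": 1})


class TestTrainLoop:
    def test_smoke_run_writes_log_and_checkpoint(self, tiny_dataset,
                                                 tmp_path):
        cfg = tiny_cfg(total_iterations=10, warm_iterations=5, log_every=5)
        out = tmp_path / "run"
        ckpt = train(tiny_dataset, cfg, out)
        assert ckpt.exists()
        lines = (out / "train_log.jsonl").read_text().splitlines()
        assert len(lines) == 10 // 5
        record = json.loads(lines[-1])
        assert record["iteration"] == 10
        assert all(np.isfinite(record[k]) for k in
                   ("total", "adv_fwd", "cycle_fwd", "haze"))

    def test_full_run_seed_determinism(self, tiny_dataset, tmp_path):
        cfg = tiny_cfg(total_iterations=6, warm_iterations=3, log_every=2)
        logs = []
        for name in ("a", "b"):
            train(tiny_dataset, cfg, tmp_path / name)
            logs.append([
                {k: v for k, v in json.loads(line).items()
                 if k != "wall_time"}
                for line in
                (tmp_path / name / "train_log.jsonl").read_text().splitlines()])
        assert logs[0] == logs[1]

    def test_resume_matches_uninterrupted_run(self, tiny_dataset, tmp_path):
        cfg = tiny_cfg(total_iterations=6, warm_iterations=3, log_every=1)
        train(tiny_dataset, cfg, tmp_path / "full")
        ckpt = train(tiny_dataset, cfg, tmp_path / "part", stop_after=4)
        train(tiny_dataset, cfg, tmp_path / "part", resume_from=ckpt)

        def read(p):
            return [{k: v for k, v in json.loads(line).items()
                     if k != "wall_time"}
                    for line in (p / "train_log.jsonl").read_text().splitlines()]
        assert read(tmp_path / "full") == read(tmp_path / "part")

    def test_resume_with_other_config_rejected(self, tiny_dataset, tmp_path):
        cfg = tiny_cfg(total_iterations=6, warm_iterations=3)
        ckpt = train(tiny_dataset, cfg, tmp_path / "r", stop_after=2)
        other = tiny_cfg(total_iterations=8, warm_iterations=3)
        with pytest.raises(CheckpointError, match="config"):
            train(tiny_dataset, other, tmp_path / "r2", resume_from=ckpt)

    def test_empty_domain_rejected(self, tmp_path):
        (tmp_path / "ds" / "trainA").mkdir(parents=True)
        (tmp_path / "ds" / "trainB").mkdir()
        with pytest.raises(ValueError, match="no training images"):
            train(tmp_path / "ds", tiny_cfg(), tmp_path / "out")


@pytest.fixture(scope="module")
def trained():
    cfg = tiny_cfg(total_iterations=2, warm_iterations=1)
    state = init_state(cfg)
    rng = np.random.default_rng(1)
    for _ in range(2):
        train_step(state, rng.uniform(0, 1, (32, 32, 3)),
                   rng.uniform(0, 1, (32, 32, 3)), cfg)
    return state, cfg


class TestDehazeInference:
    def test_output_shapes(self, trained):
        img = np.random.default_rng(2).uniform(0, 1, (32, 32, 3))
        j, t = dehaze_image(trained, img)
        assert j.shape == (32, 32, 3)
        assert t.shape == (32, 32)

    def test_eval_mode_is_deterministic(self, trained):
        img = np.random.default_rng(3).uniform(0, 1, (32, 32, 3))
        j1, t1 = dehaze_image(trained, img)
        j2, t2 = dehaze_image(trained, img)
        np.testing.assert_array_equal(j1, j2)
        np.testing.assert_array_equal(t1, t2)


def test_training_reduces_generator_objective(recovery_runs):
    """3-seed median: the logged total generator loss ends lower than it
    starts on the scaled-down physics-fused runs."""
    _, logs = recovery_runs
    ratios = []
    for run in logs["physics"]:
        ratios.append(run[-1]["total"] / run[0]["total"])
    assert np.median(ratios) < 1.0
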