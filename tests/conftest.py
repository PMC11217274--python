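import json

import pytest

from hazecycle.synthetic_scenes import DatasetSpec, build_unpaired_dataset
from hazecycle.training import desk_config, evaluate_recovery, train

DESK_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """Small unpaired 64x64 benchmark: 24+24 train, 5 clear / 20 hazy test."""
    root = tmp_path_factory.mktemp("desk_dataset")
    spec = DatasetSpec(n_clear_train=24, n_hazy_train=24, n_clear_test=5,
                       n_hazy_test=20, root=str(root), seed=11,
                       size=(64, 64), n_leaves=8)
    manifest = build_unpaired_dataset(spec)
    return root, manifest


@pytest.fixture(scope="session")
def recovery_runs(desk_dataset, tmp_path_factory):
    """Scaled-down training runs: 3 seeds, physics-fused and ablation arms.

    This is the expensive fixture (a few minutes of CPU); it is computed
    once per session and shared by the end-to-end recovery, ablation and
    loss-trajectory tests.
    """
    root, manifest = desk_dataset
    out_base = tmp_path_factory.mktemp("desk_runs")
    results = {"physics": [], "ablation": []}
    logs = {"physics": [], "ablation": []}
    for arm, physics in (("physics", True), ("ablation", False)):
        for seed in DESK_SEEDS:
            cfg = desk_config(seed, use_physics=physics)
            out = out_base / f"{arm}_{seed}"
            ckpt = train(root, cfg, out)
            results[arm].append(evaluate_recovery(ckpt, root, manifest))
            logs[arm].append([
                json.loads(line) for line in
                (out / "train_log.jsonl").read_text().splitlines()])
    return results, logs
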