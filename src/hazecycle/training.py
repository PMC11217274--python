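"""Adversarial training orchestration for the two-cycle dehazing system.

The system holds four generators and four discriminators:

* ``G_dehaze_fwd`` : hazy x  -> (haze-free J, transmission t)   [physics]
* ``G_haze_bwd``   : J       -> reconstructed hazy (closes cycle A)
* ``G_haze_fwd``   : clear y -> fake hazy
* ``G_dehaze_bwd`` : fake hazy -> (clear reconstruction, t)     [physics]
* ``D_detail_clear`` / ``D_struct_clear`` : judge real vs generated clear
* ``D_detail_hazy``  / ``D_struct_hazy``  : judge real vs generated hazy

Each iteration performs one alternating update: first the generators
(adversarial terms from all four discriminators + both cycle losses + the
scattering-model haze-consistency terms), then the discriminators (real
images labelled 1, generated labelled 0).  All networks use Adam with
betas (0.5, 0.999); the learning rate is constant for the warm phase and
decays linearly to exactly zero at the final iteration.

Checkpoints are self-describing (config + parameters + optimizer moments +
sampler state), so a resumed run reproduces the uninterrupted one bit for
bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._imgio import list_images, load_image
from ._nn import Adam
from .haze_physics import estimate_atmospheric_light
from .losses import (DivergenceError, LossWeights, cycle_loss,
                     discriminator_loss, generator_adversarial_loss,
                     haze_consistency_loss, total_objective)
from .networks import (DiscriminatorConfig, GeneratorConfig,
                       build_dehaze_generator, build_detail_discriminator,
                       build_structure_discriminator,
                       build_translation_generator, image_to_tensor,
                       tensor_to_image)

__all__ = ["TrainConfig", "TrainLogRecord", "CycleState", "lr_schedule",
           "init_state", "train_step", "train", "save_checkpoint",
           "load_checkpoint", "dehaze_image", "desk_config",
           "evaluate_recovery", "CheckpointError"]

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    """Checkpoint missing, incompatible or from another version."""


@dataclass
class TrainConfig:
    total_iterations: int = 10000
    warm_iterations: int = 5000
    lr0: float = 1e-4
    batch_size: int = 1
    image_size: int = 256
    log_every: int = 10
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    adam_betas: tuple = (0.5, 0.999)
    base_channels: int = 64
    width_multiplier: float = 1.0
    n_residual_blocks: int = 5
    use_physics: bool = True  # False disables the t head + haze loss (ablation)

    def __post_init__(self):
        if self.warm_iterations > self.total_iterations:
            raise ValueError("warm_iterations must not exceed total_iterations")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "loss_weights" in d and isinstance(d["loss_weights"], dict):
            d["loss_weights"] = LossWeights(**d["loss_weights"])
        if "adam_betas" in d:
            d["adam_betas"] = tuple(d["adam_betas"])
        return cls(**d)


@dataclass
class TrainLogRecord:
    iteration: int
    lr: float
    terms: dict            # generator loss breakdown
    d_loss_clear: float
    d_loss_hazy: float
    wall_time: float

    def to_dict(self) -> dict:
        return {"iteration": self.iteration, "lr": self.lr,
                "d_loss_clear": self.d_loss_clear,
                "d_loss_hazy": self.d_loss_hazy,
                "wall_time": self.wall_time, **self.terms}


@dataclass
class CycleState:
    G_dehaze_fwd: object
    G_haze_fwd: object
    G_dehaze_bwd: object
    G_haze_bwd: object
    D_detail_hazy: object
    D_struct_hazy: object
    D_detail_clear: object
    D_struct_clear: object
    opt_G: Adam
    opt_D: Adam
    iteration: int = 0

    def generators(self):
        return [self.G_dehaze_fwd, self.G_haze_fwd,
                self.G_dehaze_bwd, self.G_haze_bwd]

    def discriminators(self):
        return [self.D_detail_hazy, self.D_struct_hazy,
                self.D_detail_clear, self.D_struct_clear]

    def networks(self) -> dict:
        return {"G_dehaze_fwd": self.G_dehaze_fwd,
                "G_haze_fwd": self.G_haze_fwd,
                "G_dehaze_bwd": self.G_dehaze_bwd,
                "G_haze_bwd": self.G_haze_bwd,
                "D_detail_hazy": self.D_detail_hazy,
                "D_struct_hazy": self.D_struct_hazy,
                "D_detail_clear": self.D_detail_clear,
                "D_struct_clear": self.D_struct_clear}


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Constant ``lr0`` for the warm phase, then linear decay to 0."""
    if iteration < 0 or iteration > cfg.total_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {cfg.total_iterations}]")
    if iteration < cfg.warm_iterations:
        return cfg.lr0
    span = cfg.total_iterations - cfg.warm_iterations
    if span == 0:
        return 0.0
    return cfg.lr0 * (cfg.total_iterations - iteration) / span


def init_state(cfg: TrainConfig) -> CycleState:
    """Build the four generators, four discriminators and their optimizers."""
    gcfg = GeneratorConfig(base_channels=cfg.base_channels,
                           width_multiplier=cfg.width_multiplier,
                           n_residual_blocks=cfg.n_residual_blocks,
                           emit_transmission=cfg.use_physics)
    tcfg = replace(gcfg, emit_transmission=False)
    dcfg_det = DiscriminatorConfig(kind="detail",
                                   width_multiplier=cfg.width_multiplier)
    dcfg_str = DiscriminatorConfig(kind="structure",
                                   width_multiplier=cfg.width_multiplier,
                                   input_size=cfg.image_size)
    s = cfg.seed
    build_g = (build_dehaze_generator if cfg.use_physics
               else build_translation_generator)
    state = CycleState(
        G_dehaze_fwd=build_g(gcfg, seed=s + 1),
        G_haze_fwd=build_translation_generator(tcfg, seed=s + 2),
        G_dehaze_bwd=build_g(gcfg, seed=s + 3),
        G_haze_bwd=build_translation_generator(tcfg, seed=s + 4),
        D_detail_hazy=build_detail_discriminator(dcfg_det, seed=s + 5),
        D_struct_hazy=build_structure_discriminator(dcfg_str, seed=s + 6),
        D_detail_clear=build_detail_discriminator(dcfg_det, seed=s + 7),
        D_struct_clear=build_structure_discriminator(dcfg_str, seed=s + 8),
        opt_G=None, opt_D=None)
    gen_params = [p for g in state.generators() for p in g.parameters()]
    dis_params = [p for d in state.discriminators() for p in d.parameters()]
    state.opt_G = Adam(gen_params, betas=cfg.adam_betas)
    state.opt_D = Adam(dis_params, betas=cfg.adam_betas)
    return state


def _dehaze_forward(gen, x: Tensor, use_physics: bool):
    """Run a dehazing-direction generator; returns (J, t-or-None)."""
    if use_physics:
        return gen(x)
    return gen(x), None


def _check_finite(name: str, value: float, iteration: int) -> float:
    if not np.isfinite(value):
        raise DivergenceError(
            f"loss term {name!r} diverged (value {value}) at iteration "
            f"{iteration}")
    return value


def train_step(state: CycleState, hazy_batch: np.ndarray,
               clear_batch: np.ndarray, cfg: TrainConfig) -> TrainLogRecord:
    """One alternating generator/discriminator update on a (hazy, clear) pair.

    Mutates ``state`` in place and returns the loss record.
    """
    t0 = time.perf_counter()
    w = cfg.loss_weights
    lr = lr_schedule(state.iteration, cfg)
    x = image_to_tensor(hazy_batch)
    y = image_to_tensor(clear_batch)

    # ---- generator update ------------------------------------------------
    a_x = estimate_atmospheric_light(hazy_batch)
    j_fake, t_fake = _dehaze_forward(state.G_dehaze_fwd, x, cfg.use_physics)
    x_rec = state.G_haze_bwd(j_fake)                 # cycle A: x -> J -> x
    y_fake = state.G_haze_fwd(y)                     # fake hazy
    a_yf = estimate_atmospheric_light(tensor_to_image(y_fake))
    y_rec, t_rec = _dehaze_forward(state.G_dehaze_bwd, y_fake,
                                   cfg.use_physics)  # cycle B: y -> fake -> y

    sat = w.saturating
    adv_clear = 0.5 * (
        generator_adversarial_loss(state.D_detail_clear(j_fake), sat)
        + generator_adversarial_loss(state.D_struct_clear(j_fake), sat))
    adv_hazy = 0.5 * (
        generator_adversarial_loss(state.D_detail_hazy(y_fake), sat)
        + generator_adversarial_loss(state.D_struct_hazy(y_fake), sat))
    cyc_a = cycle_loss(x, x_rec)
    cyc_b = cycle_loss(y, y_rec)
    if cfg.use_physics:
        haze = 0.5 * (haze_consistency_loss(x, j_fake, t_fake, a_x)
                      + haze_consistency_loss(y_fake, y_rec, t_rec, a_yf))
    else:
        haze = Tensor(0.0)
    try:
        total_g, terms = total_objective(
            {"adv_fwd": adv_clear, "adv_bwd": adv_hazy,
             "cycle_fwd": cyc_a, "cycle_bwd": cyc_b, "haze": haze}, w)
    except DivergenceError as exc:
        raise DivergenceError(f"{exc} at iteration {state.iteration}") from exc
    for name, value in terms.items():
        _check_finite(name, value, state.iteration)
    for g in state.generators():
        g.zero_grad()
    for d in state.discriminators():
        d.zero_grad()
    total_g.backward()
    state.opt_G.step(lr)

    # ---- discriminator update -------------------------------------------
    jf, yf = j_fake.detach(), y_fake.detach()
    d_clear = 0.5 * (
        discriminator_loss(state.D_detail_clear(y), state.D_detail_clear(jf))
        + discriminator_loss(state.D_struct_clear(y),
                             state.D_struct_clear(jf)))
    d_hazy = 0.5 * (
        discriminator_loss(state.D_detail_hazy(x), state.D_detail_hazy(yf))
        + discriminator_loss(state.D_struct_hazy(x),
                             state.D_struct_hazy(yf)))
    d_total = d_clear + d_hazy
    _check_finite("d_loss", float(d_total.data), state.iteration)
    for d in state.discriminators():
        d.zero_grad()
    d_total.backward()
    state.opt_D.step(lr)

    state.iteration += 1
    return TrainLogRecord(iteration=state.iteration, lr=lr, terms=terms,
                          d_loss_clear=float(d_clear.data),
                          d_loss_hazy=float(d_hazy.data),
                          wall_time=time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: CycleState, cfg: TrainConfig,
                    rng: np.random.Generator | None = None) -> None:
    arrays = {}
    for net_name, net in state.networks().items():
        for k, v in net.state_dict().items():
            arrays[f"{net_name}/{k}"] = v
    for opt_name, opt in (("opt_G", state.opt_G), ("opt_D", state.opt_D)):
        sd = opt.state_dict()
        for i, (m, v) in enumerate(zip(sd["m"], sd["v"])):
            arrays[f"{opt_name}/m/{i}"] = m
            arrays[f"{opt_name}/v/{i}"] = v
        arrays[f"{opt_name}/t"] = np.array(sd["t"])
    meta = {"version": CHECKPOINT_VERSION, "iteration": state.iteration,
            "config": cfg.to_dict(),
            "rng_state": rng.bit_generator.state if rng is not None else None}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8).copy()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def _read_meta(npz) -> dict:
    return json.loads(bytes(npz["meta"]).decode())


def load_checkpoint(path):
    """Rebuild (state, cfg, rng_state) from a checkpoint file."""
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint {path} does not exist")
    with np.load(path) as npz:
        try:
            meta = _read_meta(npz)
        except Exception as exc:
            raise CheckpointError(f"unreadable checkpoint {path}: {exc}")
        if meta.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"checkpoint version {meta.get('version')} != "
                f"{CHECKPOINT_VERSION}")
        cfg = TrainConfig.from_dict(meta["config"])
        state = init_state(cfg)
        try:
            for net_name, net in state.networks().items():
                net.load_state_dict(
                    {k.split("/", 1)[1]: npz[k] for k in npz.files
                     if k.startswith(net_name + "/")})
            for opt_name, opt in (("opt_G", state.opt_G),
                                  ("opt_D", state.opt_D)):
                n = len(opt.params)
                opt.load_state_dict(
                    {"t": int(npz[f"{opt_name}/t"]),
                     "m": [npz[f"{opt_name}/m/{i}"] for i in range(n)],
                     "v": [npz[f"{opt_name}/v/{i}"] for i in range(n)]})
        except KeyError as exc:
            raise CheckpointError(
                f"checkpoint {path} incompatible with its config: missing "
                f"{exc}")
    state.iteration = int(meta["iteration"])
    return state, cfg, meta.get("rng_state")


# ---------------------------------------------------------------------------
# Full training loop
# ---------------------------------------------------------------------------

def _load_domain(directory, size: int) -> list:
    files = list_images(directory)
    if not files:
        raise ValueError(f"no training images in {directory}")
    images = []
    for p in files:
        img = load_image(p)
        if img.shape[0] != size or img.shape[1] != size:
            ri = (np.arange(size) * img.shape[0] / size).astype(int)
            ci = (np.arange(size) * img.shape[1] / size).astype(int)
            img = img[ri][:, ci]
        images.append(img)
    return images


def train(dataset_root, cfg: TrainConfig, out_dir,
          resume_from=None, stop_after: int | None = None) -> Path:
    """Train on ``<root>/trainA`` (hazy) and ``<root>/trainB`` (clear).

    Draws one image independently from each domain per iteration (unpaired
    sampling), logs every ``cfg.log_every`` iterations to
    ``<out_dir>/train_log.jsonl`` and writes the final self-describing
    checkpoint to ``<out_dir>/checkpoint.npz`` (returned).

    ``stop_after`` interrupts the run at that iteration (checkpoint still
    written); pass the checkpoint as ``resume_from`` with the *same* config
    to continue — the resumed trajectory is identical to an uninterrupted
    one.
    """
    root = Path(dataset_root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hazy_images = _load_domain(root / "trainA", cfg.image_size)
    clear_images = _load_domain(root / "trainB", cfg.image_size)

    if resume_from is not None:
        state, cfg_loaded, rng_state = load_checkpoint(resume_from)
        if cfg_loaded.to_dict() != cfg.to_dict():
            raise CheckpointError(
                "resume config differs from the checkpointed config")
        rng = np.random.default_rng(cfg.seed)
        if rng_state is not None:
            rng.bit_generator.state = rng_state
    else:
        state = init_state(cfg)
        rng = np.random.default_rng(cfg.seed)

    stop_at = cfg.total_iterations if stop_after is None \
        else min(stop_after, cfg.total_iterations)
    log_path = out_dir / "train_log.jsonl"
    mode = "a" if resume_from is not None else "w"
    with open(log_path, mode) as log_file:
        while state.iteration < stop_at:
            i = int(rng.integers(len(hazy_images)))
            j = int(rng.integers(len(clear_images)))
            record = train_step(state, hazy_images[i], clear_images[j], cfg)
            if record.iteration % cfg.log_every == 0:
                log_file.write(json.dumps(record.to_dict()) + "\n")
                log_file.flush()

    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt_path, state, cfg, rng)
    return ckpt_path


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def dehaze_image(checkpoint, img: np.ndarray):
    """Dehaze one HxWx3 image with a trained model.

    ``checkpoint`` is a path or an already-loaded ``(state, cfg)`` pair.
    Returns ``(J, t)`` with ``t`` None when the model was trained without
    the physics branch.  Norm layers run in eval mode, so the output is a
    pure function of the weights and the input.
    """
    if isinstance(checkpoint, tuple):
        state, cfg = checkpoint
    else:
        state, cfg, _ = load_checkpoint(checkpoint)
    gen = state.G_dehaze_fwd
    gen.eval()
    try:
        out = _dehaze_forward(gen, image_to_tensor(img), cfg.use_physics)
    finally:
        gen.train()
    j, t = out
    return tensor_to_image(j), None if t is None else tensor_to_image(t)


# ---------------------------------------------------------------------------
# Scaled-down study protocol
# ---------------------------------------------------------------------------

def desk_config(seed: int, use_physics: bool = True,
                total_iterations: int = 200) -> TrainConfig:
    """The package's scaled-down training protocol.

    64x64 images, width multiplier 0.125, 3 residual blocks, batch 1, Adam
    at lr 5e-4 held for the first half of the run then decayed linearly to
    zero.  The learning rate is raised relative to the full-scale 1e-4
    because the narrow model and short schedule need proportionally larger
    steps.  With ``use_physics=False`` the transmission head and the haze
    weight are dropped (the ablation arm).
    """
    lw = LossWeights() if use_physics else LossWeights(w_haze=0.0)
    return TrainConfig(total_iterations=total_iterations,
                       warm_iterations=total_iterations // 2,
                       lr0=5e-4, image_size=64, width_multiplier=0.125,
                       n_residual_blocks=3, seed=seed,
                       use_physics=use_physics, loss_weights=lw)


def evaluate_recovery(checkpoint, dataset_root, manifest: dict | None = None
                      ) -> dict:
    """Score a trained model on the hazy test split of a synthetic dataset.

    For every ``testA`` image the paired clear ground truth is regenerated
    from its manifest scene seed (it was withheld from training) and the
    dehazed output is compared with the hazy input on two per-image checks:
    is EGF strictly higher, and is the L1 distance to the ground truth
    strictly lower.  Returns the fractions plus the underlying means.
    """
    from .metrics import egf
    from .synthetic_scenes import paired_clear_ground_truth

    root = Path(dataset_root)
    if manifest is None:
        manifest = json.loads((root / "manifest.json").read_text())
    if isinstance(checkpoint, tuple):
        state, cfg = checkpoint
    else:
        state, cfg, _ = load_checkpoint(checkpoint)
    egf_hazy, egf_dehazed, l1_hazy, l1_dehazed = [], [], [], []
    for entry in manifest["directories"]["testA"]:
        hazy = load_image(root / "testA" / entry["file"])
        gt = paired_clear_ground_truth(manifest, "testA", entry)
        j, _ = dehaze_image((state, cfg), hazy)
        egf_hazy.append(egf(hazy))
        egf_dehazed.append(egf(j))
        l1_hazy.append(float(np.abs(hazy - gt).mean()))
        l1_dehazed.append(float(np.abs(j - gt).mean()))
    egf_hazy, egf_dehazed = np.array(egf_hazy), np.array(egf_dehazed)
    l1_hazy, l1_dehazed = np.array(l1_hazy), np.array(l1_dehazed)
    return {
        "n_test": len(egf_hazy),
        "egf_improved_fraction": float(np.mean(egf_dehazed > egf_hazy)),
        "l1_improved_fraction": float(np.mean(l1_dehazed < l1_hazy)),
        "mean_egf_hazy": float(egf_hazy.mean()),
        "mean_egf_dehazed": float(egf_dehazed.mean()),
        "mean_l1_hazy": float(l1_hazy.mean()),
        "mean_l1_dehazed": float(l1_dehazed.mean()),
    }
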