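"""Procedural plant-scene benchmark: clear foliage images and their hazy
counterparts under the atmospheric scattering model.

Real agricultural haze pairs cannot be collected on demand (a field cannot
be photographed hazy and clear at the same instant), which is exactly why
the dehazing network trains unpaired.  This module builds a self-contained
stand-in: textured scenes of overlapping elliptical leaves with vein lines
and sharp edges, hazified by ``I = J t + A (1 - t)`` with per-image
atmospheric light and a smooth pseudo-depth transmission field
``t = exp(-beta * depth)``.

Unpairedness is enforced structurally: the clear-domain and hazy-domain
scene seeds are disjoint, so no training image in one domain has its
counterpart in the other.  The manifest records every scene seed and the
haze parameters of every hazy file, which lets evaluation code regenerate
the *withheld* paired ground truth for hazy test images; training code must
never read it.

Default dataset sizes follow the field study the benchmark emulates:
407 clear / 479 hazy training images and 51 clear / 49 hazy test images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ._imgio import save_image
from .haze_physics import T_MIN, apply_scattering

__all__ = ["SceneParams", "HazeParams", "DatasetSpec", "generate_clear_image",
           "pseudo_depth", "generate_transmission", "hazify",
           "build_unpaired_dataset", "paired_clear_ground_truth"]


@dataclass
class SceneParams:
    """Controls one procedurally generated clear foliage scene."""
    seed: int
    size: tuple = (256, 256)
    n_leaves: int = 12
    vein_contrast: float = 0.35
    background_level: float = 0.30


@dataclass
class HazeParams:
    """Scattering-model parameters for one hazy image.

    ``beta`` is the extinction coefficient of ``t = exp(-beta * depth)``;
    ``depth_smoothness`` is the Gaussian smoothing scale of the pseudo-depth
    field as a fraction of the image side.
    """
    A: float = 0.9
    beta: float = 1.5
    depth_smoothness: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.A <= 1.0):
            raise ValueError(f"atmospheric light {self.A} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"extinction coefficient {self.beta} < 0")
        if self.depth_smoothness <= 0:
            raise ValueError("depth_smoothness must be positive")


#: Per-image haze parameter ranges used when sampling a dataset.
A_RANGE = (0.7, 1.0)
BETA_RANGE = (0.6, 2.5)


@dataclass
class DatasetSpec:
    """Layout and size of an unpaired benchmark dataset."""
    n_clear_train: int = 407
    n_hazy_train: int = 479
    n_clear_test: int = 51
    n_hazy_test: int = 49
    root: str = "dataset"
    seed: int = 0
    size: tuple = (256, 256)
    n_leaves: int = 12


# ---------------------------------------------------------------------------
# Clear scenes
# ---------------------------------------------------------------------------

def generate_clear_image(p: SceneParams) -> np.ndarray:
    """Render a deterministic clear plant scene (HxWx3 floats in [0, 1]).

    Overlapping ellipses with per-leaf green hues, centre-to-edge shading,
    a dark mid-rib plus lateral vein lines, over a smoothly varying soil
    background.  Same seed, same bits.
    """
    h, w = p.size
    if h < 8 or w < 8:
        raise ValueError(f"scene must be at least 8x8, got {h}x{w}")
    if p.n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(p.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # soil-toned background: level + gentle gradient + low-frequency noise
    grad = 0.08 * (yy / h - 0.5) + 0.05 * (xx / w - 0.5)
    noise = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 10)
    noise = 0.06 * noise / (np.abs(noise).max() + 1e-12)
    base = np.clip(p.background_level + grad + noise, 0.02, 0.95)
    img = np.stack([base * 0.85, base * 0.70, base * 0.55], axis=-1)

    scale = min(h, w)
    for _ in range(p.n_leaves):
        cx = rng.uniform(0.05, 0.95) * w
        cy = rng.uniform(0.05, 0.95) * h
        a = rng.uniform(0.14, 0.30) * scale          # semi-major axis
        b = a * rng.uniform(0.45, 0.75)              # semi-minor axis
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / a
        v = (-(xx - cx) * st + (yy - cy) * ct) / b
        r2 = u * u + v * v
        mask = r2 <= 1.0

        color = np.array([rng.uniform(0.05, 0.22),
                          rng.uniform(0.35, 0.65),
                          rng.uniform(0.05, 0.20)])
        shading = 1.0 - 0.35 * r2                    # brighter centre
        leaf = shading[..., None] * color

        # mid-rib along the major axis and oblique lateral veins
        rib = np.abs(v) < 0.045
        lateral = (np.abs(((u * 4.0 + np.abs(v)) % 1.0) - 0.5) < 0.055) \
            & (np.abs(v) < 0.85)
        veins = (rib | lateral) & mask
        leaf = np.where(veins[..., None],
                        leaf * (1.0 - p.vein_contrast), leaf)
        img = np.where(mask[..., None], leaf, img)

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Transmission fields and hazification
# ---------------------------------------------------------------------------

def pseudo_depth(size: tuple, smoothness: float, seed: int) -> np.ndarray:
    """Seed-deterministic smooth depth field rescaled to [0, 1].

    Gaussian-smoothed white noise; ``smoothness`` is the filter sigma as a
    fraction of the shorter image side.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    depth = gaussian_filter(rng.standard_normal((h, w)),
                            sigma=smoothness * min(h, w))
    dmin, dmax = depth.min(), depth.max()
    if dmax <= dmin:
        return np.zeros((h, w))
    return (depth - dmin) / (dmax - dmin)


def generate_transmission(hp: HazeParams, size: tuple, seed: int
                          ) -> np.ndarray:
    """Smooth seed-deterministic transmission ``t = exp(-beta * depth)``,
    clamped to ``[T_MIN, 1]``."""
    if hp.beta < 0:
        raise ValueError("extinction coefficient must be nonnegative")
    depth = pseudo_depth(size, hp.depth_smoothness, seed)
    return np.clip(np.exp(-hp.beta * depth), T_MIN, 1.0)


def hazify(clear: np.ndarray, hp: HazeParams, seed: int) -> tuple:
    """Hazify a clear image; returns ``(hazy, t)``.

    The returned transmission is ground truth for validation only — the
    unpaired training pipeline never sees it.
    """
    t = generate_transmission(hp, clear.shape[:2], seed)
    return apply_scattering(clear, t, hp.A), t


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _scene_seed(base: int, index: int, hazy: bool) -> int:
    # even seeds -> clear domain, odd -> hazy domain: disjoint by parity
    return (base * 1_000_003 + 2 * index + (1 if hazy else 0)) % (2 ** 31)


def _render(spec: DatasetSpec, seed: int) -> np.ndarray:
    return generate_clear_image(SceneParams(seed=seed, size=spec.size,
                                            n_leaves=spec.n_leaves))


def build_unpaired_dataset(spec: DatasetSpec) -> dict:
    """Write trainA (hazy) / trainB (clear) / testA (hazy) / testB (clear).

    Returns the manifest: per-file scene seed and, for hazy files, the
    sampled haze parameters and transmission seed.  The manifest is also
    written to ``<root>/manifest.json``.
    """
    for name, n in (("n_clear_train", spec.n_clear_train),
                    ("n_hazy_train", spec.n_hazy_train),
                    ("n_clear_test", spec.n_clear_test),
                    ("n_hazy_test", spec.n_hazy_test)):
        if n <= 0:
            raise ValueError(f"{name} must be positive, got {n}")
    root = Path(spec.root)
    root.mkdir(parents=True, exist_ok=True)
    haze_rng = np.random.default_rng(spec.seed + 77)
    manifest: dict = {"seed": spec.seed, "size": list(spec.size),
                      "directories": {}}

    layout = [("trainB", spec.n_clear_train, False, 0),
              ("trainA", spec.n_hazy_train, True, 0),
              ("testB", spec.n_clear_test, False, spec.n_clear_train),
              ("testA", spec.n_hazy_test, True, spec.n_hazy_train)]
    for dirname, count, hazy, offset in layout:
        d = root / dirname
        d.mkdir(exist_ok=True)
        entries = []
        for i in range(count):
            seed = _scene_seed(spec.seed, offset + i, hazy)
            clear = _render(spec, seed)
            fname = f"{dirname}_{i:04d}.png"
            entry = {"file": fname, "scene_seed": seed}
            if hazy:
                hp = HazeParams(A=haze_rng.uniform(*A_RANGE),
                                beta=haze_rng.uniform(*BETA_RANGE))
                t_seed = int(seed + 10_007)
                img, _ = hazify(clear, hp, t_seed)
                entry["haze"] = {"A": hp.A, "beta": hp.beta,
                                 "depth_smoothness": hp.depth_smoothness,
                                 "t_seed": t_seed}
            else:
                img = clear
            save_image(d / fname, img)
            entries.append(entry)
        manifest["directories"][dirname] = entries

    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def paired_clear_ground_truth(manifest: dict, dirname: str, entry: dict,
                              ) -> np.ndarray:
    """Regenerate the clear source of a hazy manifest entry (evaluation only)."""
    size = tuple(manifest["size"])
    spec = DatasetSpec(size=size)
    return generate_clear_image(SceneParams(seed=entry["scene_seed"],
                                            size=size,
                                            n_leaves=spec.n_leaves))
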