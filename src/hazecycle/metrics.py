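"""Evaluation indices: EGF sharpness and Fréchet distance between feature
distributions (FID).

EGF (energy gradient function) is a no-reference sharpness score: the image
is converted to 8-bit-scale BT.601 grayscale f(x, y) in [0, 255] and

    EGF = sum_{x,y} ( |f(x+1,y) - f(x,y)|^2 + |f(x,y+1) - f(x,y)|^2 ) / (H*W),

with forward differences that would leave the image omitted.  Higher is
sharper; haze, which is multiplicative contrast loss, lowers it.

FID fits a Gaussian to feature embeddings of each image set and reports the
squared Wasserstein-2 distance

    FID = ||mu_x - mu_z||^2 + Tr(S_x + S_z - 2 (S_x S_z)^{1/2}).

The canonical extractor is an Inception network; this package's default is
a fixed-seed random-weight convnet ("random64") so that evaluation is fully
deterministic and self-contained.  FID values are only comparable between
runs that used the same extractor, which the report records.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import _im2col
from ._imgio import list_images, load_image
from .haze_physics import to_grayscale

logger = logging.getLogger(__name__)

__all__ = ["egf", "extract_features", "fid", "evaluate_directory",
           "MetricReport", "FEATURE_DIM"]

FEATURE_DIM = 64
_EXTRACTOR_INPUT = 64  # images are resampled to this size before embedding


# ---------------------------------------------------------------------------
# EGF sharpness
# ---------------------------------------------------------------------------

def egf(img: np.ndarray) -> float:
    """Energy-gradient sharpness of an HxWx3 (or HxW grayscale) image."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        gray = to_grayscale(img) * 255.0
    elif img.ndim == 2:
        gray = img * 255.0
    else:
        raise ValueError(f"expected HxW or HxWx3 image, got shape {img.shape}")
    h, w = gray.shape
    if h < 2 or w < 2:
        raise ValueError("EGF needs at least a 2x2 image")
    dx = np.diff(gray, axis=1)  # f(x+1, y) - f(x, y)
    dy = np.diff(gray, axis=0)  # f(x, y+1) - f(x, y)
    return float((np.sum(dx ** 2) + np.sum(dy ** 2)) / (h * w))


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _resample(img: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resample of an HxWx3 array to size x size."""
    h, w = img.shape[:2]
    ri = (np.arange(size) * h / size).astype(int)
    ci = (np.arange(size) * w / size).astype(int)
    return img[ri][:, ci]


class _RandomConvNet:
    """Deterministic random-weight embedding network.

    Three stride-2 3x3 convolutions (16, 32, 64 channels) with leaky-ReLU,
    then global average pooling: a 64-d descriptor sensitive to colour,
    contrast and texture statistics.  Weights come from a fixed seed, so the
    embedding is a pure function of the pixels.
    """

    def __init__(self, seed: int = 20240701):
        rng = np.random.default_rng(seed)
        chans = [3, 16, 32, FEATURE_DIM]
        self.weights = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            w = rng.normal(0.0, 1.0, (cout, cin, 3, 3)).astype(np.float32)
            w /= np.sqrt(cin * 9)
            self.weights.append(w)

    def __call__(self, img: np.ndarray) -> np.ndarray:
        x = _resample(np.asarray(img, dtype=np.float32), _EXTRACTOR_INPUT)
        x = (x - 0.5)[None].transpose(0, 3, 1, 2)  # 1x3xHxW
        for w in self.weights:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            cols, ho, wo = _im2col(xp, 3, 3, stride=2)
            x = (cols @ w.reshape(w.shape[0], -1).T)
            x = x.reshape(1, ho, wo, w.shape[0]).transpose(0, 3, 1, 2)
            x = np.where(x > 0, x, 0.2 * x)
        return x.mean(axis=(0, 2, 3)).astype(np.float64)


_EXTRACTORS: dict = {}


def _get_extractor(name: str):
    if name != "random64":
        raise ValueError(f"unknown extractor {name!r}; available: 'random64'")
    if name not in _EXTRACTORS:
        _EXTRACTORS[name] = _RandomConvNet()
    return _EXTRACTORS[name]


def extract_features(images, extractor: str = "random64") -> np.ndarray:
    """Embed a list of HxWx3 images into an n x 64 feature matrix."""
    images = list(images)
    if not images:
        raise ValueError("no images to extract features from")
    net = _get_extractor(extractor)
    return np.stack([net(img) for img in images])


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

def fid(x: np.ndarray, z: np.ndarray) -> float:
    """Fréchet distance between Gaussians fitted to two feature matrices.

    Sample means and unbiased covariances; the matrix square root of
    ``S_x @ S_z`` comes from an eigendecomposition of the product with
    negative eigenvalues clamped at zero and any imaginary residue
    discarded.  The result is floored at zero.
    """
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if x.ndim != 2 or z.ndim != 2 or x.shape[1] != z.shape[1]:
        raise ValueError(f"feature dims differ: {x.shape} vs {z.shape}")
    if x.shape[0] < 2 or z.shape[0] < 2:
        raise ValueError("need at least 2 samples per side for a covariance")
    mu_x, mu_z = x.mean(axis=0), z.mean(axis=0)
    sx = np.atleast_2d(np.cov(x, rowvar=False))
    sz = np.atleast_2d(np.cov(z, rowvar=False))
    prod = sx @ sz
    evals, evecs = np.linalg.eig(prod)
    evals = np.where(evals.real > 0, evals, 0)
    sqrt_prod = (evecs @ np.diag(np.sqrt(evals)) @ np.linalg.inv(evecs)).real
    value = (np.sum((mu_x - mu_z) ** 2)
             + np.trace(sx + sz - 2.0 * sqrt_prod))
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# Directory-level report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    per_image_egf: dict = field(default_factory=dict)
    mean_egf: float = 0.0
    fid: float = 0.0
    n_images: int = 0
    n_reference: int = 0
    extractor: str = "random64"

    def to_dict(self) -> dict:
        return {"mean_egf": self.mean_egf, "fid": self.fid,
                "n_images": self.n_images, "n_reference": self.n_reference,
                "extractor": self.extractor,
                "per_image_egf": self.per_image_egf}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _load_directory(directory) -> tuple:
    names, imgs = [], []
    for p in list_images(directory):
        try:
            imgs.append(load_image(p))
            names.append(p.name)
        except Exception as exc:  # corrupt file: skip, keep evaluating
            logger.warning("skipping unreadable image %s: %s", p, exc)
            warnings.warn(f"skipping unreadable image {p}: {exc}")
    if not imgs:
        raise ValueError(f"no readable images in {directory}")
    return names, imgs


def evaluate_directory(dehazed_dir, reference_clear_dir,
                       extractor: str = "random64") -> MetricReport:
    """Mean EGF of the dehazed directory and FID against a clear reference."""
    names, dehazed = _load_directory(dehazed_dir)
    _, reference = _load_directory(reference_clear_dir)
    per_image = {n: egf(im) for n, im in zip(names, dehazed)}
    feats_d = extract_features(dehazed, extractor)
    feats_r = extract_features(reference, extractor)
    return MetricReport(
        per_image_egf=per_image,
        mean_egf=float(np.mean(list(per_image.values()))),
        fid=fid(feats_d, feats_r),
        n_images=len(dehazed),
        n_reference=len(reference),
        extractor=extractor,
    )
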