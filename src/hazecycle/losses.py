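"""Training objectives.

The total objective couples three ingredients:

* **Adversarial loss** (binary cross-entropy GAN loss) in both domains,
  with each domain judged by *two* discriminators (detail + structure)
  whose losses are averaged with equal weight.  The generator view is the
  non-saturating form ``-E[log D(G(x))]`` by default; the saturating
  ``+E[log(1 - D(G(x)))]`` form is available behind a flag.
* **Cycle-consistency loss** — mean L1 between an image and its
  round-trip translation, weighted by ``lambda_cycle``.
* **Scattering-model (haze-consistency) loss** — the dehazing generator's
  haze-free and transmission outputs are recomposed through
  ``I = J t + A (1 - t)`` and penalised by mean L1 against the actual hazy
  input, weighted by ``w_haze``.  This is what ties the learned mapping to
  the physics.

All functions accept either plain numpy arrays or autodiff tensors.  With
tensor inputs they build the (float32) training graph and return a scalar
:class:`~hazecycle._autodiff.Tensor`; with plain arrays they evaluate in
double precision and return a float.  ``float()`` works on both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = ["LossWeights", "discriminator_loss", "generator_adversarial_loss",
           "cycle_loss", "haze_consistency_loss", "total_objective",
           "DivergenceError"]

#: Scores are clamped into [SCORE_EPS, 1 - SCORE_EPS] before any log.
SCORE_EPS = 1e-7


class DivergenceError(RuntimeError):
    """Raised when a loss term turns non-finite during training."""


@dataclass
class LossWeights:
    lambda_cycle: float = 10.0
    w_haze: float = 10.0
    saturating: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.lambda_cycle) and self.lambda_cycle >= 0):
            raise ValueError("lambda_cycle must be finite and nonnegative")
        if not (np.isfinite(self.w_haze) and self.w_haze >= 0):
            raise ValueError("w_haze must be finite and nonnegative")


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _check_scores(s: Tensor, name: str) -> Tensor:
    if np.any(s.data < 0) or np.any(s.data > 1):
        raise ValueError(f"{name} scores must lie in [0, 1]")
    return s.clip(SCORE_EPS, 1.0 - SCORE_EPS)


def _check_scores_np(s, name: str) -> np.ndarray:
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError(f"{name} scores must lie in [0, 1]")
    return np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)


def discriminator_loss(d_real, d_fake):
    """``-E[log D(real)] - E[log(1 - D(fake))]`` over all score-map cells.

    Zero for a perfect discriminator; ``2 ln 2`` for the uninformative
    all-0.5 critic.  Minimised by the discriminator.
    """
    if _any_tensor(d_real, d_fake):
        d_real = _check_scores(d_real, "real")
        d_fake = _check_scores(d_fake, "fake")
        return -(d_real.log().mean()) - ((1.0 - d_fake).log().mean())
    r = _check_scores_np(d_real, "real")
    f = _check_scores_np(d_fake, "fake")
    return float(-np.mean(np.log(r)) - np.mean(np.log(1.0 - f)))


def generator_adversarial_loss(d_fake, saturating: bool = False):
    """Generator's view of the adversarial game.

    Non-saturating by default: ``-E[log D(fake)]``, which keeps gradients
    alive when the discriminator wins early.  With ``saturating=True``
    returns ``E[log(1 - D(fake))]`` (the literal minimax term).
    """
    if _any_tensor(d_fake):
        d_fake = _check_scores(d_fake, "fake")
        if saturating:
            return (1.0 - d_fake).log().mean()
        return -(d_fake.log().mean())
    f = _check_scores_np(d_fake, "fake")
    if saturating:
        return float(np.mean(np.log(1.0 - f)))
    return float(-np.mean(np.log(f)))


def cycle_loss(x, x_rec):
    """Mean absolute error between an image and its cycle reconstruction."""
    if _any_tensor(x, x_rec):
        if x.shape != x_rec.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
        return (x_rec - x).abs().mean()
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    return float(np.mean(np.abs(x_rec - x)))


def haze_consistency_loss(hazy, j_hat, t_hat, airlight: float):
    """Mean L1 between the recomposed haze ``J t + A(1-t)`` and the input.

    ``airlight`` is a constant (estimated from the hazy input, no
    gradient).  Since J, t and A all lie in [0, 1], the recomposition is a
    convex combination and needs no clipping.  With array inputs the
    transmission may be HxW (broadcast over the colour channels).
    """
    a = float(airlight)
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"atmospheric light {a} outside [0, 1]")
    if _any_tensor(hazy, j_hat, t_hat):
        recomposed = j_hat * t_hat + a * (1.0 - t_hat)
        if recomposed.shape != hazy.shape:
            raise ValueError(f"shape mismatch: recomposed "
                             f"{recomposed.shape} vs hazy {hazy.shape}")
        return (recomposed - hazy).abs().mean()
    hazy = np.asarray(hazy, dtype=np.float64)
    j_hat = np.asarray(j_hat, dtype=np.float64)
    t_hat = np.asarray(t_hat, dtype=np.float64)
    if t_hat.ndim == 2:
        t_hat = t_hat[..., None]
    recomposed = j_hat * t_hat + a * (1.0 - t_hat)
    if recomposed.shape != hazy.shape:
        raise ValueError(f"shape mismatch: recomposed {recomposed.shape} "
                         f"vs hazy {hazy.shape}")
    return float(np.mean(np.abs(recomposed - hazy)))


def total_objective(parts: dict, w: LossWeights):
    """Combine loss terms; returns ``(total, breakdown)``.

    ``parts`` maps term names to scalars/tensors: ``adv_fwd`` and
    ``adv_bwd`` (the two domains' generator adversarial terms),
    ``cycle_fwd`` and ``cycle_bwd``, and ``haze``.  Total is

        adv_fwd + adv_bwd + lambda * (cycle_fwd + cycle_bwd) + w_haze * haze.
    """
    required = ("adv_fwd", "adv_bwd", "cycle_fwd", "cycle_bwd", "haze")
    terms = {}
    for name in required:
        t = parts[name]
        value = float(t.data) if isinstance(t, Tensor) else float(t)
        if not np.isfinite(value):
            raise DivergenceError(f"loss term {name!r} is non-finite")
        terms[name] = t
    total = (terms["adv_fwd"] + terms["adv_bwd"]
             + w.lambda_cycle * (terms["cycle_fwd"] + terms["cycle_bwd"])
             + w.w_haze * terms["haze"])
    breakdown = {k: float(v) for k, v in terms.items()}
    breakdown["total"] = float(total)
    return total, breakdown
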