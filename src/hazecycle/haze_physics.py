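"""The atmospheric scattering model as pure array functions.

Haze formation is modelled by Koschmieder's law

    I(x) = J(x) * t(x) + A * (1 - t(x)),

where ``J`` is the haze-free scene radiance, ``I`` the observed hazy image,
``t`` the per-pixel transmission (fraction of radiance surviving the haze)
and ``A`` the global atmospheric light.  All images are H x W x 3 floats in
[0, 1]; transmissions are H x W floats clamped to ``[T_MIN, 1]``.

These functions are shared by the synthetic benchmark (to *make* haze), the
training objective (to recompose a hazy image from a generator's haze-free
and transmission outputs) and inference.
"""

from __future__ import annotations

import numpy as np

#: Lower clamp on transmission, bounding the 1/t amplification on inversion.
T_MIN = 0.05

#: BT.601 luma weights used wherever a grayscale brightness is needed.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

__all__ = ["T_MIN", "LUMA_WEIGHTS", "apply_scattering", "invert_scattering",
           "estimate_atmospheric_light", "to_grayscale"]


def _check_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must be HxWx3, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    return img


def _check_pair(img: np.ndarray, t: np.ndarray):
    img = _check_image(img)
    t = np.asarray(t, dtype=np.float64)
    if t.shape != img.shape[:2]:
        raise ValueError(
            f"transmission shape {t.shape} does not match image {img.shape[:2]}")
    if not np.all(np.isfinite(t)):
        raise ValueError("transmission contains non-finite values")
    return img, t


def _check_airlight(a: float) -> float:
    a = float(a)
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"atmospheric light {a} outside [0, 1]")
    return a


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luma of an H x W x 3 image, same value range as the input."""
    return np.asarray(img, dtype=np.float64) @ LUMA_WEIGHTS


def apply_scattering(clear: np.ndarray, t: np.ndarray, airlight: float
                     ) -> np.ndarray:
    """Hazify: ``I = J*t + A*(1 - t)``, clipped to [0, 1].

    ``t`` is broadcast across the three colour channels.
    """
    clear, t = _check_pair(clear, t)
    a = _check_airlight(airlight)
    hazy = clear * t[..., None] + a * (1.0 - t[..., None])
    return np.clip(hazy, 0.0, 1.0)


def invert_scattering(hazy: np.ndarray, t: np.ndarray, airlight: float
                      ) -> np.ndarray:
    """Dehaze with a known transmission: ``J = (I - A*(1-t)) / t``.

    ``t`` is clamped to ``T_MIN`` before the division; output clipped to
    [0, 1].  Exact inverse of :func:`apply_scattering` wherever the forward
    model did not clip.
    """
    hazy, t = _check_pair(hazy, t)
    a = _check_airlight(airlight)
    t = np.clip(t, T_MIN, 1.0)[..., None]
    clear = (hazy - a * (1.0 - t)) / t
    return np.clip(clear, 0.0, 1.0)


def estimate_atmospheric_light(img: np.ndarray) -> float:
    """Estimate A as the brightest gray level in the image.

    Brightness is BT.601 luma; the single scalar is used for all three
    channels.
    """
    img = _check_image(img)
    return float(np.clip(to_grayscale(img).max(), 0.0, 1.0))
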