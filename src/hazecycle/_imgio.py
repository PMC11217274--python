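"""8-bit PNG/JPEG image I/O.

The only quantisation in the pipeline happens here: internal images are
float arrays in [0, 1]; files are 8-bit RGB (or 8-bit grayscale for
transmission maps).  Round-trip error is at most 1/255 per channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image as PILImage

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

__all__ = ["load_image", "save_image", "save_gray", "load_gray",
           "list_images", "IMAGE_EXTENSIONS"]


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB image into an HxWx3 float64 array in [0, 1]."""
    with PILImage.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_image(path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="RGB").save(path)


def save_gray(path, field: np.ndarray) -> None:
    """Write an HxW float field in [0, 1] as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(field) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)


def load_gray(path) -> np.ndarray:
    with PILImage.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def list_images(directory) -> list:
    """Sorted image paths under `directory` (non-recursive)."""
    directory = Path(directory)
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_EXTENSIONS)
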