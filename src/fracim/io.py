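"""Grayscale image reading and writing (PNG, TIFF).

The enhancement method is defined for single-channel images: multi-channel
inputs are collapsed to luma with ITU-R 601 weights (with a logged
warning) and 16-bit inputs are rescaled to the [0, 255] working range.
Writing quantizes with round-half-away-from-zero after clipping, so
metrics computed on written files match in-memory metrics to within half a
gray level per pixel.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .enhance import as_gray_image

__all__ = ["read_image", "write_image"]

log = logging.getLogger("fracim")

_LUMA_601 = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a float64 grayscale array in [0, 255]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        log.warning(
            "%s has %d channels; converting to luma (ITU-R 601)", path, arr.shape[2]
        )
        arr = arr[..., :3].astype(np.float64) @ _LUMA_601
    arr = arr.astype(np.float64)
    if arr.max() > 255.0:  # 16-bit input
        arr = arr * (255.0 / 65535.0)
    return as_gray_image(np.clip(arr, 0.0, 255.0))


def quantize(image) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to uint8."""
    img = np.clip(as_gray_image(np.asarray(image, dtype=float), check_range=False), 0, 255)
    return np.floor(img + 0.5).astype(np.uint8)


def write_image(path, image) -> None:
    """Write a grayscale image as an 8-bit file; format from the extension."""
    Image.fromarray(quantize(image), mode="L").save(Path(path))
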