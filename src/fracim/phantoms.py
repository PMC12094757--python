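"""Seeded grayscale phantoms with ground-truth region labels.

The generator emulates the statistical structure of the medical test
imagery the enhancement method targets — smooth anatomy plateaus, fine
texture patches, step edges — together with the modality-typical noise
models: additive Gaussian (CT / X-ray), multiplicative speckle
(ultrasound) and Rician magnitude noise (MRI). It makes no attempt at
anatomical realism (no k-space or beam physics); its job is to provide
deterministic inputs whose smooth/texture/edge layout is known exactly.

Texture is band-limited noise: a uniform random field passed through a
3x3 moving average and rescaled to a target RMS amplitude. Identical
:class:`PhantomSpec` values (including the seed) produce bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .enhance import EDGE, SMOOTH, TEXTURE, as_gray_image

__all__ = ["PhantomSpec", "generate_phantom", "noise_models"]

#: half-width (in columns/rows) of the band labeled "edge" around a step:
#: a 3x3 Sobel responds to a unit step only on the two flanking columns
_EDGE_BAND = 1

_CHECKER_BLOCK = 8  # checkerboard block side, pixels
_RING_WIDTH = 12  # concentric-ring width, pixels


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``smooth_level`` is the flat-region intensity; ``texture_amplitude``
    the RMS amplitude of the band-limited texture fluctuation;
    ``edge_contrast`` the step height between plateaus. ``noise_sd`` is in
    intensity units for ``gaussian`` and ``rician`` and a relative factor
    for ``speckle``.
    """

    height: int = 128
    width: int = 128
    layout: Literal["three_region", "step_edge", "checkerboard", "concentric"] = (
        "three_region"
    )
    smooth_level: float = 50.0
    texture_amplitude: float = 25.0
    edge_contrast: float = 180.0
    noise: Literal["none", "gaussian", "speckle", "rician"] = "gaussian"
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("phantoms must be at least 8x8")
        if not 0.0 <= self.smooth_level <= 255.0:
            raise ValueError("smooth_level must lie in [0, 255]")


def _texture_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited noise with RMS amplitude ``amplitude``."""
    raw = rng.uniform(-0.5, 0.5, size=shape)
    smooth = ndimage.uniform_filter(raw, size=3, mode="wrap")
    sd = smooth.std()
    if sd == 0 or amplitude == 0:
        return np.zeros(shape)
    return smooth * (amplitude / sd)


def _vertical_split(spec: PhantomSpec, rng: np.random.Generator, ramp: bool = False):
    """Left flat plateau, right elevated plateau; edge band at the split.

    With ``ramp`` the step passes through one intermediate mid-level
    column, so the transition a 3x3 Sobel flags spans the same three
    columns that larger (5x5) masks respond strongly to.
    """
    h, w = spec.height, spec.width
    split = w // 2
    img = np.full((h, w), spec.smooth_level, dtype=float)
    img[:, split:] += spec.edge_contrast
    labels = np.full((h, w), SMOOTH, dtype=np.uint8)
    if ramp:
        img[:, split - 1] += spec.edge_contrast / 2.0
        labels[:, split - 2 : split + 1] = EDGE
    else:
        labels[:, split - _EDGE_BAND : split + _EDGE_BAND] = EDGE
    return img, labels, split


def _build(spec: PhantomSpec, rng: np.random.Generator):
    h, w = spec.height, spec.width
    if spec.layout == "three_region":
        # two flat plateaus split by a vertical step edge; the texture
        # patch sits on the elevated plateau, away from the step
        # texture patch on the low plateau, clear of the step, so the step
        # contrast can be large without pushing the textured side into clip
        img, labels, split = _vertical_split(spec, rng, ramp=True)
        texture = _texture_field((h, w), spec.texture_amplitude, rng)
        r0, r1 = h // 4, h - h // 4
        c0, c1 = w // 8, 3 * (w // 8)
        img[r0:r1, c0:c1] += texture[r0:r1, c0:c1]
        labels[r0:r1, c0:c1] = TEXTURE
        return img, labels
    if spec.layout == "step_edge":
        img, labels, _ = _vertical_split(spec, rng)
        return img, labels
    if spec.layout == "checkerboard":
        yy, xx = np.mgrid[0:h, 0:w]
        parity = (yy // _CHECKER_BLOCK + xx // _CHECKER_BLOCK) % 2
        img = spec.smooth_level + parity * spec.edge_contrast
        near_y = np.minimum(yy % _CHECKER_BLOCK, (-yy - 1) % _CHECKER_BLOCK) < 1
        near_x = np.minimum(xx % _CHECKER_BLOCK, (-xx - 1) % _CHECKER_BLOCK) < 1
        labels = np.where(near_y | near_x, EDGE, SMOOTH).astype(np.uint8)
        return img.astype(float), labels
    if spec.layout == "concentric":
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        ring = (r // _RING_WIDTH).astype(int) % 2
        img = spec.smooth_level + ring * spec.edge_contrast
        frac = r % _RING_WIDTH
        near = (frac < 1.0) | (frac > _RING_WIDTH - 1.0)
        labels = np.where(near, EDGE, SMOOTH).astype(np.uint8)
        return img.astype(float), labels
    raise ValueError(f"unknown layout {spec.layout!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build a phantom and its ground-truth label grid.

    Returns ``(image, labels)``: a float image clipped to ``[0, 255]`` and
    a uint8 grid over ``{SMOOTH, TEXTURE, EDGE}`` covering every pixel.
    Noise is applied last, after the structural layout.
    """
    rng = np.random.default_rng(spec.seed)
    img, labels = _build(spec, rng)
    img = noise_models(np.clip(img, 0.0, 255.0), spec.noise, spec.noise_sd, rng=rng)
    return img, labels


def noise_models(
    image,
    model: str,
    sd: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply a modality noise model; result clipped to [0, 255].

    ``gaussian`` adds ``N(0, sd^2)``; ``speckle`` multiplies by
    ``1 + N(0, sd^2)`` (ultrasound-like, noise scales with intensity);
    ``rician`` returns ``sqrt((I + n1)^2 + n2^2)`` with independent
    ``N(0, sd^2)`` channels (magnitude-MRI-like). ``sd = 0`` is the
    identity for every model.
    """
    img = as_gray_image(image)
    if model == "none" or sd == 0:
        return img.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    if model == "gaussian":
        out = img + rng.normal(0.0, sd, img.shape)
    elif model == "speckle":
        out = img * (1.0 + rng.normal(0.0, sd, img.shape))
    elif model == "rician":
        n1 = rng.normal(0.0, sd, img.shape)
        n2 = rng.normal(0.0, sd, img.shape)
        out = np.hypot(img + n1, n2)
    else:
        raise ValueError(f"unknown noise model {model!r}")
    return np.clip(out, 0.0, 255.0)
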