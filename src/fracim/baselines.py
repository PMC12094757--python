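"""Integer-order comparison operators.

Sobel, Prewitt and Laplacian-of-Gaussian kernels, plus global histogram
equalization — the classical foils the fractional masks are benchmarked
against. Baseline enhancement runs through the same additive combination
rule as the fractional pipeline (``clip(image + lambda * response)``) so
comparisons are apples-to-apples.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from skimage import exposure

from .enhance import apply_mask, as_gray_image
from .masks import Mask

__all__ = ["classical_operator", "histogram_equalize", "enhance_classical"]

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_PREWITT_X = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])


def _plain_mask(weights: np.ndarray, name: str) -> Mask:
    # classical kernels carry no rho decomposition; record exact entries
    # symbolically in the rho0 slot times 0 to keep the Mask contract
    sym = tuple(
        tuple((Fraction(0), Fraction(0)) for _ in row) for row in weights
    )
    return Mask(
        size=weights.shape[0],
        direction=name,
        variant="canonical",
        weights=np.asarray(weights, dtype=float),
        symbolic=sym,
    )


def log_kernel(sigma: float = 1.0) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian kernel, mean-corrected to zero sum.

    Size is ``ceil(6*sigma)`` rounded up to the next odd integer.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    size = int(np.ceil(6.0 * sigma))
    if size % 2 == 0:
        size += 1
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x**2 + y**2
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    return k - k.mean()


def classical_operator(name: str, sigma: float = 1.0):
    """Standard integer-order kernels.

    ``sobel`` and ``prewitt`` return an ``(x, y)`` :class:`Mask` pair;
    ``log`` returns a single mean-corrected Laplacian-of-Gaussian mask.
    """
    name = name.lower()
    if name == "sobel":
        return (_plain_mask(_SOBEL_X, "sobel_x"), _plain_mask(_SOBEL_X.T, "sobel_y"))
    if name == "prewitt":
        return (
            _plain_mask(_PREWITT_X, "prewitt_x"),
            _plain_mask(_PREWITT_X.T, "prewitt_y"),
        )
    if name == "log":
        return _plain_mask(log_kernel(sigma), "log")
    raise ValueError(f"unknown classical operator {name!r}")


def histogram_equalize(image) -> np.ndarray:
    """Global histogram equalization via a 256-bin CDF remap, output in [0, 255]."""
    img = as_gray_image(image)
    return exposure.equalize_hist(img, nbins=256) * 255.0


def enhance_classical(
    image, name: str, intensity_factor: float = 1.0, padding: str = "replicate",
    sigma: float = 1.0,
) -> np.ndarray:
    """Classical-operator enhancement through the shared additive rule.

    Gradient-pair operators use the Euclidean magnitude of their x/y
    responses as the response; LoG uses its (signed) response directly.
    """
    img = as_gray_image(image)
    op = classical_operator(name, sigma)
    if isinstance(op, tuple):
        gx = apply_mask(img, op[0], padding)
        gy = apply_mask(img, op[1], padding)
        response = np.hypot(gx, gy)
    else:
        response = apply_mask(img, op, padding)
    return np.clip(img + intensity_factor * response, 0.0, 255.0)
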