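"""Full-reference image-quality metrics: MSE, PSNR, SSIM, CNR.

SSIM follows the standard three-component (luminance, contrast, structure)
construction evaluated on unweighted square sliding windows (stride 1) and
averaged over all windows; with the default unit exponents and
``C3 = C2/2`` the product collapses to the familiar single-fraction form.
Stabilizers use the universal constants ``C1 = (0.01*255)^2`` and
``C2 = (0.03*255)^2``.

CNR has no universally agreed formula; this module's convention is

    CNR = |mean(roi) - mean(background)| / std(background)

which is documented here because published CNR numbers elsewhere may use a
different one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .enhance import as_gray_image

__all__ = ["SSIMParams", "MetricReport", "mse", "psnr", "ssim", "cnr", "report"]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM window size, stabilizers and component exponents."""

    window: int = 8
    c1: float = (0.01 * 255.0) ** 2
    c2: float = (0.03 * 255.0) ** 2
    c3: float | None = None  # defaults to c2 / 2
    alpha_l: float = 1.0
    beta_c: float = 1.0
    gamma_s: float = 1.0

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("SSIM window must be at least 2 pixels")
        if self.c3 is None:
            object.__setattr__(self, "c3", self.c2 / 2.0)


@dataclass(frozen=True)
class MetricReport:
    """PSNR/MSE/SSIM (and optionally CNR) for a reference/test pair."""

    mse: float
    psnr_db: float
    ssim_mean: float
    cnr: float | None = None

    def to_json(self) -> str:
        d = {
            "mse": self.mse,
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "ssim_mean": self.ssim_mean,
        }
        if self.cnr is not None:
            d["cnr"] = "inf" if math.isinf(self.cnr) else self.cnr
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [
            f"MSE   {self.mse:.6g}",
            f"PSNR  {self.psnr_db:.6g} dB",
            f"SSIM  {self.ssim_mean:.6g}",
        ]
        if self.cnr is not None:
            lines.append(f"CNR   {self.cnr:.6g}")
        return "\n".join(lines)


def _pair(ref, test) -> tuple[np.ndarray, np.ndarray]:
    r = as_gray_image(ref, check_range=False)
    t = as_gray_image(test, check_range=False)
    if r.shape != t.shape:
        raise ValueError(f"image shapes differ: {r.shape} vs {t.shape}")
    return r, t


def mse(ref, test) -> float:
    """Mean squared per-pixel difference."""
    r, t = _pair(ref, test)
    return float(np.mean((r - t) ** 2))


def psnr(ref, test, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are identical."""
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / err)


def _windows(img: np.ndarray, w: int):
    """Per-window mean and raw second moment over all w-by-w windows, stride 1."""
    views = np.lib.stride_tricks.sliding_window_view(img, (w, w))
    mu = views.mean(axis=(-2, -1))
    ex2 = (views * views).mean(axis=(-2, -1))
    return mu, ex2, views


def ssim(ref, test, params: SSIMParams | None = None) -> tuple[float, np.ndarray]:
    """Structural similarity: returns ``(mean over windows, per-window map)``.

    The map has shape ``(H - w + 1, W - w + 1)`` for window side ``w``.
    """
    params = params or SSIMParams()
    r, t = _pair(ref, test)
    w = params.window
    if w > min(r.shape):
        raise ValueError(f"window {w} exceeds image dimensions {r.shape}")
    mu_x, ex2_x, vx = _windows(r, w)
    mu_y, ex2_y, vy = _windows(t, w)
    # variance and covariance share the moment formula E[uv] - mu_u*mu_v so
    # identical inputs give bitwise-equal var/cov and an exact score of 1
    var_x = ex2_x - mu_x * mu_x
    var_y = ex2_y - mu_y * mu_y
    cov = (vx * vy).mean(axis=(-2, -1)) - mu_x * mu_y

    if params.alpha_l == params.beta_c == params.gamma_s == 1.0 and (
        params.c3 == params.c2 / 2.0
    ):
        # the three components collapse to the single-fraction form
        smap = ((2 * mu_x * mu_y + params.c1) * (2 * cov + params.c2)) / (
            (mu_x * mu_x + mu_y * mu_y + params.c1) * (var_x + var_y + params.c2)
        )
    else:
        sd_x = np.sqrt(np.maximum(var_x, 0.0))
        sd_y = np.sqrt(np.maximum(var_y, 0.0))
        lum = (2 * mu_x * mu_y + params.c1) / (mu_x * mu_x + mu_y * mu_y + params.c1)
        con = (2 * sd_x * sd_y + params.c2) / (var_x + var_y + params.c2)
        struct = (cov + params.c3) / (sd_x * sd_y + params.c3)
        smap = lum**params.alpha_l * con**params.beta_c * struct**params.gamma_s
    return float(smap.mean()), smap


def cnr(image, roi_mask, background_mask) -> float:
    """Contrast-to-noise ratio between an ROI and a background region.

    ``|mean(roi) - mean(bg)| / std(bg)``; ``inf`` when the background has
    zero variance but the means differ, ``0.0`` when both statistics match.
    """
    img = as_gray_image(image, check_range=False)
    roi = np.asarray(roi_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if roi.shape != img.shape or bg.shape != img.shape:
        raise ValueError("masks must match the image shape")
    if not roi.any() or not bg.any():
        raise ValueError("both masks must select at least one pixel")
    if (roi & bg).any():
        raise ValueError("ROI and background masks must be disjoint")
    contrast = abs(float(img[roi].mean()) - float(img[bg].mean()))
    noise = float(img[bg].std())
    if noise == 0.0:
        return math.inf if contrast > 0 else 0.0
    return contrast / noise


def report(
    ref, test, params: SSIMParams | None = None, roi_mask=None, background_mask=None
) -> MetricReport:
    """Bundle MSE/PSNR/SSIM (and CNR if masks are given) for a pair."""
    value_cnr = None
    if roi_mask is not None and background_mask is not None:
        value_cnr = cnr(test, roi_mask, background_mask)
    return MetricReport(
        mse=mse(ref, test),
        psnr_db=psnr(ref, test),
        ssim_mean=ssim(ref, test, params)[0],
        cnr=value_cnr,
    )
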