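"""Full-reference image-quality metrics: MSE, PSNR, SSIM.

Used to score each preprocessing stage against a reference image. PSNR is
``10·log10(MAX²/MSE)`` in decibels with ``MAX`` taken from the declared
value range; identical images report ``mse = 0`` and an infinite PSNR.
SSIM follows the canonical Wang et al. formulation (11×11 Gaussian window,
σ = 1.5, K1 = 0.01, K2 = 0.03) on the luminance channel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .image import ImageTensor

__all__ = ["QualityReport", "mse", "psnr", "ssim"]

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _check_pair(a: ImageTensor, b: ImageTensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.value_range != b.value_range:
        raise ValueError("images must share a declared value range")


def mse(a: ImageTensor, b: ImageTensor) -> float:
    """Mean squared per-pixel difference over all pixels and channels."""
    _check_pair(a, b)
    return float(np.mean((a.pixels - b.pixels) ** 2))


def psnr(a: ImageTensor, b: ImageTensor, max_value: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    ``max_value`` defaults to the top of the images' declared range.
    """
    _check_pair(a, b)
    if max_value is None:
        max_value = a.value_range[1]
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / err)


def ssim(a: ImageTensor, b: ImageTensor) -> float:
    """Mean local structural similarity of the luminance channels."""
    _check_pair(a, b)
    la, lb = a.luminance(), b.luminance()
    if min(la.shape) < SSIM_WINDOW:
        raise ValueError(f"image smaller than the {SSIM_WINDOW}×{SSIM_WINDOW} SSIM window")
    lo, hi = a.value_range
    return float(
        structural_similarity(
            la,
            lb,
            win_size=SSIM_WINDOW,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            K1=SSIM_K1,
            K2=SSIM_K2,
            use_sample_covariance=False,
            data_range=hi - lo,
        )
    )


@dataclass(frozen=True)
class QualityReport:
    """MSE / PSNR / SSIM of a test image against a reference."""

    mse: float
    psnr_db: float  # math.inf when mse == 0
    ssim: float

    @classmethod
    def from_pair(cls, ref: ImageTensor, test: ImageTensor) -> "QualityReport":
        return cls(mse(ref, test), psnr(ref, test), ssim(ref, test))

    def to_json(self) -> str:
        d = {
            "mse": self.mse,
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
        }
        return json.dumps(d)
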