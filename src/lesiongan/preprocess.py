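"""Dermoscopy image preprocessing pipeline.

Stages, in pipeline order: bicubic rescaling (Keys cubic-convolution kernel,
a = −0.5, the classical 16-neighbor weighted average), normalization to
[0, 1], CDF-based histogram equalization of the luminance channel, combined
sharpening (spatial-domain unsharp masking + frequency-domain Gaussian
high-pass filtering, blended with configurable weights), CIELAB channel-wise
color balance (mean/std matching), and median filtering. Noise models
(salt & pepper, Gaussian, speckle, Poisson) are provided for denoising
evaluation, not as a pipeline stage.

All operations take and return :class:`~lesiongan.image.ImageTensor`; any
operation that can push values out of the declared range clips back into it.
Windowed filters use reflect padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .image import ImageTensor, RANGE_8BIT, RANGE_UNIT

def _lab2rgb_clipped(lab: np.ndarray) -> np.ndarray:
    """LAB → RGB, clipped to [0,1]; out-of-gamut warnings are expected
    after channel rescaling and suppressed."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        return np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)


__all__ = [
    "HistogramCDF",
    "SharpenConfig",
    "NoiseSpec",
    "PipelineConfig",
    "normalize01",
    "resize_bicubic",
    "histogram_cdf",
    "equalize_histogram",
    "sharpen_usm",
    "ghpf",
    "combine_sharpen",
    "color_balance_lab",
    "add_noise",
    "median_filter",
    "preprocess_pipeline",
]


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def normalize01(img: ImageTensor) -> ImageTensor:
    """Rescale an 8-bit-range image to [0, 1] by dividing by 255."""
    if img.value_range == RANGE_UNIT:
        warnings.warn("image already in [0, 1]; normalize01 is a no-op", stacklevel=2)
        return img.with_pixels(img.pixels.copy())
    if img.value_range != RANGE_8BIT:
        raise ValueError(f"cannot normalize from range {img.value_range}")
    return img.with_pixels(img.pixels / 255.0, value_range=RANGE_UNIT)


# ----------------------------------------------------------------------
# bicubic resize (Keys cubic convolution, a = -0.5)
# ----------------------------------------------------------------------

def _keys_kernel(s: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic-convolution interpolation kernel of Keys (1981)."""
    s = np.abs(s)
    out = np.zeros_like(s)
    m1 = s <= 1
    out[m1] = (a + 2) * s[m1] ** 3 - (a + 3) * s[m1] ** 2 + 1
    m2 = (s > 1) & (s < 2)
    out[m2] = a * s[m2] ** 3 - 5 * a * s[m2] ** 2 + 8 * a * s[m2] - 4 * a
    return out


def _resize_weights(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) row-interpolation matrix for one axis.

    Output sample i maps to source coordinate (i + 0.5)·n_in/n_out − 0.5
    (pixel-center alignment); the four taps around it get Keys-kernel
    weights, with out-of-bounds taps clamped to the edge sample.
    """
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    base = np.floor(src).astype(int)
    frac = src - base
    W = np.zeros((n_out, n_in))
    for t in range(-1, 3):
        w = _keys_kernel(frac - t)
        idx = np.clip(base + t, 0, n_in - 1)
        np.add.at(W, (np.arange(n_out), idx), w)
    return W


def resize_bicubic(img: ImageTensor, out_h: int, out_w: int) -> ImageTensor:
    """Bicubic resampling: each output pixel is a weighted average of the
    16 nearest source pixels (4×4 neighborhood, separable Keys kernel)."""
    if out_h < 1 or out_w < 1:
        raise ValueError("output size must be at least 1×1")
    if img.height == 0 or img.width == 0:
        raise ValueError("cannot resize an empty image")
    Wr = _resize_weights(img.height, out_h)
    Wc = _resize_weights(img.width, out_w)
    out = np.einsum("ij,jkc,lk->ilc", Wr, img.pixels, Wc, optimize=True)
    lo, hi = img.value_range
    return img.with_pixels(np.clip(out, lo, hi))


# ----------------------------------------------------------------------
# histogram equalization
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HistogramCDF:
    """256-bin histogram and its normalized cumulative distribution."""

    bin_counts: np.ndarray  # (256,) int
    cdf: np.ndarray  # (256,) float in [0, 1]


def _quantize_256(values: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    """Map intensities in the declared range onto integer levels 0..255
    (half-up rounding; [0,1] images are scaled by 255 first)."""
    lo, hi = value_range
    levels = (values - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(levels + 0.5), 0, 255).astype(np.intp)


def histogram_cdf(img: ImageTensor) -> HistogramCDF:
    """256-bin histogram + CDF of the luminance channel.

    The histogram is normalized by the pixel count; the CDF is its
    cumulative sum, so ``cdf[255] == 1`` for any non-empty image.
    """
    levels = _quantize_256(img.luminance(), img.value_range)
    counts = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(counts) / levels.size
    return HistogramCDF(counts, cdf)


def _equalize_channel(levels: np.ndarray) -> np.ndarray:
    """Equalize integer levels 0..255 via the CDF mapping
    out(v) = round((cdf(v) − cdf_min) / (1 − cdf_min) · 255)."""
    counts = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(counts) / levels.size
    nonzero = cdf[cdf > 0]
    cdf_min = nonzero[0]
    if cdf_min >= 1.0:  # constant image: mapping is 0/0 — leave unchanged
        return levels
    lut = np.floor((cdf - cdf_min) / (1.0 - cdf_min) * 255.0 + 0.5)
    return np.clip(lut, 0, 255)[levels]


def equalize_histogram(img: ImageTensor) -> ImageTensor:
    """Histogram-equalize the luminance, preserving chroma.

    Grayscale images are equalized directly on their 256-level
    quantization. RGB images are converted to CIELAB, the L channel
    (rescaled to 0..255) is equalized, and the result converted back — so
    contrast is stretched without distorting hue.
    """
    if img.color_space == "GRAY":
        levels = _quantize_256(img.pixels[:, :, 0], img.value_range)
        eq = _equalize_channel(levels).astype(np.float64)
        lo, hi = img.value_range
        return img.with_pixels((eq / 255.0 * (hi - lo) + lo)[:, :, None])
    if img.color_space != "RGB":
        raise ValueError("equalize_histogram expects RGB or GRAY input")
    lo, hi = img.value_range
    rgb = (img.pixels - lo) / (hi - lo)
    lab = skcolor.rgb2lab(rgb)
    levels = np.clip(np.floor(lab[:, :, 0] / 100.0 * 255.0 + 0.5), 0, 255).astype(np.intp)
    lab[:, :, 0] = _equalize_channel(levels).astype(np.float64) / 255.0 * 100.0
    out = _lab2rgb_clipped(lab) * (hi - lo) + lo
    return img.with_pixels(out)


# ----------------------------------------------------------------------
# sharpening: USM (spatial) + GHPF (frequency) blend
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SharpenConfig:
    """Parameters of the combined USM + GHPF sharpener.

    ``ghpf_cutoff`` is the Gaussian high-pass cutoff D0 in normalized
    frequency units (cycles/pixel; Nyquist = 0.5). The default 0.05 is
    0.1 × Nyquist. ``weight_usm``/``weight_ghpf`` blend the two branch
    outputs; they need not sum to 1 but cannot both be zero.
    """

    usm_sigma: float = 1.0
    usm_amount: float = 1.0
    ghpf_cutoff: float = 0.05
    ghpf_gain: float = 1.0
    weight_usm: float = 0.5
    weight_ghpf: float = 0.5

    def __post_init__(self) -> None:
        if self.usm_sigma <= 0 or self.ghpf_cutoff <= 0:
            raise ValueError("usm_sigma and ghpf_cutoff must be positive")
        if min(self.usm_amount, self.ghpf_gain, self.weight_usm, self.weight_ghpf) < 0:
            raise ValueError("amounts, gains and weights must be nonnegative")
        if self.weight_usm + self.weight_ghpf <= 0:
            raise ValueError("at least one branch weight must be positive")


def sharpen_usm(img: ImageTensor, sigma: float = 1.0, amount: float = 1.0) -> ImageTensor:
    """Unsharp masking: ``clip(img + amount·(img − gaussian_blur(img, sigma)))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    blurred = np.stack(
        [
            ndimage.gaussian_filter(img.pixels[:, :, c], sigma=sigma, mode="reflect")
            for c in range(img.channels)
        ],
        axis=2,
    )
    lo, hi = img.value_range
    return img.with_pixels(np.clip(img.pixels + amount * (img.pixels - blurred), lo, hi))


def _ghpf_transfer(h: int, w: int, cutoff: float) -> np.ndarray:
    """Gaussian high-pass transfer 1 − exp(−D²/(2·D0²)) on the FFT grid,
    with D in cycles/pixel."""
    fu = np.fft.fftfreq(h)[:, None]
    fv = np.fft.fftfreq(w)[None, :]
    d2 = fu**2 + fv**2
    return 1.0 - np.exp(-d2 / (2.0 * cutoff**2))


def ghpf(img: ImageTensor, cutoff: float = 0.05, gain: float = 1.0) -> ImageTensor:
    """Frequency-domain Gaussian high-pass sharpening.

    The high-frequency component extracted with transfer
    ``H = 1 − exp(−D²/2D0²)`` is scaled by ``gain`` and added back:
    ``clip(img + gain·highpass(img))``, per channel.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    H = _ghpf_transfer(img.height, img.width, cutoff)
    out = np.empty_like(img.pixels)
    for c in range(img.channels):
        hp = np.fft.ifft2(np.fft.fft2(img.pixels[:, :, c]) * H).real
        out[:, :, c] = img.pixels[:, :, c] + gain * hp
    lo, hi = img.value_range
    return img.with_pixels(np.clip(out, lo, hi))


def combine_sharpen(img: ImageTensor, cfg: SharpenConfig | None = None) -> ImageTensor:
    """Weighted blend of the USM and GHPF branch outputs, then clip."""
    cfg = cfg or SharpenConfig()
    usm = sharpen_usm(img, cfg.usm_sigma, cfg.usm_amount)
    hp = ghpf(img, cfg.ghpf_cutoff, cfg.ghpf_gain)
    mix = cfg.weight_usm * usm.pixels + cfg.weight_ghpf * hp.pixels
    lo, hi = img.value_range
    return img.with_pixels(np.clip(mix, lo, hi))


# ----------------------------------------------------------------------
# CIELAB color balance
# ----------------------------------------------------------------------

def color_balance_lab(
    img: ImageTensor,
    target_means: tuple[float, float, float] = (50.0, 0.0, 0.0),
    target_stds: tuple[float, float, float] = (25.0, 10.0, 10.0),
) -> ImageTensor:
    """Match per-channel CIELAB mean/std to targets, channel by channel.

    Each LAB channel is shifted and scaled so its mean and standard
    deviation equal the targets (scale factor std_target/std_channel,
    chosen separately per channel); a zero-variance channel keeps scale 1
    and is only re-centered. Output is converted back to RGB and clipped.
    The default targets (a mid-lightness, chroma-neutral reference) are a
    package convention, configurable per run.
    """
    if img.color_space != "RGB":
        raise ValueError("color_balance_lab expects an RGB image")
    lo, hi = img.value_range
    lab = skcolor.rgb2lab((img.pixels - lo) / (hi - lo))
    for c in range(3):
        ch = lab[:, :, c]
        mu, sd = ch.mean(), ch.std()
        scale = target_stds[c] / sd if sd > 1e-12 else 1.0
        lab[:, :, c] = (ch - mu) * scale + target_means[c]
    out = _lab2rgb_clipped(lab) * (hi - lo) + lo
    return img.with_pixels(out)


# ----------------------------------------------------------------------
# noise models + median filter
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """One corruption model for denoising evaluation.

    ``density`` applies to salt & pepper (fraction of corrupted pixels);
    ``sigma`` to Gaussian/speckle noise (on the [0,1] intensity scale);
    ``photon_budget`` to Poisson resampling (expected counts at full
    intensity). Irrelevant parameters are validated but ignored.
    """

    kind: str  # salt_pepper | poisson | speckle | gaussian
    density: float = 0.05
    sigma: float = 0.1
    photon_budget: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("salt_pepper", "poisson", "speckle", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")


def add_noise(img: ImageTensor, spec: NoiseSpec) -> ImageTensor:
    """Seeded corruption of an image under one of four noise models."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = img.value_range
    px = img.pixels.copy()
    if spec.kind == "salt_pepper":
        hit = rng.random(px.shape[:2]) < spec.density
        salt = rng.random(px.shape[:2]) < 0.5
        px[hit & salt] = hi
        px[hit & ~salt] = lo
    elif spec.kind == "gaussian":
        px = px + rng.normal(0.0, spec.sigma * (hi - lo), px.shape)
    elif spec.kind == "speckle":
        px = px * (1.0 + rng.normal(0.0, spec.sigma, px.shape))
    else:  # poisson
        unit = (px - lo) / (hi - lo)
        counts = rng.poisson(unit * spec.photon_budget)
        px = counts / spec.photon_budget * (hi - lo) + lo
    return img.with_pixels(np.clip(px, lo, hi))


def median_filter(img: ImageTensor, k: int = 3) -> ImageTensor:
    """Per-channel k×k sliding-window median with reflect padding."""
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer ≥ 3")
    out = np.stack(
        [
            ndimage.median_filter(img.pixels[:, :, c], size=k, mode="reflect")
            for c in range(img.channels)
        ],
        axis=2,
    )
    return img.with_pixels(out)


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Which stages run, and with what parameters.

    Stage order is fixed (resize → normalize → equalize → sharpen → color
    balance → median filter); each stage can be disabled independently.
    """

    target_size: tuple[int, int] = (64, 64)
    resize: bool = True
    normalize: bool = True
    equalize: bool = True
    sharpen: bool = True
    sharpen_cfg: SharpenConfig = field(default_factory=SharpenConfig)
    color_balance: bool = True
    lab_target_means: tuple[float, float, float] = (50.0, 0.0, 0.0)
    lab_target_stds: tuple[float, float, float] = (25.0, 10.0, 10.0)
    median: bool = True
    median_k: int = 3


def preprocess_pipeline(img: ImageTensor, cfg: PipelineConfig | None = None) -> ImageTensor:
    """Run the configured stages in order and return a [0, 1] RGB image."""
    cfg = cfg or PipelineConfig()
    if img.color_space != "RGB":
        raise ValueError("pipeline expects an RGB image")
    out = img
    if cfg.resize:
        out = resize_bicubic(out, *cfg.target_size)
    if cfg.normalize and out.value_range == RANGE_8BIT:
        out = normalize01(out)
    if cfg.equalize:
        out = equalize_histogram(out)
    if cfg.sharpen:
        out = combine_sharpen(out, cfg.sharpen_cfg)
    if cfg.color_balance:
        out = color_balance_lab(out, cfg.lab_target_means, cfg.lab_target_stds)
    if cfg.median:
        out = median_filter(out, cfg.median_k)
    return out
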