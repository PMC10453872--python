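"""Image container with a declared intensity range and color space.

Every stage of the preprocessing and modelling pipeline passes images around
as :class:`ImageTensor` — an ``H×W×C`` float array plus the metadata needed
to interpret it (whether intensities live in ``[0, 1]`` or ``[0, 255]``, and
which color space the channels represent). Keeping the declared range with
the pixels lets each stage clip and rescale against the right bounds instead
of guessing from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ImageTensor", "RANGE_UNIT", "RANGE_8BIT"]

RANGE_UNIT = (0.0, 1.0)
RANGE_8BIT = (0.0, 255.0)

_COLOR_CHANNELS = {"RGB": 3, "LAB": 3, "GRAY": 1}


@dataclass
class ImageTensor:
    """An ``H×W×C`` real-valued image with a declared intensity range.

    Parameters
    ----------
    pixels:
        Float array of shape ``(H, W, C)``; single-channel images may be
        passed as ``(H, W)`` and are reshaped to ``(H, W, 1)``.
    value_range:
        Declared intensity bounds, either ``(0, 1)`` or ``(0, 255)``.
        LAB images carry their native channel ranges and use the range of
        the RGB image they came from only for bookkeeping.
    color_space:
        One of ``"RGB"``, ``"LAB"``, ``"GRAY"``.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = RANGE_UNIT
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"expected H×W×C pixels, got shape {px.shape}")
        if self.color_space not in _COLOR_CHANNELS:
            raise ValueError(f"unknown color space {self.color_space!r}")
        want = _COLOR_CHANNELS[self.color_space]
        if px.shape[2] != want:
            raise ValueError(
                f"{self.color_space} image must have {want} channels, "
                f"got {px.shape[2]}"
            )
        self.pixels = px
        self.value_range = (float(self.value_range[0]), float(self.value_range[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    # -- transforms -----------------------------------------------------
    def with_pixels(self, pixels: np.ndarray, **changes) -> "ImageTensor":
        """Copy of this image with new pixel data (and optional metadata)."""
        return replace(self, pixels=pixels, **changes)

    def clipped(self) -> "ImageTensor":
        lo, hi = self.value_range
        return self.with_pixels(np.clip(self.pixels, lo, hi))

    def luminance(self) -> np.ndarray:
        """Rec. 601 luma as an ``(H, W)`` array in this image's range."""
        if self.color_space == "GRAY":
            return self.pixels[:, :, 0]
        if self.color_space != "RGB":
            raise ValueError("luminance is defined for RGB or GRAY images")
        r, g, b = (self.pixels[:, :, i] for i in range(3))
        return 0.299 * r + 0.587 * g + 0.114 * b

    # -- I/O --------------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "ImageTensor":
        """Read a PNG/JPEG file as an RGB image in ``[0, 1]``."""
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        return cls(arr, RANGE_UNIT, "RGB")

    def save(self, path: str | Path) -> None:
        """Write as an 8-bit PNG/JPEG (format from the file extension)."""
        lo, hi = self.value_range
        px = (self.pixels - lo) / (hi - lo)
        arr = np.clip(np.floor(px * 255.0 + 0.5), 0, 255).astype(np.uint8)
        if self.channels == 1:
            arr = arr[:, :, 0]
        Image.fromarray(arr).save(path)
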