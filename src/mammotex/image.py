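"""Grayscale image container used throughout the package.

A region of interest (ROI) is a plain 2-D raster of gray levels together
with the maximum representable level ``K`` (255 for 8-bit input, 65535 for
16-bit).  Pixel values may become real-valued after interpolation or mean
filtering, so the container stores floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "as_pixels"]


@dataclass
class GrayImage:
    """A 2-D grayscale raster.

    Parameters
    ----------
    pixels
        2-D array of gray values.  Stored as ``float64``.
    max_level
        Maximum gray level ``K`` implied by the bit depth of the source
        (255 for 8-bit).  All pixels must lie in ``[0, max_level]``.
    """

    pixels: np.ndarray
    max_level: float = 255
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > self.max_level:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.max_level}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def crop(self, row0: int, col0: int, height: int, width: int) -> "GrayImage":
        """Exact sub-raster copy; 0-based, half-open intervals."""
        if row0 < 0 or col0 < 0 or height < 1 or width < 1:
            raise ValueError("crop rectangle must be non-empty and non-negative")
        if row0 + height > self.height or col0 + width > self.width:
            raise ValueError(
                f"crop ({row0}:{row0 + height}, {col0}:{col0 + width}) exceeds "
                f"image shape {self.shape}"
            )
        return GrayImage(
            self.pixels[row0 : row0 + height, col0 : col0 + width].copy(),
            max_level=self.max_level,
        )


def as_pixels(image: "GrayImage | np.ndarray") -> np.ndarray:
    """Return the float64 pixel raster of an image-like argument."""
    if isinstance(image, GrayImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)
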