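"""Circular neighborhood geometry and bilinear sampling.

All texture coders in this package threshold the gray values of ``P``
neighbors placed evenly on a circle of radius ``R`` around each pixel.
Neighbor ``p`` sits at angle ``2*pi*p/P`` measured counter-clockwise from
the positive column (east) axis; because image rows grow downward the row
offset is ``-R*sin`` and the column offset ``R*cos``.  Off-grid sample
points are estimated by bilinear interpolation of the four surrounding
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import GrayImage, as_pixels

__all__ = [
    "NeighborhoodConfig",
    "neighbor_offsets",
    "sample_neighbors",
    "sample_neighbor_stack",
    "valid_border",
    "valid_slices",
]


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Circularly symmetric neighbor set: ``n_neighbors`` (P) on radius ``R``.

    The presets (8, 1), (16, 2) and (24, 3) are the standard operating
    points; (24, 3) is the package default.
    """

    n_neighbors: int = 24
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.n_neighbors < 4:
            raise ValueError(f"need at least 4 neighbors, got {self.n_neighbors}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1 pixel, got {self.radius}")

    @classmethod
    def preset(cls, p: int) -> "NeighborhoodConfig":
        presets = {8: (8, 1.0), 16: (16, 2.0), 24: (24, 3.0)}
        if p not in presets:
            raise ValueError(f"no preset for P={p}; known: {sorted(presets)}")
        return cls(*presets[p])


def neighbor_offsets(config: NeighborhoodConfig) -> np.ndarray:
    """(P, 2) array of (row, col) offsets of the circular neighbors."""
    p = np.arange(config.n_neighbors)
    angles = 2.0 * math.pi * p / config.n_neighbors
    rows = -config.radius * np.sin(angles)
    cols = config.radius * np.cos(angles)
    # snap almost-integral coordinates so axial neighbors hit the grid exactly
    rows[np.abs(rows - np.round(rows)) < 1e-9] = np.round(
        rows[np.abs(rows - np.round(rows)) < 1e-9]
    )
    cols[np.abs(cols - np.round(cols)) < 1e-9] = np.round(
        cols[np.abs(cols - np.round(cols)) < 1e-9]
    )
    return np.stack([rows, cols], axis=1)


def valid_border(config: NeighborhoodConfig) -> int:
    """Border width excluded from coding.

    Wide enough for both the sampling circle and the 3x3 mean window.
    """
    return int(math.ceil(config.radius)) + 1


def valid_slices(shape: tuple[int, int], config: NeighborhoodConfig) -> tuple[slice, slice]:
    """Interior region where every sample point and mean window fits."""
    b = valid_border(config)
    n1, n2 = shape
    if n1 - 2 * b < 1 or n2 - 2 * b < 1:
        raise ValueError(
            f"image {shape} too small for P={config.n_neighbors}, R={config.radius}"
        )
    return slice(b, n1 - b), slice(b, n2 - b)


def _bilinear(pixels: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at real-valued (row, col) positions.

    All positions must be inside the image; identical to
    ``scipy.ndimage.map_coordinates(order=1)`` but kept explicit so that
    on-grid points return the exact pixel value.
    """
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    r0 = np.clip(r0, 0, pixels.shape[0] - 2)
    c0 = np.clip(c0, 0, pixels.shape[1] - 2)
    dr = rows - r0
    dc = cols - c0
    top = pixels[r0, c0] * (1 - dc) + pixels[r0, c0 + 1] * dc
    bot = pixels[r0 + 1, c0] * (1 - dc) + pixels[r0 + 1, c0 + 1] * dc
    return top * (1 - dr) + bot * dr


def sample_neighbors(
    image: GrayImage | np.ndarray,
    row: float,
    col: float,
    config: NeighborhoodConfig,
) -> np.ndarray:
    """Gray values of the P circular neighbors of one pixel.

    Raises if any sample point falls outside the image; callers should
    restrict themselves to the valid interior region.
    """
    pixels = as_pixels(image)
    offsets = neighbor_offsets(config)
    rows = row + offsets[:, 0]
    cols = col + offsets[:, 1]
    n1, n2 = pixels.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > n1 - 1 or cols.max() > n2 - 1:
        raise ValueError(
            f"sample circle around ({row}, {col}) leaves the {pixels.shape} image"
        )
    return _bilinear(pixels, rows, cols)


def sample_neighbor_stack(
    image: GrayImage | np.ndarray, config: NeighborhoodConfig
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Neighbor gray values for every valid pixel at once.

    Returns
    -------
    stack
        Array of shape ``(P, H_v, W_v)``: plane ``p`` holds the value of
        neighbor ``p`` for each pixel of the valid region.
    valid
        The (row, col) slices of the valid region in the input image.
    """
    pixels = as_pixels(image)
    valid = valid_slices(pixels.shape, config)
    rows = np.arange(valid[0].start, valid[0].stop, dtype=np.float64)
    cols = np.arange(valid[1].start, valid[1].stop, dtype=np.float64)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    offsets = neighbor_offsets(config)
    planes = np.empty((config.n_neighbors, grid_r.shape[0], grid_r.shape[1]))
    for p, (dr, dc) in enumerate(offsets):
        if dr == int(dr) and dc == int(dc):
            # on-grid neighbor: exact pixel values via an integer shift
            planes[p] = pixels[
                int(valid[0].start + dr) : int(valid[0].stop + dr),
                int(valid[1].start + dc) : int(valid[1].stop + dc),
            ]
        else:
            planes[p] = _bilinear(pixels, grid_r + dr, grid_c + dc)
    return planes, valid
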