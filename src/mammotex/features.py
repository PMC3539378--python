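"""Histogramming of code rasters and assembly of the GLLD feature vector.

Two assembly modes are provided:

* ``"joint"`` (default) — the 3-D joint histogram over the triple
  (SGLLD^riu2, MGLLD^riu2, CGLLD), flattened to ``(P+2) * (P+2) * 2``
  bins.  At the standard operating point (P, R) = (24, 3) this yields the
  1352-component descriptor that feeds a 1352-input perceptron.
* ``"concat"`` — the three marginal histograms concatenated,
  ``2*(P+2) + 2`` bins.

Features are L1-normalized by default so descriptors of ROIs with
different pixel counts are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import CodeMaps, compute_code_maps
from .image import GrayImage
from .neighborhood import NeighborhoodConfig

__all__ = [
    "FeatureVector",
    "code_histogram",
    "feature_length",
    "glld_feature",
    "extract_features",
]


def code_histogram(codes: np.ndarray, n_bins: int) -> np.ndarray:
    """Occurrence histogram of an integer code raster.

    Bin ``k`` counts the pixels whose code equals ``k``; the bins sum to
    the number of coded pixels.
    """
    flat = np.asarray(codes).ravel()
    if flat.size and (flat.min() < 0 or flat.max() >= n_bins):
        raise ValueError(
            f"codes span [{flat.min()}, {flat.max()}], outside [0, {n_bins - 1}]"
        )
    return np.bincount(flat, minlength=n_bins).astype(np.int64)


def feature_length(n_neighbors: int, mode: str) -> int:
    """Descriptor length for a given neighbor count and assembly mode."""
    if mode == "joint":
        return (n_neighbors + 2) * (n_neighbors + 2) * 2
    if mode == "concat":
        return 2 * (n_neighbors + 2) + 2
    raise ValueError(f"unknown mode {mode!r}; use 'joint' or 'concat'")


@dataclass
class FeatureVector:
    """A texture descriptor for one ROI."""

    values: np.ndarray
    mode: str
    n_neighbors: int
    radius: float
    normalized: bool

    def __len__(self) -> int:
        return self.values.size


def _assemble(maps: CodeMaps, mode: str) -> np.ndarray:
    p = maps.config.n_neighbors
    n_riu2 = p + 2
    if mode == "joint":
        idx = (maps.sglld * n_riu2 + maps.mglld) * 2 + maps.cglld
        return code_histogram(idx, n_riu2 * n_riu2 * 2)
    if mode == "concat":
        return np.concatenate(
            [
                code_histogram(maps.sglld, n_riu2),
                code_histogram(maps.mglld, n_riu2),
                code_histogram(maps.cglld, 2),
            ]
        )
    raise ValueError(f"unknown mode {mode!r}; use 'joint' or 'concat'")


def glld_feature(
    image: GrayImage | np.ndarray,
    config: NeighborhoodConfig | None = None,
    mode: str = "joint",
    normalize: bool = True,
) -> FeatureVector:
    """GLLD texture descriptor of one ROI under riu2 coding.

    Parameters
    ----------
    image
        Grayscale ROI (2-D raster or :class:`GrayImage`).
    config
        Neighborhood; defaults to the (24, 3) operating point.
    mode
        ``"joint"`` for the flattened 3-D joint histogram (default) or
        ``"concat"`` for concatenated marginal histograms.
    normalize
        If true (default), L1-normalize so the vector sums to 1.
    """
    if config is None:
        config = NeighborhoodConfig()
    maps = compute_code_maps(image, config, mapping="riu2")
    hist = _assemble(maps, mode).astype(np.float64)
    if normalize:
        total = hist.sum()
        if total > 0:
            hist = hist / total
    return FeatureVector(
        values=hist,
        mode=mode,
        n_neighbors=config.n_neighbors,
        radius=config.radius,
        normalized=normalize,
    )


def extract_features(
    images,
    config: NeighborhoodConfig | None = None,
    mode: str = "joint",
    normalize: bool = True,
) -> np.ndarray:
    """Stack GLLD descriptors of many ROIs into an (n, d) feature matrix."""
    rows = [glld_feature(im, config, mode, normalize).values for im in images]
    return np.vstack(rows)
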