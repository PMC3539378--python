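"""Texture coders: LBP baseline and the GLLD sign/modulus/center codes.

The classical local binary pattern (LBP) thresholds each circular neighbor
against the raw center pixel and packs the resulting bits into an integer
code.  Because it encodes only gray-level *differences*, two regions with
identical local structure but different absolute brightness produce the
same LBP histogram — a real limitation for breast tissue, where absolute
gray level tracks tissue density.

The GLLD (gray level and local difference) family repairs this by coding
three complementary quantities per pixel, each against the 3x3-mean-filtered
center value ``gc_mean``:

* **SGLLD** — the *signs* of the neighbor differences ``g_p - gc_mean``
  (the structural component, analogous to LBP);
* **MGLLD** — the difference *moduli* thresholded at the mean modulus of
  the whole ROI (the contrast component);
* **CGLLD** — a single bit saying whether ``gc_mean`` lies above the mean
  gray level of the whole ROI (the absolute-brightness component).

Each multi-bit code is reduced with the rotation-invariant uniform (riu2)
mapping: patterns with at most two 0/1 transitions around the circle keep
their popcount (P+1 possible values), all others collapse into a single
miscellaneous code ``P+1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .image import GrayImage, as_pixels
from .neighborhood import NeighborhoodConfig, sample_neighbor_stack

__all__ = [
    "LocalDifference",
    "CodeMaps",
    "lbp_code",
    "uniformity",
    "riu2_code",
    "center_mean",
    "decompose",
    "sglld_code",
    "mglld_threshold",
    "mglld_code",
    "cglld_code",
    "compute_code_maps",
]


# ---------------------------------------------------------------------------
# scalar coders (one pixel at a time)


def lbp_code(g_c: float, neighbors: np.ndarray) -> int:
    """LBP code: bit p is set iff neighbor p is >= the center value."""
    bits = np.asarray(neighbors, dtype=np.float64) >= g_c
    return int(np.sum(bits * (1 << np.arange(bits.size, dtype=np.int64))))


def uniformity(bits: np.ndarray) -> int:
    """Number of 0<->1 transitions around the circular pattern (wrap included)."""
    b = np.asarray(bits).astype(np.int64)
    return int(np.sum(np.abs(b - np.roll(b, 1))))


def riu2_code(bits: np.ndarray) -> int:
    """Rotation-invariant uniform code of a circular bit pattern.

    Popcount if the pattern has at most two transitions, else the
    miscellaneous label P+1; the codomain therefore has exactly P+2 values.
    """
    b = np.asarray(bits).astype(np.int64)
    if uniformity(b) <= 2:
        return int(b.sum())
    return b.size + 1


def sglld_code(signs: np.ndarray) -> int:
    """Sign code: bit p set iff the p-th difference sign is +1.

    Signs are +/-1; the -1 branch contributes a zero bit so the code is an
    ordinary non-negative binary word suitable for histogramming.
    """
    s = np.asarray(signs)
    bits = s >= 0
    return int(np.sum(bits * (1 << np.arange(bits.size, dtype=np.int64))))


def mglld_code(moduli: np.ndarray, c: float) -> int:
    """Modulus code: bit p set iff modulus p is >= the global threshold c."""
    m = np.asarray(moduli, dtype=np.float64)
    bits = m >= c
    return int(np.sum(bits * (1 << np.arange(bits.size, dtype=np.int64))))


def cglld_code(gc_mean: float, c_image: float) -> int:
    """Center code: 1 iff the mean-filtered center is >= the ROI mean level."""
    return int(gc_mean >= c_image)


# ---------------------------------------------------------------------------
# raster operators


def center_mean(image: GrayImage | np.ndarray) -> np.ndarray:
    """3x3 neighborhood mean attributed to the central pixel.

    Every interior pixel becomes the arithmetic mean of its 9-pixel window
    (center included).  The returned raster has the input shape; border
    values use edge replication and are never consumed by the coders,
    which restrict themselves to the valid interior.
    """
    pixels = as_pixels(image)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError(f"image {pixels.shape} smaller than the 3x3 mean window")
    return ndimage.uniform_filter(pixels, size=3, mode="nearest")


@dataclass
class LocalDifference:
    """Per-pixel local differences against the mean-filtered center.

    ``diffs``, ``signs`` and ``moduli`` have shape ``(P, H_v, W_v)`` over
    the valid region; ``gc_mean`` has shape ``(H_v, W_v)``.  The identity
    ``diffs = moduli * signs`` holds exactly, with sign +1 on ties.
    """

    gc_mean: np.ndarray
    diffs: np.ndarray
    signs: np.ndarray
    moduli: np.ndarray
    valid: tuple[slice, slice]
    config: NeighborhoodConfig


def decompose(
    image: GrayImage | np.ndarray, config: NeighborhoodConfig
) -> LocalDifference:
    """Sample neighbors, subtract ``gc_mean``, split into sign and modulus."""
    pixels = as_pixels(image)
    stack, valid = sample_neighbor_stack(pixels, config)
    gc = center_mean(pixels)[valid]
    diffs = stack - gc[None, :, :]
    signs = np.where(diffs >= 0, 1, -1).astype(np.int8)
    moduli = np.abs(diffs)
    return LocalDifference(gc, diffs, signs, moduli, valid, config)


def mglld_threshold(moduli: np.ndarray) -> float:
    """Adaptive modulus threshold: mean of all moduli over the whole ROI."""
    m = np.asarray(moduli, dtype=np.float64)
    if m.size == 0:
        raise ValueError("empty valid region: no moduli to average")
    return float(m.mean())


def _pack_codes(bits: np.ndarray) -> np.ndarray:
    """Pack a (P, H, W) bit stack into integer codes (bit p has weight 2^p)."""
    weights = (1 << np.arange(bits.shape[0], dtype=np.int64))[:, None, None]
    return np.sum(bits.astype(np.int64) * weights, axis=0)


def _riu2_map(bits: np.ndarray) -> np.ndarray:
    """riu2-map a (P, H, W) bit stack to a (H, W) code raster."""
    b = bits.astype(np.int8)
    transitions = np.sum(np.abs(b - np.roll(b, 1, axis=0)), axis=0)
    popcount = np.sum(b, axis=0)
    return np.where(transitions <= 2, popcount, bits.shape[0] + 1).astype(np.int64)


@dataclass
class CodeMaps:
    """Per-pixel code rasters for one ROI, all over the same valid region."""

    sglld: np.ndarray
    mglld: np.ndarray
    cglld: np.ndarray
    lbp: Optional[np.ndarray]
    mapping: str
    valid: tuple[slice, slice]
    config: NeighborhoodConfig
    modulus_threshold: float
    level_threshold: float


def compute_code_maps(
    image: GrayImage | np.ndarray,
    config: NeighborhoodConfig,
    mapping: str = "riu2",
    include_lbp: bool = False,
) -> CodeMaps:
    """All GLLD code rasters (and optionally the LBP baseline) for one ROI.

    ``mapping`` is either ``"riu2"`` (default; codes in [0, P+1]) or
    ``"raw"`` (full 2^P binary words).  Thresholds are computed per-ROI:
    the modulus threshold is the mean modulus over the whole valid region,
    the center-level threshold is the mean gray level of the whole input.
    """
    if mapping not in ("riu2", "raw"):
        raise ValueError(f"unknown mapping {mapping!r}; use 'riu2' or 'raw'")
    pixels = as_pixels(image)
    ld = decompose(pixels, config)

    sign_bits = ld.signs >= 0
    c_mod = mglld_threshold(ld.moduli)
    mod_bits = ld.moduli >= c_mod
    c_level = float(pixels.mean())
    cglld = (ld.gc_mean >= c_level).astype(np.int64)

    if mapping == "riu2":
        sglld = _riu2_map(sign_bits)
        mglld = _riu2_map(mod_bits)
    else:
        sglld = _pack_codes(sign_bits)
        mglld = _pack_codes(mod_bits)

    lbp = None
    if include_lbp:
        stack, valid = sample_neighbor_stack(pixels, config)
        center = pixels[valid]
        lbp_bits = stack >= center[None, :, :]
        lbp = _riu2_map(lbp_bits) if mapping == "riu2" else _pack_codes(lbp_bits)

    return CodeMaps(
        sglld=sglld,
        mglld=mglld,
        cglld=cglld,
        lbp=lbp,
        mapping=mapping,
        valid=ld.valid,
        config=config,
        modulus_threshold=c_mod,
        level_threshold=c_level,
    )
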