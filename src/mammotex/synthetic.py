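"""Seeded generator of mammogram-like mass and mass-free ROIs.

Real screening data cannot be redistributed, so every stage of the
pipeline is exercised on synthetic regions of interest that emulate the
statistics the texture operator must detect: a smoothly varying
parenchyma-like background (low-pass-filtered Gaussian noise) and, for the
positive class, a centered, edge-blurred, elliptical bright blob whose
area falls inside one of six clinical mass-size classes:

====== ================
class  area (mm^2)
====== ================
1      < 10
2      [10, 60)
3      [60, 120)
4      [120, 190)
5      [190, 270)
6      >= 270
====== ================

The blob is a Gaussian-profiled ellipse with random eccentricity in
[1, 2] and random orientation; its reported area is the pixel count of
the half-amplitude level set times ``mm_per_pixel**2``.  No attempt is
made at photorealism (no spiculation, no microcalcifications): the
generator targets only the gray-level contrast statistics that separate
mass from mass-free tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "SIZE_CLASS_BOUNDS",
    "SynthConfig",
    "ROIDataset",
    "generate_background",
    "generate_mass_roi",
    "generate_dataset",
]

# half-open area intervals in mm^2, per size class
SIZE_CLASS_BOUNDS: dict[int, tuple[float, float]] = {
    1: (0.0, 10.0),
    2: (10.0, 60.0),
    3: (60.0, 120.0),
    4: (120.0, 190.0),
    5: (190.0, 270.0),
    6: (270.0, math.inf),
}

_HALF_MAX = math.sqrt(2.0 * math.log(2.0))  # half-amplitude radius in sigma units


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic ROI.

    Parameters
    ----------
    roi_pixels
        Side of the square ROI in pixels.  128 px at 0.2 mm/px gives a
        25.6 mm field of view, enough for all feasible size classes.
    mm_per_pixel
        Spatial sampling; 0.2 mm/px so classes 1-5 (and moderate class-6
        masses) fit the default ROI.
    background_sigma
        Gaussian blur applied to white noise; controls parenchyma
        smoothness (larger -> smoother, lower variance).
    background_amplitude
        Gray-level gain applied to the unblurred unit-variance noise.
    contrast
        Mass amplitude as a multiple of the realized background standard
        deviation; 3.0 gives a clearly visible lesion.
    size_class
        Mass-size class 1-6 (see module docstring).
    max_level
        Maximum gray level K of the output image.
    """

    roi_pixels: int = 128
    mm_per_pixel: float = 0.2
    background_sigma: float = 4.0
    background_amplitude: float = 60.0
    contrast: float = 3.0
    size_class: int = 3
    max_level: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_pixels < 16:
            raise ValueError("ROI must be at least 16 pixels on a side")
        if self.size_class not in SIZE_CLASS_BOUNDS:
            raise ValueError(f"size class must be 1..6, got {self.size_class}")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


def generate_background(config: SynthConfig, seed: int | None = None) -> GrayImage:
    """Mass-free tissue background: low-pass-filtered Gaussian noise.

    The field is centered at K/2 with standard deviation shrinking as the
    blur widens; values are clipped to [0, K].  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.roi_pixels
    noise = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(noise, sigma=config.background_sigma)
    k = config.max_level
    pixels = np.clip(k / 2.0 + config.background_amplitude * smooth, 0, k)
    return GrayImage(pixels, max_level=k)


def _blob_geometry(config: SynthConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    """Sample half-amplitude semi-axes (pixels) and orientation for the mass.

    Raises if the requested size class cannot fit inside the ROI.
    """
    lo, hi = SIZE_CLASS_BOUNDS[config.size_class]
    mm = config.mm_per_pixel
    # the half-amplitude ellipse must fit with a 2-pixel margin
    a_max_mm = (config.roi_pixels / 2.0 - 2.0) * mm
    if a_max_mm <= 0:
        raise ValueError("ROI too small for any mass")
    ecc = rng.uniform(1.0, 2.0)
    # area = pi * a * b with a = ecc * b  =>  a = sqrt(area * ecc / pi)
    max_area_for_ecc = math.pi * a_max_mm**2 / ecc
    if max_area_for_ecc <= lo:
        # try the roundest shape before giving up
        ecc = 1.0
        max_area_for_ecc = math.pi * a_max_mm**2
        if max_area_for_ecc <= lo:
            raise ValueError(
                f"size class {config.size_class} (>= {lo} mm^2) does not fit a "
                f"{config.roi_pixels}-px ROI at {mm} mm/px "
                f"(max representable area {max_area_for_ecc:.0f} mm^2)"
            )
    hi_eff = min(hi, max_area_for_ecc)
    lo_eff = max(lo, 2.5)  # keep the lesion supra-pixel
    if lo_eff >= hi_eff:
        raise ValueError(
            f"size class {config.size_class} not representable in this ROI"
        )
    # draw away from the interval edges so discretization stays in-class
    span = hi_eff - lo_eff
    area = rng.uniform(lo_eff + 0.08 * span, hi_eff - 0.08 * span)
    a_mm = math.sqrt(area * ecc / math.pi)
    b_mm = a_mm / ecc
    theta = rng.uniform(0.0, math.pi)
    return a_mm / mm, b_mm / mm, theta


def generate_mass_roi(
    config: SynthConfig, seed: int | None = None
) -> tuple[GrayImage, float]:
    """Background plus a centered Gaussian-profiled elliptical mass.

    Returns the ROI and the realized mass area in mm^2 (pixel count of the
    half-amplitude level set of the blob).  The blob amplitude is
    ``contrast`` times the realized background standard deviation, so the
    lesion interior is brighter than the surrounding tissue.
    """
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    bg = generate_background(config, seed=use_seed)
    bg_std = float(bg.pixels.std())
    a_px, b_px, theta = _blob_geometry(config, rng)

    n = config.roi_pixels
    center = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    dr = rr - center
    dc = cc - center
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    sig_a = a_px / _HALF_MAX
    sig_b = b_px / _HALF_MAX
    profile = np.exp(-0.5 * ((u / sig_a) ** 2 + (v / sig_b) ** 2))

    amplitude = config.contrast * bg_std
    blob = amplitude * profile
    pixels = np.clip(bg.pixels + blob, 0, config.max_level)

    mask = blob >= amplitude / 2.0
    area_mm2 = float(mask.sum()) * config.mm_per_pixel**2
    return GrayImage(pixels, max_level=config.max_level), area_mm2


@dataclass
class ROIDataset:
    """Labeled collection of synthetic ROIs (label 1 = mass, 0 = mass-free)."""

    images: list[GrayImage]
    labels: np.ndarray
    ids: list[str]
    mass_areas: np.ndarray  # NaN for mass-free samples
    config: SynthConfig
    seed: int
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)


def generate_dataset(
    n_mass: int,
    n_normal: int,
    config: SynthConfig | None = None,
    seed: int = 0,
) -> ROIDataset:
    """Balanced labeled dataset of mass and mass-free ROIs.

    Per-sample seeds are spawned deterministically from the master seed,
    so the dataset is byte-identical across runs.
    """
    if n_mass < 1 or n_normal < 1:
        raise ValueError("need at least one sample per class")
    if config is None:
        config = SynthConfig()
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_mass + n_normal)]

    images: list[GrayImage] = []
    labels = np.concatenate([np.ones(n_mass, dtype=np.int64), np.zeros(n_normal, dtype=np.int64)])
    ids: list[str] = []
    areas = np.full(n_mass + n_normal, np.nan)
    for i in range(n_mass):
        img, area = generate_mass_roi(replace(config, seed=child_seeds[i]))
        images.append(img)
        areas[i] = area
        ids.append(f"mass_{i:04d}")
    for j in range(n_normal):
        img = generate_background(replace(config, seed=child_seeds[n_mass + j]))
        images.append(img)
        ids.append(f"normal_{j:04d}")
    return ROIDataset(images, labels, ids, areas, config, seed)
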