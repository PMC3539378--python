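"""Image and tabular I/O: reading ROIs, writing features, models, results.

Conventions used everywhere: pixel coordinates are 0-based and row-major;
crop rectangles are half-open intervals.  The maximum gray level K is
taken from the bit depth of the source file (255 for 8-bit, 65535 for
16-bit), never from the realized maximum.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FeatureVector
from .image import GrayImage

__all__ = [
    "read_image",
    "write_image",
    "crop_roi",
    "features_to_csv",
    "features_from_csv",
    "save_model",
    "load_model",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit grayscale image (PNG, PGM, TIFF).

    Color inputs are converted to luminance (ITU-R 601 weights) with a
    warning.  16-bit depth is preserved; K is set from the dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"cannot interpret {path} with shape {arr.shape}")
        warnings.warn(
            f"{path.name}: color image converted to luminance", stacklevel=2
        )
        arr = arr.astype(np.float64) @ _LUMA
        max_level = 255 if arr.max() <= 255 else 65535
        return GrayImage(arr, max_level=max_level)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} with shape {arr.shape}")
    if arr.dtype == np.uint8:
        max_level = 255
    elif arr.dtype == np.uint16:
        max_level = 65535
    elif np.issubdtype(arr.dtype, np.integer):
        max_level = int(max(255, 2 ** int(np.ceil(np.log2(arr.max() + 1))) - 1))
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return GrayImage(arr, max_level=max_level)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a grayscale image; 16-bit PNG/TIFF when K > 255."""
    path = Path(path)
    if image.max_level <= 255:
        arr = np.clip(np.round(image.pixels), 0, 255).astype(np.uint8)
    else:
        arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(path, arr)


def crop_roi(
    image: GrayImage, row0: int, col0: int, height: int, width: int
) -> GrayImage:
    """Exact sub-raster copy; 0-based, half-open intervals."""
    return image.crop(row0, col0, height, width)


def features_to_csv(
    path: str | Path,
    ids: list[str],
    labels: np.ndarray,
    vectors: list[FeatureVector] | np.ndarray,
    mode: str | None = None,
    n_neighbors: int | None = None,
    radius: float | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write one row per ROI: id, label, mode, P, R, then feature values.

    A JSON sidecar (same stem, ``.json``) records the configuration.
    """
    path = Path(path)
    if isinstance(vectors, np.ndarray):
        matrix = vectors
        if mode is None or n_neighbors is None or radius is None:
            raise ValueError("mode, n_neighbors and radius required with a raw matrix")
    else:
        matrix = np.vstack([fv.values for fv in vectors])
        mode = vectors[0].mode
        n_neighbors = vectors[0].n_neighbors
        radius = vectors[0].radius
    d = matrix.shape[1]
    frame = pd.DataFrame(matrix, columns=[f"f{i}" for i in range(d)])
    frame.insert(0, "R", radius)
    frame.insert(0, "P", n_neighbors)
    frame.insert(0, "mode", mode)
    frame.insert(0, "label", np.asarray(labels).astype(int))
    frame.insert(0, "id", ids)
    frame.to_csv(path, index=False)
    meta = {"mode": mode, "P": n_neighbors, "R": radius, "dims": d, "n": len(ids)}
    meta["versions"] = _library_versions()
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def features_from_csv(path: str | Path):
    """Read a feature CSV back as (ids, labels, matrix, meta)."""
    frame = pd.read_csv(path)
    ids = frame["id"].astype(str).tolist()
    labels = frame["label"].to_numpy(dtype=np.int64)
    meta = {
        "mode": frame["mode"].iloc[0],
        "P": int(frame["P"].iloc[0]),
        "R": float(frame["R"].iloc[0]),
    }
    matrix = frame[[c for c in frame.columns if c.startswith("f")]].to_numpy(
        dtype=np.float64
    )
    return ids, labels, matrix, meta


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted classifier to JSON."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path):
    """Rebuild a classifier from its JSON form."""
    from .classifiers import model_from_dict

    return model_from_dict(json.loads(Path(path).read_text()))


def _library_versions() -> dict:
    import numpy
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
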