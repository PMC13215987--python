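"""Image and mask I/O with a fixed coordinate convention.

Everything in this package uses (row, col) indexing, 0-based, origin at the
top-left — including centroids and the image center.  Images are held in
memory as float64 arrays normalized to [0, 1]; binary masks as uint8 arrays
over {0, 1}.

Masks round-trip losslessly; 8-bit grayscale images round-trip losslessly up
to the 1/255 quantization of the file format.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

# ITU-R BT.709 luminance weights, used to collapse RGB input.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


class ImageReadError(IOError):
    """Raised when a raster cannot be read or has an unsupported layout."""


def _load_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.is_file():
        raise ImageReadError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except ImageReadError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize to the I/O contract
        raise ImageReadError(f"cannot read raster {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageReadError(f"zero-sized image: {path}")
    return arr


def _to_gray(arr: np.ndarray, path: str | Path) -> np.ndarray:
    """Collapse channels and rescale to float64 in [0, 1]."""
    was_integer = np.issubdtype(arr.dtype, np.integer)
    sixteen_bit = was_integer and arr.dtype.itemsize > 1
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ImageReadError(
                f"unsupported channel layout {arr.shape} in {path}"
            )
        warnings.warn(
            f"multi-channel image {path} collapsed to luminance "
            "(BT.709 weights)",
            stacklevel=3,
        )
        arr = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ImageReadError(f"expected a 2-D raster, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if was_integer:
        return arr / (65535.0 if sixteen_bit else 255.0)
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale slice as float64 in [0, 1], shape (rows, cols).

    RGB input is accepted and collapsed to luminance with a warning; 16-bit
    data is rescaled by 65535, 8-bit by 255.
    """
    arr = _load_raster(path)
    gray = _to_gray(arr, path)
    if not np.all(np.isfinite(gray)):
        raise ImageReadError(f"non-finite pixel values in {path}")
    return gray


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as an 8-bit single-channel TIFF/PNG."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got {img.shape}")
    data = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        Image.fromarray(data, mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any single positive level maps to 1."""
    arr = _load_raster(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    levels = np.unique(arr)
    positive = levels[levels > 0]
    if positive.size > 1:
        raise ValueError(
            f"mask {path} has more than two levels: {levels.tolist()}"
        )
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit raster with levels {0, 255}."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    data = (mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        Image.fromarray(data, mode="L").save(path)
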