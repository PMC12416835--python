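"""Reading and writing microscopy images and instance label masks.

Conventions used throughout the package:

* arrays are row-major, origin top-left, 0-based indices;
* an :class:`Image` holds real-valued intensities exactly as stored on disk
  (no range rescaling); multi-channel inputs are reduced to a single channel
  with an unweighted channel mean, because microscopy channels are not
  photometric RGB;
* a :class:`LabelMask` is a 2D non-negative integer map, 0 = background and
  every positive integer one cell; labels need not be contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


class FormatError(ValueError):
    """Unreadable file or a pixel type the format contract forbids."""


class UnsupportedShapeError(ValueError):
    """More than 3 channels or more than 2 spatial dimensions."""


@dataclass(frozen=True)
class Image:
    """A single-channel real-valued image."""

    pixels: np.ndarray  # 2D float64
    source_dtype: str = "float64"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise UnsupportedShapeError(f"expected a 2D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LabelMask:
    """An instance label map; 0 = background, each positive label one cell."""

    labels: np.ndarray  # 2D integer

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise FormatError(f"labels must be integer-typed, got {lab.dtype}")
        if lab.ndim != 2:
            raise UnsupportedShapeError(f"expected a 2D label mask, got shape {lab.shape}")
        if lab.size and lab.min() < 0:
            raise FormatError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def cell_labels(self) -> np.ndarray:
        """Sorted unique positive labels."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.size)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Reduce an (H, W[, C]) array to (H, W) by unweighted channel mean.

    Idempotent on single-channel input.
    """
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0]
        if arr.shape[2] in (3, 4):
            # alpha, if present, is not intensity
            return arr[:, :, :3].mean(axis=2)
        raise UnsupportedShapeError(f"unsupported channel count {arr.shape[2]}")
    raise UnsupportedShapeError(f"unsupported array shape {arr.shape}")


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"cannot read {path}: {exc}") from exc


def load_image(path: str | Path) -> Image:
    """Load a TIFF/PNG image, reducing channels to one; no range rescale."""
    path = Path(path)
    arr = _read_array(path)
    if arr.ndim > 3:
        raise UnsupportedShapeError(f"{path}: more than 2 spatial dims ({arr.shape})")
    gray = to_grayscale(arr)
    return Image(pixels=np.asarray(gray, dtype=np.float64), source_dtype=str(arr.dtype))


def load_labels(path: str | Path) -> LabelMask:
    """Load an instance label mask; values are preserved exactly."""
    path = Path(path)
    arr = _read_array(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: label masks must be integer-typed (got {arr.dtype}); "
            "labels must be exact"
        )
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise UnsupportedShapeError(f"{path}: label mask must be single-channel 2D")
    return LabelMask(labels=arr)


def save_labels(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as single-channel TIFF/PNG.

    16-bit when the maximum label fits, otherwise 32-bit TIFF; the round
    trip through :func:`load_labels` is the pixelwise identity.
    """
    path = Path(path)
    lab = mask.labels
    maxlab = int(lab.max()) if lab.size else 0
    if maxlab <= np.iinfo(np.uint16).max:
        out = lab.astype(np.uint16)
    else:
        out = lab.astype(np.int32)
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise FormatError(">16-bit labels require TIFF output")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def save_image(img: Image | np.ndarray, path: str | Path) -> None:
    """Write a single-channel image; float data goes to float32 TIFF."""
    path = Path(path)
    arr = img.pixels if isinstance(img, Image) else np.asarray(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(arr, 0, 255).astype(np.uint8))
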