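"""Grayscale image input/output and validation.

Throughout the package an "image" is a 2-D :class:`numpy.ndarray` of
``float64`` intensities in the nominal range [0, 1], addressed row-major
(pixel ``(i, j)`` is row *i*, column *j*).  This module is the only place
that touches files; every other module consumes and produces these arrays.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ShapeError",
    "as_image",
    "read_image",
    "write_image",
    "check_compatible",
]


class ShapeError(ValueError):
    """Raised when image dimensions are invalid or incompatible."""


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array into the internal image representation.

    Parameters
    ----------
    pixels
        2-D array-like of intensities.

    Returns
    -------
    numpy.ndarray
        ``float64`` 2-D array.  Raises :class:`ShapeError` if the array is
        not 2-D with both dimensions >= 2, or ``ValueError`` if any value
        is non-finite.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"image must be 2-D, got {arr.ndim}-D array")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ShapeError(f"image must be at least 2x2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8/16-bit grayscale (or RGB) PNG/TIFF as a [0, 1] float image.

    Integer samples are scaled linearly by the dtype maximum (255 or
    65535).  RGB(A) inputs are collapsed to one channel by the unweighted
    mean of the color channels; an alpha channel, if present, is dropped.
    Floating-point files are taken as already being on [0, 1].
    """
    raw = iio.imread(path)
    scale = (
        float(np.iinfo(raw.dtype).max)
        if np.issubdtype(raw.dtype, np.integer)
        else 1.0
    )
    if raw.ndim == 3:
        # drop alpha, average color channels
        if raw.shape[2] == 4:
            raw = raw[:, :, :3]
        raw = raw.mean(axis=2)
    if raw.size == 0:
        raise ShapeError(f"zero-area image: {path}")
    return as_image(raw.astype(np.float64) / scale)


def write_image(img: np.ndarray, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write an image as 8- or 16-bit grayscale PNG/TIFF.

    Intensities are clipped to [0, 1], scaled by ``2**bit_depth - 1`` and
    rounded half away from zero, so a write/read round trip reproduces the
    image within one quantization step.
    """
    img = as_image(img)
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    maxval = 2**bit_depth - 1
    quantized = np.floor(np.clip(img, 0.0, 1.0) * maxval + 0.5)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(path, quantized.astype(dtype))


def check_compatible(images: list[np.ndarray]) -> None:
    """Raise :class:`ShapeError` unless all images share one shape."""
    if not images:
        raise ValueError("empty image list")
    first = np.shape(images[0])
    for other in images[1:]:
        if np.shape(other) != first:
            raise ShapeError(
                f"incompatible image shapes: {first} vs {np.shape(other)}"
            )
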