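"""Image reading and writing at the package boundary.

The canonical internal representation is a 2-D uint8 array (8-bit gray,
256 levels).  Other raster depths are converted on the way in: 16-bit
images are rescaled to 8 bits with round-half-up, RGB images are rejected
unless luminance conversion is requested.  Binary masks are written as
{0, 255} 8-bit PNG/TIFF and read back with a >127 cut.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray_image", "read_mask", "write_gray_image", "write_mask"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray_image(path: str | Path, to_gray: bool = False) -> np.ndarray:
    """Read a raster file as a 2-D uint8 gray image.

    16-bit inputs are rescaled by 255/65535 and rounded half-up; colour
    inputs raise unless ``to_gray`` is set, in which case the Rec. 601
    luminance is used.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
        if not to_gray:
            raise ValueError(
                f"{path} is a colour image; pass to_gray=True (--to-gray) to convert"
            )
        arr = arr[:, :, :3] @ _LUMA
        return np.floor(arr + 0.5).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a 2-D raster")
    if arr.dtype == np.uint8:
        return arr.copy()
    if arr.dtype == np.uint16:
        return np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5).astype(
            np.uint8
        )
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    if np.issubdtype(arr.dtype, np.integer):
        lo, hi = int(arr.min()), int(arr.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"{path}: integer values outside [0, 255]")
        return arr.astype(np.uint8)
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a stored mask back to {0, 1} via a >127 cut."""
    return (read_gray_image(path) > 127).astype(np.uint8)


def write_gray_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D uint8 image as PNG/TIFF (by file extension)."""
    image = np.asarray(image)
    if image.ndim != 2 or image.dtype != np.uint8:
        raise ValueError("expected a 2-D uint8 image")
    iio.imwrite(Path(path), image)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit image with values {0, 255}."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (values 0/1)")
    iio.imwrite(Path(path), (mask.astype(np.uint8)) * 255)
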