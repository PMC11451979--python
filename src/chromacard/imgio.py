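"""Reading and writing card photographs (PNG/TIFF, 8- or 16-bit)."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .colorspace import Encoding, ImageF32, WhitePoint

__all__ = ["read_image", "write_image"]


def read_image(
    path: str | os.PathLike,
    encoding: Encoding = Encoding.SRGB_ENCODED,
    white_point: WhitePoint = WhitePoint.D50,
) -> ImageF32:
    """Load an RGB PNG/TIFF into an :class:`ImageF32`.

    8-bit images are scaled by 1/255 and 16-bit by 1/65535; an alpha
    channel, if present, is dropped. The caller states the encoding tag
    (camera exports are sRGB-encoded unless known otherwise).
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float32) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(np.float32)
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype}")
    return ImageF32(pixels, encoding, white_point)


def write_image(path: str | os.PathLike, img: ImageF32, bit_depth: int = 8) -> None:
    """Write an sRGB-encoded image as 8-bit PNG/TIFF or 16-bit TIFF.

    16-bit RGB requires the TIFF container (the PNG backend only handles
    8-bit RGB).
    """
    img.require(Encoding.SRGB_ENCODED)
    pixels = np.clip(img.pixels, 0.0, 1.0)
    suffix = str(path).lower().rsplit(".", 1)[-1]
    if bit_depth == 8:
        out = np.round(pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if suffix not in ("tif", "tiff"):
            raise ValueError("16-bit RGB output requires a .tif/.tiff path")
        out = np.round(pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, out)
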