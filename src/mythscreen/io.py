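"""Image and table I/O: 16-bit grayscale TIFF/PNG plates, multi-page stacks."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import tifffile

PathLike = Union[str, Path]


def read_image(path: PathLike) -> np.ndarray:
    """Read an 8/16-bit grayscale plate image (TIFF or PNG) as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A): average to gray
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def write_image(path: PathLike, image: np.ndarray) -> None:
    """Write a 2-D image as 16-bit grayscale TIFF (values clipped to range)."""
    arr = np.clip(np.asarray(image), 0, 65535).round().astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def read_stack(path: PathLike) -> np.ndarray:
    """Read a multi-page TIFF z-stack as a float64 (z, y, x) array."""
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr.astype(float)


def write_stack(path: PathLike, stack: np.ndarray) -> None:
    """Write a (z, y, x) stack as a multi-page 16-bit TIFF."""
    arr = np.clip(np.asarray(stack), 0, 65535).round().astype(np.uint16)
    tifffile.imwrite(Path(path), arr)
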