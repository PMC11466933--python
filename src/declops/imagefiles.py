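"""TIFF and PNG readers/writers for the CLI.

TIFF carries 2-D or 3-D data (multi-page maps to the leading planar axis);
PNG carries 2-D uint8 only.  Grids are written in the declared axis order
(slowest to fastest, 0-based).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ParameterError
from .images import DenseImage


def read_image(path: str | Path) -> DenseImage:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) to grayscale by averaging
            arr = np.clip(np.floor(arr[..., :3].mean(axis=-1) + 0.5),
                          0, 255).astype(np.uint8)
    else:
        raise ParameterError(f"unsupported image format {suffix!r} for {path}")
    if arr.dtype == np.uint8:
        return DenseImage(arr)
    return DenseImage(arr.astype(np.float64))


def write_image(path: str | Path, image: DenseImage) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values)
    elif suffix == ".png":
        arr = image.values
        if arr.ndim != 2:
            raise ParameterError("PNG output requires a 2-D image")
        if arr.dtype != np.uint8:
            arr = np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)
        iio.imwrite(path, arr)
    else:
        raise ParameterError(f"unsupported image format {suffix!r} for {path}")
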