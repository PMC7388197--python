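"""Reading and writing single 2D raster planes.

Planes are greyscale TIFF or PNG files holding one unsigned 8- or 16-bit
image each.  TIFF goes through :mod:`tifffile`, PNG through
:mod:`imageio`; both round-trip uint8 and uint16 exactly.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

#: Extensions (lower-case, with dot) accepted as plane images.
SUPPORTED_EXTENSIONS = {".tif", ".tiff", ".png"}


def read_plane(path: Path | str) -> np.ndarray:
    """Read one 2D plane; returns a 2D array with the stored dtype."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ValueError(f"unsupported plane format {ext!r}: {path}")
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(f"expected a single 2D greyscale plane, got shape {data.shape}: {path}")
    return data


def write_plane(path: Path | str, data: np.ndarray) -> None:
    """Write one 2D plane; format chosen from the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ValueError(f"unsupported plane format {ext!r}: {path}")
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(f"plane must be 2D, got shape {data.shape}")
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        iio.imwrite(path, data)
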