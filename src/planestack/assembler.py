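"""Materialise 5D hypercubes from validated plane indexes.

One microscope position becomes one five-dimensional image with axes
ordered (T, C, Z, Y, X) in memory.  The deposition sink converts this
canonical order to the declared OME dimension order on write, so no
silent transposition can occur between assembly and storage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import scanner
from .errors import CompletenessError, ShapeError
from .raster import read_plane

logger = logging.getLogger(__name__)

FillPolicy = Literal["error", "zero"]


@dataclass
class HyperCube:
    """A five-dimensional image for one stage position.

    ``pixels`` has axes (T, C, Z, Y, X); ``provenance`` maps each rank
    coordinate to the source plane file it was read from.
    """

    position_id: int
    pixels: np.ndarray
    channel_names: list[str]
    provenance: dict[tuple[int, int, int], Path] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixels.ndim != 5:
            raise ValueError(f"hypercube must have 5 axes, got {self.pixels.ndim}")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length must equal the C axis size")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.pixels.shape

    @property
    def pixel_type(self) -> np.dtype:
        return self.pixels.dtype


def assemble_cube(index: scanner.PlaneIndex, fill_policy: FillPolicy = "error") -> HyperCube:
    """Assemble one hypercube from a plane index.

    Every indexed file is read exactly once and placed at its rank
    coordinate.  All planes must agree in height, width and pixel type;
    mixed types are an error, never an implicit promotion.  Cells absent
    from the full T x C x Z grid abort under the default ``error``
    policy and become all-zero planes under ``zero`` — zero-fill is
    opt-in because fabricated planes corrupt quantitative measurements.
    """
    size_t, size_c, size_z = index.shape
    if not index.planes:
        raise CompletenessError(f"position {index.position_id}: no planes to assemble")

    missing = [(t, c, z)
               for t in range(size_t) for c in range(size_c) for z in range(size_z)
               if (t, c, z) not in index.planes]
    if missing and fill_policy == "error":
        raise CompletenessError(
            f"position {index.position_id}: {len(missing)} missing grid cell(s) "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}; "
            "use fill_policy='zero' to pad with blank planes",
            missing=missing)

    pixels: np.ndarray | None = None
    ref_coord: tuple[int, int, int] | None = None
    provenance: dict[tuple[int, int, int], Path] = {}
    for coord in sorted(index.planes):
        key = index.planes[coord]
        plane = read_plane(key.path)
        if pixels is None:
            pixels = np.zeros((size_t, size_c, size_z) + plane.shape, dtype=plane.dtype)
            ref_coord = coord
        elif plane.shape != pixels.shape[3:] or plane.dtype != pixels.dtype:
            ref = index.planes[ref_coord]
            raise ShapeError(
                f"position {index.position_id}: plane {key.path} has shape "
                f"{plane.shape} dtype {plane.dtype}, but {ref.path} has shape "
                f"{pixels.shape[3:]} dtype {pixels.dtype}")
        pixels[coord] = plane
        provenance[coord] = key.path

    return HyperCube(position_id=index.position_id, pixels=pixels,
                     channel_names=index.channel_names, provenance=provenance)


def process_image(sink, path: Path | str, dataset, fill_policy: FillPolicy = "error") -> list:
    """Default image-processor: one hypercube per position, via the broker.

    This is the replaceable half of the processing contract: any object
    with the same ``process_image(sink, path, dataset)`` signature can
    stand in for it at runtime.  Returns image references in ascending
    position order.
    """
    positions = scanner.scan_positions(path)
    if not positions:
        logger.warning("no position directories found under %s", path)
        return []
    refs = []
    for position_id, directory in positions:
        index, report = scanner.build_index(position_id, directory)
        for rejection in report.rejected:
            logger.warning("pos%03d: skipped %s (%s)", position_id,
                           rejection.name, rejection.reason)
        cube = assemble_cube(index, fill_policy=fill_policy)
        refs.append(sink.write_hypercube(dataset, cube))
    return refs


class DefaultImageProcessor:
    """Class form of the default processor, for plug-in substitution."""

    def __init__(self, fill_policy: FillPolicy = "error"):
        self.fill_policy = fill_policy

    def process_image(self, sink, path, dataset):
        return process_image(sink, path, dataset, fill_policy=self.fill_policy)
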