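"""Directory-tree scanning and plane-filename parsing.

A multi-position time-lapse acquisition is laid out as one sub-directory
per microscope stage position, named ``pos{xxx}`` where ``{xxx}`` is a
numeric identifier of any digit width.  Each position directory holds one
2D plane image per (timepoint, channel, z-section), named
``{prefix}_{timepoint}_{channel}_{z}`` plus a raster extension.  The
prefix may itself contain underscores, so filenames are tokenised from
the right: the last underscore-separated token is the z-section, the one
before it the channel, the one before that the timepoint, and everything
remaining is the prefix.

Tokens are mapped to dense 0-based rank coordinates by sorting the
distinct tokens seen in a position (numerically for timepoint and z;
channels numerically when every token parses as an integer, otherwise
lexicographically).  Ranks tolerate gaps and arbitrary origins in the
acquisition software's numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .raster import SUPPORTED_EXTENSIONS

_POSITION_RE = re.compile(r"pos(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class PlaneKey:
    """Parsed identity of one 2D plane file."""

    prefix: str
    timepoint: int
    channel: str
    z: int
    path: Path

    def __post_init__(self):
        if self.timepoint < 0 or self.z < 0:
            raise ValueError("timepoint and z tokens must be non-negative")
        if not self.channel:
            raise ValueError("channel token must be non-empty")


@dataclass(frozen=True)
class Rejection:
    """A filename that does not conform to the naming convention."""

    name: str
    reason: str


@dataclass
class PlaneIndex:
    """Per-position mapping from (t, c, z) rank coordinates to planes.

    ``planes`` maps 0-based rank triples to :class:`PlaneKey`; the rank
    dictionaries record how acquisition tokens were ordered.
    """

    position_id: int
    timepoint_ranks: dict[int, int] = field(default_factory=dict)
    channel_ranks: dict[str, int] = field(default_factory=dict)
    z_ranks: dict[int, int] = field(default_factory=dict)
    planes: dict[tuple[int, int, int], PlaneKey] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(SizeT, SizeC, SizeZ) extents."""
        return (len(self.timepoint_ranks), len(self.channel_ranks), len(self.z_ranks))

    @property
    def channel_names(self) -> list[str]:
        """Channel tokens in rank order; used to name OME channels."""
        return [c for c, _ in sorted(self.channel_ranks.items(), key=lambda kv: kv[1])]


@dataclass
class ValidationReport:
    """Completeness diagnosis of a plane index against its full grid."""

    missing: list[tuple[int, int, int]] = field(default_factory=list)
    duplicates: list[tuple[Path, Path]] = field(default_factory=list)
    rejected: list[Rejection] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return not self.missing and not self.duplicates


def parse_plane_filename(name: str, path: Path | None = None) -> Union[PlaneKey, Rejection]:
    """Parse a bare filename into a :class:`PlaneKey`, or reject it.

    Rejection is a value, not an exception: scans over mixed directories
    report non-conforming files rather than aborting.
    """
    p = Path(name)
    ext = p.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        return Rejection(name, f"unsupported extension {ext or '(none)'!r}")
    parts = p.stem.rsplit("_", 3)
    if len(parts) < 4:
        return Rejection(name, "fewer than 4 underscore-separated tokens")
    prefix, t_tok, c_tok, z_tok = parts
    try:
        timepoint = int(t_tok)
        z = int(z_tok)
    except ValueError:
        return Rejection(name, "timepoint and z tokens must be integers")
    if timepoint < 0 or z < 0:
        return Rejection(name, "timepoint and z tokens must be non-negative")
    if not c_tok:
        return Rejection(name, "empty channel token")
    return PlaneKey(prefix=prefix, timepoint=timepoint, channel=c_tok, z=z,
                    path=path if path is not None else Path(name))


def scan_positions(root: Path | str) -> list[tuple[int, Path]]:
    """Find position sub-directories under ``root``.

    Returns ``(position_id, directory)`` pairs for every immediate
    sub-directory named ``pos`` + digits (case-insensitive), ordered by
    ascending numeric id.  Everything else is ignored.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"data directory not found: {root}")
    found = []
    for entry in root.iterdir():
        if not entry.is_dir():
            continue
        m = _POSITION_RE.fullmatch(entry.name)
        if m:
            found.append((int(m.group(1)), entry))
    found.sort(key=lambda pair: pair[0])
    return found


def _sort_channels(tokens: set[str]) -> list[str]:
    # numeric ordering when every token is an integer, else lexicographic
    try:
        return sorted(tokens, key=lambda c: int(c))
    except ValueError:
        return sorted(tokens)


def index_planes(position_id: int, paths: Iterable[Path]) -> tuple[PlaneIndex, ValidationReport]:
    """Build a validated :class:`PlaneIndex` from an explicit file list.

    The result is independent of the iteration order of ``paths``:
    rank maps come from sorted distinct tokens and duplicate resolution
    keeps the lexicographically first path.
    """
    keys: list[PlaneKey] = []
    report = ValidationReport()
    for path in sorted(paths):
        if path.name.startswith("."):
            continue
        parsed = parse_plane_filename(path.name, path=path)
        if isinstance(parsed, Rejection):
            report.rejected.append(parsed)
        else:
            keys.append(parsed)

    index = PlaneIndex(position_id=position_id)
    t_tokens = sorted({k.timepoint for k in keys})
    z_tokens = sorted({k.z for k in keys})
    c_tokens = _sort_channels({k.channel for k in keys})
    index.timepoint_ranks = {tok: i for i, tok in enumerate(t_tokens)}
    index.channel_ranks = {tok: i for i, tok in enumerate(c_tokens)}
    index.z_ranks = {tok: i for i, tok in enumerate(z_tokens)}

    for key in keys:
        coord = (index.timepoint_ranks[key.timepoint],
                 index.channel_ranks[key.channel],
                 index.z_ranks[key.z])
        if coord in index.planes:
            report.duplicates.append((index.planes[coord].path, key.path))
        else:
            index.planes[coord] = key

    size_t, size_c, size_z = index.shape
    for t in range(size_t):
        for c in range(size_c):
            for z in range(size_z):
                if (t, c, z) not in index.planes:
                    report.missing.append((t, c, z))
    return index, report


def build_index(position_id: int, directory: Path | str) -> tuple[PlaneIndex, ValidationReport]:
    """Index every regular file in one position directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"position directory not found: {directory}")
    return index_planes(position_id, (p for p in directory.iterdir() if p.is_file()))
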