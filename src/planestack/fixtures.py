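"""Synthetic acquisition trees with known pixel and metadata content.

Everything downstream — scanning, assembly, OME-TIFF writing, metadata
parsing — is tested against trees generated here, so no real microscopy
data is ever needed.  A generated tree mimics a multi-position
time-lapse acquisition: ``pos{xxx}`` sub-directories, one plane file per
(timepoint, channel, z-section) named by the
``{prefix}_{timepoint}_{channel}_{z}`` convention, and a pair of
semi-structured text metadata files at the root.

Each plane is filled with a single deterministic value computed by
:func:`encode_pixel` from the plane's rank coordinates.  The encoding is
injective at small ranks, so a plane landing in the wrong hypercube slot
changes some voxel and is detectable; for 8-bit output the value wraps
modulo the dtype maximum (staying in ``[1, max]`` so a fabricated
zero-filled plane can never collide with a real one).

Generation is fully deterministic: the same spec always produces a
byte-identical tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import LayoutError
from .metadata import MetadataBundle, NamedTable, aggregate
from .raster import write_plane
from .scanner import PlaneKey

_EXTENSIONS = {"tiff": "tif", "png": "png"}


@dataclass(frozen=True)
class LayoutSpec:
    """Shape of a synthetic acquisition tree.

    ``timepoints`` and ``z_sections`` are the integer tokens written
    into filenames; ``channels`` are string tokens (numeric strings or
    names, both occur in practice).  Token lists keep their given order
    for enumeration, but pixel encodings use the sorted ranks the
    scanner will assign.
    """

    n_positions: int
    timepoints: tuple[int, ...]
    channels: tuple[str, ...]
    z_sections: tuple[int, ...]
    plane_height: int = 16
    plane_width: int = 16
    prefix: str = "img"
    image_format: str = "tiff"
    pixel_type: str = "uint16"

    def __post_init__(self):
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        object.__setattr__(self, "channels", tuple(str(c) for c in self.channels))
        object.__setattr__(self, "z_sections", tuple(self.z_sections))
        if self.n_positions < 1:
            raise LayoutError("n_positions must be >= 1")
        for label, tokens in (("timepoints", self.timepoints),
                              ("channels", self.channels),
                              ("z_sections", self.z_sections)):
            if not tokens:
                raise LayoutError(f"{label} must be non-empty")
            if len(set(tokens)) != len(tokens):
                raise LayoutError(f"{label} must be duplicate-free")
        if self.plane_height < 1 or self.plane_width < 1:
            raise LayoutError("plane dimensions must be >= 1")
        if self.image_format not in _EXTENSIONS:
            raise LayoutError(f"image_format must be one of {sorted(_EXTENSIONS)}")
        if self.pixel_type not in ("uint8", "uint16"):
            raise LayoutError("pixel_type must be 'uint8' or 'uint16'")

    @property
    def n_planes(self) -> int:
        return (self.n_positions * len(self.timepoints)
                * len(self.channels) * len(self.z_sections))


@dataclass(frozen=True)
class PlaneEntry:
    path: Path
    key: PlaneKey
    value: int  # expected fill value of every pixel in the plane


@dataclass
class FixtureManifest:
    """Ground truth for one generated tree."""

    root: Path
    planes: list[PlaneEntry] = field(default_factory=list)
    metadata_files: tuple[Path, ...] = ()
    bundle: MetadataBundle | None = None


def encode_pixel(position_rank: int, t_rank: int, c_rank: int, z_rank: int,
                 pixel_type: str = "uint16") -> int:
    """Deterministic fill value for the plane at the given rank coordinates.

    ``((position_rank*7 + t_rank)*5 + c_rank)*11 + z_rank + 1``, wrapped
    into ``[1, dtype max]`` so a genuine plane is never all-zero.
    """
    if min(position_rank, t_rank, c_rank, z_rank) < 0:
        raise ValueError("ranks must be non-negative")
    raw = ((position_rank * 7 + t_rank) * 5 + c_rank) * 11 + z_rank + 1
    maximum = int(np.iinfo(pixel_type).max)
    return 1 + (raw - 1) % maximum


def _scanner_ranks(spec: LayoutSpec):
    """Ranks as the scanner will assign them (sorted distinct tokens)."""
    t_ranks = {tok: i for i, tok in enumerate(sorted(spec.timepoints))}
    z_ranks = {tok: i for i, tok in enumerate(sorted(spec.z_sections))}
    try:
        ordered_c = sorted(spec.channels, key=lambda c: int(c))
    except ValueError:
        ordered_c = sorted(spec.channels)
    c_ranks = {tok: i for i, tok in enumerate(ordered_c)}
    return t_ranks, c_ranks, z_ranks


def plan_tree(spec: LayoutSpec, dest: Path | str) -> FixtureManifest:
    """Enumerate every plane of a tree without writing any file."""
    dest = Path(dest)
    ext = _EXTENSIONS[spec.image_format]
    t_ranks, c_ranks, z_ranks = _scanner_ranks(spec)
    manifest = FixtureManifest(root=dest)
    for p in range(spec.n_positions):
        pos_dir = dest / f"pos{p + 1:03d}"
        for t in spec.timepoints:
            for c in spec.channels:
                for z in spec.z_sections:
                    path = pos_dir / f"{spec.prefix}_{t}_{c}_{z}.{ext}"
                    key = PlaneKey(prefix=spec.prefix, timepoint=t, channel=c,
                                   z=z, path=path)
                    value = encode_pixel(p, t_ranks[t], c_ranks[c], z_ranks[z],
                                         spec.pixel_type)
                    manifest.planes.append(PlaneEntry(path=path, key=key, value=value))
    return manifest


def generate_tree(spec: LayoutSpec, dest: Path | str) -> FixtureManifest:
    """Write a complete synthetic tree and return its ground truth."""
    manifest = plan_tree(spec, dest)
    manifest.root.mkdir(parents=True, exist_ok=True)
    shape = (spec.plane_height, spec.plane_width)
    for entry in manifest.planes:
        entry.path.parent.mkdir(exist_ok=True)
        write_plane(entry.path, np.full(shape, entry.value, dtype=spec.pixel_type))
    return manifest


def _check_writable(bundle: MetadataBundle) -> None:
    """Reject bundle content the text dialect cannot represent losslessly."""
    if "\n" in bundle.description or "\t" in bundle.description:
        raise ValueError("description must be a single line without tabs")
    if len(set(bundle.tags)) != len(bundle.tags):
        raise ValueError("tags must be duplicate-free for an exact round trip")
    for tag in bundle.tags:
        if not tag.strip() or "\t" in tag or "\n" in tag:
            raise ValueError(f"tag {tag!r} not representable")
    seen = set()
    for key, value in bundle.kvps:
        if ":" in key or "\t" in key or "\n" in key or not key.strip():
            raise ValueError(f"key {key!r} not representable")
        if "\t" in value or "\n" in value:
            raise ValueError(f"value {value!r} not representable")
        if key == "Description":
            raise ValueError("the 'Description' key is reserved for the description field")
        if key.lower() == "tags" and not value:
            raise ValueError("a bare 'tags' key would open a tag block")
        if (key, value) in seen:
            raise ValueError("exact-duplicate key-value pairs do not round trip")
        seen.add((key, value))
    for table in bundle.tables:
        if len(table.columns) < 2:
            raise ValueError(f"table {table.name!r}: the tab dialect needs >= 2 columns")
        if not table.rows:
            raise ValueError(f"table {table.name!r}: the tab dialect needs >= 1 row")
        if "\t" in table.name or "\n" in table.name or ":" in table.name:
            raise ValueError(f"table name {table.name!r} not representable")
        for cell in list(table.columns) + [c for row in table.rows for c in row]:
            if "\t" in cell or "\n" in cell:
                raise ValueError(f"cell {cell!r} not representable")


def _render_bundle(bundle: MetadataBundle) -> str:
    _check_writable(bundle)
    lines: list[str] = []
    if bundle.description:
        lines.append(f"Description: {bundle.description}")
    for key, value in bundle.kvps:
        lines.append(f"{key}: {value}")
    if bundle.tags:
        if lines:
            lines.append("")
        lines.append("tags:")
        lines.extend(bundle.tags)
        lines.append("")
    for table in bundle.tables:
        if lines and lines[-1] != "":
            lines.append("")
        lines.append(table.name)
        lines.append("\t".join(table.columns))
        lines.extend("\t".join(row) for row in table.rows)
        lines.append("")
    return "\n".join(lines) + "\n"


def generate_metadata_files(dest: Path | str, bundle: MetadataBundle,
                            acq_bundle: MetadataBundle | None = None
                            ) -> tuple[Path, Path]:
    """Write ``*Acq.txt`` and ``*log.txt`` files encoding the bundle.

    The log file carries ``bundle``; the acquisition file carries
    ``acq_bundle`` when given, else a single prose line that parses to
    nothing.  Parsing both files with the default parsers and
    aggregating recovers ``aggregate([acq or empty, bundle])`` exactly.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    acq_path = dest / "experimentAcq.txt"
    log_path = dest / "experimentlog.txt"
    if acq_bundle is None:
        acq_text = "Acquisition settings recorded at run start\n"
    else:
        acq_text = _render_bundle(acq_bundle)
    acq_path.write_text(acq_text, encoding="utf-8", newline="\n")
    log_path.write_text(_render_bundle(bundle), encoding="utf-8", newline="\n")
    return acq_path, log_path


def expected_bundle(bundle: MetadataBundle,
                    acq_bundle: MetadataBundle | None = None) -> MetadataBundle:
    """Ground truth the default aggregator recovers from generated files."""
    return aggregate([acq_bundle or MetadataBundle(), bundle])


def make_demo_bundle(seed: int | None = None) -> MetadataBundle:
    """A small, realistic experiment bundle for fixtures and examples.

    Deterministic for a given seed; mimics the annotations a yeast
    time-lapse log would carry: strain and medium key-value pairs, tag
    labels, and a channel-exposure table.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    strains = ["BY4741", "W303", "FY4"]
    media = ["SC 2% glucose", "YPD", "SC 0.1% glucose"]
    strain = strains[int(rng.integers(len(strains)))]
    medium = media[int(rng.integers(len(media)))]
    interval = float(rng.choice([2.5, 5.0]))
    table = NamedTable(
        name="channel settings",
        columns=("channel", "exposure_ms", "gain"),
        rows=[("Brightfield", "30", "1"),
              ("GFP", "100", "2"),
              ("mCherry", "120", "2")],
    )
    return MetadataBundle(
        description="Time-lapse imaging of budding yeast under a glucose shift",
        tags=["timelapse", "yeast", "microfluidics"],
        kvps=[("Microscope", "Nikon Ti"),
              ("Strain", strain),
              ("Medium", medium),
              ("Imaging interval (min)", f"{interval:g}"),
              ("Start time", "12:30:00")],
        tables=[table],
    )
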