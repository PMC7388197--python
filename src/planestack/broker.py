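"""Deposition layer: broker contract, local OME-TIFF sink, orchestration.

The broker contract mirrors what an image-repository transport needs:
create a dataset, write multi-dimensional images into it, link
annotations to it.  The fully-implemented sink is local: each dataset is
a directory holding one OME-TIFF per position, one HDF5 attachment per
metadata table, and a JSON manifest recording the annotations and image
dimensions — the machine-readable stand-in for a repository's tag /
key-value / table annotation objects.  A remote OMERO-style transport is
declared with the same surface so a live backend can be added without
touching callers, but no server code ships here.

OME-TIFF files declare ``DimensionOrder="XYZCT"`` and emit planes in the
matching sequence (z fastest, then channel, then time), converted from
the in-memory (T, C, Z, Y, X) layout at write time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .assembler import DefaultImageProcessor, FillPolicy, HyperCube
from .errors import DatasetConflictError
from .metadata import MetadataAggregator, MetadataBundle, MetadataParser, NamedTable

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class DatasetRef:
    """Handle to a dataset within a sink."""

    dataset_id: str
    name: str
    location: str


@dataclass(frozen=True)
class ImageRef:
    """Handle to one deposited hypercube image."""

    dataset_id: str
    position_id: int
    file_name: str
    size_t: int
    size_c: int
    size_z: int
    size_y: int
    size_x: int
    channel_names: tuple[str, ...]

    @property
    def plane_count(self) -> int:
        return self.size_t * self.size_c * self.size_z


@dataclass
class AnnotationManifest:
    """Sink-side record of everything deposited into one dataset."""

    dataset_name: str
    description: str = ""
    tags: list[str] = field(default_factory=list)
    kvps: list[list[str]] = field(default_factory=list)
    table_files: list[str] = field(default_factory=list)
    images: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "AnnotationManifest":
        return cls(**json.loads(text))


@dataclass
class UploadReport:
    """Summary of one deposition run."""

    dataset: str = ""
    images: int = 0
    planes: int = 0
    tags: int = 0
    kvps: int = 0
    tables: int = 0
    warnings: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"dataset:  {self.dataset}",
            f"images:   {self.images}",
            f"planes:   {self.planes}",
            f"tags:     {self.tags}",
            f"kvps:     {self.kvps}",
            f"tables:   {self.tables}",
        ]
        for w in self.warnings:
            lines.append(f"warning:  {w}")
        return "\n".join(lines)


class DataBroker:
    """Abstract deposition contract."""

    def create_dataset(self, name: str) -> DatasetRef:
        raise NotImplementedError

    def write_hypercube(self, ds: DatasetRef, cube: HyperCube) -> ImageRef:
        raise NotImplementedError

    def annotate_dataset(self, ds: DatasetRef, bundle: MetadataBundle) -> AnnotationManifest:
        raise NotImplementedError


class RemoteBrokerInterface(DataBroker):
    """Declared surface of a live image-server transport.

    Opens a session from credentials and deposits through the server
    API.  Intentionally unimplemented: the local sink covers every
    testable behaviour, and a server backend slots in behind this
    class without changing callers.
    """

    def __init__(self, user: str, credential: str, host: str):
        self.user = user
        self.host = host

    def connect(self):
        raise NotImplementedError("remote transport is declared but not implemented")

    def create_dataset(self, name: str) -> DatasetRef:
        raise NotImplementedError("remote transport is declared but not implemented")

    def write_hypercube(self, ds: DatasetRef, cube: HyperCube) -> ImageRef:
        raise NotImplementedError("remote transport is declared but not implemented")

    def annotate_dataset(self, ds: DatasetRef, bundle: MetadataBundle) -> AnnotationManifest:
        raise NotImplementedError("remote transport is declared but not implemented")


def _sanitize(name: str) -> str:
    return re.sub(r"[\\/:\0]", "_", name).strip() or "dataset"


class LocalSink(DataBroker):
    """File-system sink: one directory per dataset, OME-TIFF per image."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._manifests: dict[str, AnnotationManifest] = {}

    def _dataset_dir(self, ds: DatasetRef) -> Path:
        return self.root / ds.dataset_id

    def _persist(self, ds: DatasetRef) -> None:
        manifest = self._manifests[ds.dataset_id]
        (self._dataset_dir(ds) / MANIFEST_NAME).write_text(manifest.to_json(), encoding="utf-8")

    def create_dataset(self, name: str) -> DatasetRef:
        if not name:
            raise ValueError("dataset name must be non-empty")
        base = _sanitize(name)
        candidate, suffix = base, 2
        while (self.root / candidate).exists():
            candidate = f"{base}_{suffix}"
            suffix += 1
        (self.root / candidate).mkdir(parents=True)
        ds = DatasetRef(dataset_id=candidate, name=name, location=str(self.root))
        self._manifests[candidate] = AnnotationManifest(dataset_name=name)
        self._persist(ds)
        return ds

    def write_hypercube(self, ds: DatasetRef, cube: HyperCube) -> ImageRef:
        target = self._dataset_dir(ds) / f"pos{cube.position_id:03d}.ome.tiff"
        if target.exists():
            raise DatasetConflictError(
                f"image for position {cube.position_id} already exists: {target}")
        size_t, size_c, size_z, size_y, size_x = cube.shape
        with tifffile.TiffWriter(target, ome=True) as writer:
            # axes TCZYX <=> OME DimensionOrder XYZCT (z fastest page order)
            writer.write(np.ascontiguousarray(cube.pixels),
                         photometric="minisblack",
                         metadata={"axes": "TCZYX",
                                   "Channel": {"Name": list(cube.channel_names)}})
        ref = ImageRef(dataset_id=ds.dataset_id, position_id=cube.position_id,
                       file_name=target.name, size_t=size_t, size_c=size_c,
                       size_z=size_z, size_y=size_y, size_x=size_x,
                       channel_names=tuple(cube.channel_names))
        manifest = self._manifests[ds.dataset_id]
        manifest.images.append({
            "position_id": cube.position_id, "file_name": target.name,
            "size_t": size_t, "size_c": size_c, "size_z": size_z,
            "size_y": size_y, "size_x": size_x,
            "channel_names": list(cube.channel_names),
        })
        manifest.images.sort(key=lambda e: e["position_id"])
        self._persist(ds)
        return ref

    def _write_table(self, directory: Path, table: NamedTable, file_name: str) -> None:
        try:
            with h5py.File(directory / file_name, "w") as h5:
                group = h5.create_group(table.name)
                group.attrs["columns"] = list(table.columns)
                str_dtype = h5py.string_dtype(encoding="utf-8")
                for j, column in enumerate(table.columns):
                    values = [row[j] for row in table.rows]
                    group.create_dataset(column, data=values, dtype=str_dtype)
        except Exception as exc:
            raise RuntimeError(f"failed to serialize table {table.name!r}") from exc

    def annotate_dataset(self, ds: DatasetRef, bundle: MetadataBundle) -> AnnotationManifest:
        directory = self._dataset_dir(ds)
        manifest = self._manifests[ds.dataset_id]
        manifest.description = bundle.description
        manifest.tags = list(bundle.tags)
        manifest.kvps = [list(kv) for kv in bundle.kvps]
        manifest.table_files = []
        for table in bundle.tables:
            file_name = f"{_sanitize(table.name)}.h5"
            self._write_table(directory, table, file_name)
            manifest.table_files.append(file_name)
        self._persist(ds)
        return manifest

    def read_manifest(self, ds: DatasetRef) -> AnnotationManifest:
        """Reload a dataset manifest from disk."""
        text = (self._dataset_dir(ds) / MANIFEST_NAME).read_text(encoding="utf-8")
        return AnnotationManifest.from_json(text)


def read_table(path: Path | str) -> list[NamedTable]:
    """Read back HDF5 table attachments written by :class:`LocalSink`."""
    tables = []
    with h5py.File(path, "r") as h5:
        for name, group in h5.items():
            columns = tuple(group.attrs["columns"])
            column_data = [[v.decode("utf-8") if isinstance(v, bytes) else str(v)
                            for v in group[c][()]] for c in columns]
            rows = [tuple(cells) for cells in zip(*column_data)] if column_data and column_data[0] else []
            tables.append(NamedTable(name=name, columns=columns, rows=rows))
    return tables


def resolve_sink(host: str) -> DataBroker:
    """Map a server/sink designator to a broker.

    ``local:<dir>`` (or a bare path) selects the local sink; anything
    else is taken as a remote server address, for which no transport is
    implemented.
    """
    if host.startswith("local:"):
        return LocalSink(host[len("local:"):])
    looks_like_path = ("/" in host or "\\" in host or Path(host).is_dir()
                       or ("." not in host and host not in ("", "localhost")))
    if looks_like_path:
        return LocalSink(host)
    raise NotImplementedError(
        f"no transport for remote host {host!r}; use 'local:<directory>'")


def launch_upload(user: str, credential: str, host: str, dataset_name: str,
                  data_path: Path | str, include_metadata: bool = True, *,
                  parser: MetadataParser | None = None,
                  processor=None,
                  fill_policy: FillPolicy = "error",
                  sink: DataBroker | None = None) -> UploadReport:
    """Run the full deposition pipeline and summarise it.

    Orchestrates: metadata extraction (when ``include_metadata``), tree
    scan, hypercube assembly, dataset creation, image writes and
    annotation linking.  With a local sink the credentials are ignored;
    ``host`` only selects the sink directory.
    """
    data_path = Path(data_path)
    if not data_path.is_dir():
        raise FileNotFoundError(f"data path not found: {data_path}")
    if sink is None:
        sink = resolve_sink(host)

    bundle = MetadataBundle()
    if include_metadata:
        bundle = (parser or MetadataAggregator()).extract_metadata(data_path)

    report = UploadReport(dataset=dataset_name)
    ds = sink.create_dataset(dataset_name)
    report.dataset = ds.dataset_id

    image_processor = processor or DefaultImageProcessor(fill_policy=fill_policy)
    refs = image_processor.process_image(sink, data_path, ds)
    if not refs:
        report.warnings.append(f"no position directories found under {data_path}")
    report.images = len(refs)
    report.planes = sum(r.plane_count for r in refs)

    sink.annotate_dataset(ds, bundle)
    report.tags = len(bundle.tags)
    report.kvps = len(bundle.kvps)
    report.tables = len(bundle.tables)
    return report


class Uploader:
    """Convenience front end bound to one server/sink and credentials."""

    def __init__(self, user: str, credential: str, host: str):
        self.user = user
        self.credential = credential
        self.host = host

    def launch_upload(self, dataset_name: str, data_path: Path | str,
                      include_metadata: bool = True, **kwargs) -> UploadReport:
        return launch_upload(self.user, self.credential, self.host,
                             dataset_name, data_path, include_metadata, **kwargs)
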