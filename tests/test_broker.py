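"""Local sink deposition: OME-TIFF writing, HDF5 attachments, manifests."""

import json
import xml.etree.ElementTree as ET

import numpy as np
import pytest
import tifffile

from planestack import (DatasetConflictError, HyperCube, LocalSink,
                        MetadataBundle, NamedTable, assemble_cube, build_index,
                        launch_upload, make_demo_bundle)
from planestack.broker import read_table
from planestack.fixtures import expected_bundle

OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _ome_pixels(path):
    xml = tifffile.TiffFile(path).ome_metadata
    return ET.fromstring(xml).find(f"{OME_NS}Image/{OME_NS}Pixels")


class TestCreateDataset:
    def test_creates_directory_and_manifest(self, tmp_path):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("my_first_dataset")
        assert (tmp_path / "my_first_dataset" / "manifest.json").is_file()
        assert ds.dataset_id == "my_first_dataset"

    def test_empty_name_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            LocalSink(tmp_path).create_dataset("")

    def test_repeated_name_gets_numeric_suffix(self, tmp_path):
        sink = LocalSink(tmp_path)
        assert sink.create_dataset("d").dataset_id == "d"
        assert sink.create_dataset("d").dataset_id == "d_2"
        assert sink.create_dataset("d").dataset_id == "d_3"

    def test_path_separators_sanitized(self, tmp_path):
        ds = LocalSink(tmp_path).create_dataset("a/b\\c")
        assert "/" not in ds.dataset_id and "\\" not in ds.dataset_id


class TestWriteHypercube:
    @pytest.fixture
    def cube(self, small_tree):
        root, _, _ = small_tree
        index, _ = build_index(1, root / "pos001")
        return assemble_cube(index)

    def test_ome_xml_dimensions(self, tmp_path, cube):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        ref = sink.write_hypercube(ds, cube)
        pixels = _ome_pixels(tmp_path / "d" / ref.file_name)
        assert pixels.get("DimensionOrder") == "XYZCT"
        assert (int(pixels.get("SizeT")), int(pixels.get("SizeC")),
                int(pixels.get("SizeZ"))) == (3, 3, 1)
        assert (int(pixels.get("SizeY")), int(pixels.get("SizeX"))) == (16, 16)

    def test_read_back_bit_exact(self, tmp_path, cube):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        ref = sink.write_hypercube(ds, cube)
        stored = tifffile.imread(tmp_path / "d" / ref.file_name)
        assert stored.dtype == cube.pixel_type
        assert (stored.reshape(cube.shape) == cube.pixels).all()

    def test_channel_elements_and_names(self, tmp_path, cube):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        ref = sink.write_hypercube(ds, cube)
        pixels = _ome_pixels(tmp_path / "d" / ref.file_name)
        channels = pixels.findall(f"{OME_NS}Channel")
        assert [ch.get("Name") for ch in channels] == cube.channel_names

    def test_single_channel_cube_one_channel_element(self, tmp_path):
        cube = HyperCube(position_id=4,
                         pixels=np.ones((2, 1, 2, 4, 4), np.uint16),
                         channel_names=["GFP"])
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        ref = sink.write_hypercube(ds, cube)
        pixels = _ome_pixels(tmp_path / "d" / ref.file_name)
        assert len(pixels.findall(f"{OME_NS}Channel")) == 1

    def test_rewrite_same_position_conflicts(self, tmp_path, cube):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        sink.write_hypercube(ds, cube)
        with pytest.raises(DatasetConflictError):
            sink.write_hypercube(ds, cube)

    def test_manifest_entry_matches_ome_xml(self, tmp_path, cube):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        sink.write_hypercube(ds, cube)
        manifest = sink.read_manifest(ds)
        entry = manifest.images[0]
        pixels = _ome_pixels(tmp_path / "d" / entry["file_name"])
        for axis in "tczyx":
            assert entry[f"size_{axis}"] == int(pixels.get(f"Size{axis.upper()}"))


class TestAnnotateDataset:
    def test_one_h5_per_table(self, tmp_path):
        bundle = MetadataBundle(tables=[
            NamedTable("first", ("a", "b"), [("1", "2")]),
            NamedTable("second", ("x", "y"), [("3", "4")])])
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        manifest = sink.annotate_dataset(ds, bundle)
        assert len(manifest.table_files) == 2
        for name in manifest.table_files:
            assert (tmp_path / "d" / name).is_file()

    def test_h5_read_back_exact(self, tmp_path):
        table = NamedTable("channel settings", ("channel", "exposure_ms"),
                           [("GFP", "100"), ("BF", "30")])
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        manifest = sink.annotate_dataset(ds, MetadataBundle(tables=[table]))
        (recovered,) = read_table(tmp_path / "d" / manifest.table_files[0])
        assert recovered == table

    def test_empty_bundle_empty_sections(self, tmp_path):
        sink = LocalSink(tmp_path)
        ds = sink.create_dataset("d")
        manifest = sink.annotate_dataset(ds, MetadataBundle())
        assert manifest.tags == [] and manifest.kvps == [] and manifest.table_files == []


class TestLaunchUpload:
    def test_full_pipeline_report(self, small_tree, tmp_path):
        root, _, truth = small_tree
        report = launch_upload("user", "", f"local:{tmp_path/'sink'}",
                               "my_first_dataset", root)
        assert report.images == 3
        assert report.planes == 27
        assert report.tags == len(truth.tags)
        assert report.kvps == len(truth.kvps)
        assert report.tables == len(truth.tables)
        files = sorted(p.name for p in (tmp_path / "sink" / "my_first_dataset").glob("*.ome.tiff"))
        assert files == ["pos001.ome.tiff", "pos002.ome.tiff", "pos003.ome.tiff"]

    def test_metadata_flag_off(self, small_tree, tmp_path):
        root, _, _ = small_tree
        report = launch_upload("u", "", f"local:{tmp_path/'sink'}", "d", root,
                               include_metadata=False)
        assert (report.tags, report.kvps, report.tables) == (0, 0, 0)

    def test_no_positions_warns(self, tmp_path):
        (tmp_path / "empty").mkdir()
        report = launch_upload("u", "", f"local:{tmp_path/'sink'}", "d",
                               tmp_path / "empty")
        assert report.images == 0
        assert report.warnings

    def test_remote_host_unsupported(self, small_tree):
        root, _, _ = small_tree
        with pytest.raises(NotImplementedError):
            launch_upload("u", "pw", "demo.openmicroscopy.org", "d", root)

    def test_manifest_annotations_match_ground_truth(self, small_tree, tmp_path):
        root, _, truth = small_tree
        launch_upload("u", "", f"local:{tmp_path/'sink'}", "d", root)
        manifest = json.loads((tmp_path / "sink" / "d" / "manifest.json").read_text())
        assert manifest["description"] == truth.description
        assert manifest["tags"] == truth.tags
        assert manifest["kvps"] == [list(kv) for kv in truth.kvps]

    def test_deterministic_manifests_across_runs(self, small_tree, tmp_path):
        root, _, _ = small_tree
        launch_upload("u", "", f"local:{tmp_path/'s1'}", "d", root)
        launch_upload("u", "", f"local:{tmp_path/'s2'}", "d", root)
        a = (tmp_path / "s1" / "d" / "manifest.json").read_text()
        b = (tmp_path / "s2" / "d" / "manifest.json").read_text()
        assert a == b
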