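import pytest

from planestack import LayoutSpec, generate_metadata_files, generate_tree, make_demo_bundle
from planestack.fixtures import expected_bundle


@pytest.fixture
def small_spec():
    """The canonical demo layout: 3 positions, 3 timepoints, 3 channels, 1 z."""
    return LayoutSpec(n_positions=3, timepoints=(1, 2, 3),
                      channels=("1", "2", "3"), z_sections=(1,),
                      plane_height=16, plane_width=16)


@pytest.fixture
def small_tree(tmp_path, small_spec):
    """A generated 3x3x3x1 tree with metadata files; returns (root, manifest, truth)."""
    root = tmp_path / "data"
    manifest = generate_tree(small_spec, root)
    bundle = make_demo_bundle(seed=7)
    generate_metadata_files(root, bundle)
    manifest.bundle = expected_bundle(bundle)
    return root, manifest, manifest.bundle
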