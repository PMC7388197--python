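# planestack

Turn a directory tree of 2D microscopy planes into annotated
five-dimensional hypercube images, and deposit them — together with
metadata extracted from semi-structured experiment logs — through a
broker whose default sink writes OME-TIFF files, HDF5 table attachments
and a JSON manifest.

## Who this is for

Labs running multi-position time-lapse experiments: organisms imaged at
20+ stage positions, several optical channels and z-sections, hundreds
of timepoints. Acquisition software leaves behind tens of thousands of
individual 2D rasters plus free-text logs; repositories such as OMERO
want one 5D image per position plus structured annotations (tags,
key-value pairs, tables). `planestack` automates the transformation.

## The model

An acquisition tree obeys three conventions:

1. the root contains sub-directories `pos{xxx}`, one per microscope
   stage position (`{xxx}` numeric, any digit width);
2. each position directory holds one plane image per
   (timepoint, channel, z-section) combination;
3. plane filenames follow `{prefix}_{timepoint}_{channel}_{z}` with a
   raster extension (`.tif`, `.tiff`, `.png`); `{prefix}` may itself
   contain underscores, so tokens are taken from the right.

For each position, the distinct timepoint/channel/z tokens are sorted
and mapped to dense 0-based ranks, giving extents
(SizeT, SizeC, SizeZ). Planes are placed into a single array with axes
**(T, C, Z, Y, X)** — one hypercube per position. The local sink writes
each hypercube as an OME-TIFF whose embedded OME-XML declares
`DimensionOrder="XYZCT"`, the dimension sizes and the channel names;
reading the file back reproduces the cube bit-exactly.

Metadata comes from two text files at the tree root (`*Acq.txt`,
`*log.txt`). The default parsers extract colon-delimited key-value
pairs (split at the *first* colon, so `Start time: 12:30:00` survives),
a `tags:` block of free-text labels, and tab-separated table blocks.
Each parser returns the four-field contract record
`{description, tags, kvps, tables}`; an aggregator merges the two
files. Both the metadata parser and the image processor are pluggable
at runtime — any object with `extract_metadata(source)` /
`process_image(sink, path, dataset)` substitutes for the default.

## Worked example

```python
from pathlib import Path
from planestack import (LayoutSpec, generate_tree, generate_metadata_files,
                        make_demo_bundle, launch_upload)

root = Path("demo_data")
spec = LayoutSpec(n_positions=3, timepoints=(1, 2, 3),
                  channels=("1", "2", "3"), z_sections=(1,))
generate_tree(spec, root)                       # 27 plane files
generate_metadata_files(root, make_demo_bundle(seed=1))

report = launch_upload("alice", "", "local:demo_sink",
                       "my_first_dataset", root)
print(report)
```

prints

```
dataset:  my_first_dataset
images:   3
planes:   27
tags:     3
kvps:     5
tables:   1
```

— 3 hypercubes (one per position, each 3 timepoints x 3 channels x
1 z-section of 16x16 pixels) written to
`demo_sink/my_first_dataset/pos00{1,2,3}.ome.tiff`, 27 source planes
consumed, and the demo log's 3 tags, 5 key-value pairs and 1 table
recorded in `manifest.json` with the table serialized to an `.h5`
attachment.

The same run from a shell:

```sh
planestack-upload -d demo_data -n my_first_dataset -u alice \
    -s local:demo_sink -y
```

`--dry-run` scans, validates the T x C x Z grid (reporting missing or
duplicate planes) and parses metadata without writing anything;
`--fill zero` pads missing grid cells with blank planes instead of
aborting; `--parser`/`--processor` load custom plug-in modules.

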