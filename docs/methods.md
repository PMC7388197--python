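# Methods

## Scope and architecture

`planestack` is a deposition toolkit, not an analysis package: it moves
pixels and annotations from an acquisition layout into a repository
layout without altering either. Three layers mirror how such tools are
usually factored: a **metadata parser** layer (pluggable extractors
returning a fixed four-field record), a **transfer** layer (scan the
tree, assemble hypercubes, orchestrate via `launch_upload`), and a
**broker** layer (create datasets, write images, link annotations). The
broker is a contract; the only shipped implementation is a local sink
writing OME-TIFF + HDF5 + JSON. A remote image-server transport is
declared (`RemoteBrokerInterface`) with the same surface so a live
backend can be added without touching callers, but deliberately carries
no network code: every behaviour of the pipeline is exercisable and
verifiable on a local filesystem.

## Filename convention and indexing

Filenames are tokenised **from the right** (`rsplit('_', 3)`): z, then
channel, then timepoint, with the remainder as the prefix. This lets
the prefix contain underscores, which real acquisition prefixes do.
Non-conforming names are *rejections* (values carrying a reason), not
exceptions, so a stray `README.txt` inside a position directory is
reported and skipped rather than aborting a 90,000-file scan.

Tokens are mapped to dense 0-based ranks by sorting the distinct values
per position: numerically for timepoint and z; channels numerically
when every token parses as an integer, else lexicographically. Ranks
rather than raw tokens mean gapped or 1-based numbering (timepoints
{1, 3, 5}, z starting at 0 or 1) all index correctly. The chosen
channel ordering is recorded in the index and becomes the OME channel
name list, so downstream naming is reproducible. Position-directory
matching (`pos` + digits) is case-insensitive and accepts any digit
width; generated fixtures zero-pad to three digits.

Indexing is order-independent by construction — rank maps derive from
sorted token sets, duplicate resolution keeps the lexicographically
first path — which the tests check by shuffling enumeration order.

## Hypercube assembly

The in-memory axis order is **(T, C, Z, Y, X)**; the sink converts to
the declared OME dimension order at write time. One canonical order
plus one explicit conversion avoids silent transposition bugs.

All planes of a position must share height, width and pixel type;
mixed types are an error, never an implicit promotion, because a
promoted plane would silently change intensity statistics. Missing
grid cells abort under the default `error` fill policy; `zero` fill is
opt-in and pads with all-zero planes (how an interrupted acquisition
should be treated is an experiment-level decision, so both policies
exist but fabrication is never the default).

## OME-TIFF writing

The local sink writes one multi-page OME-TIFF per position via
`tifffile`, with `DimensionOrder="XYZCT"` — pages emitted z-fastest,
then channel, then time, exactly the reverse of the memory axes — plus
SizeT/SizeC/SizeZ/SizeY/SizeX and per-channel `Name` attributes.
Greyscale photometric interpretation is forced so narrow planes are
never misread as RGB(A) samples. Tests verify round trips with an
independent read path (`tifffile.imread` + stdlib XML parsing of the
embedded OME-XML), never the writer's own bookkeeping.

## Metadata dialect

The default extractors target the structural features of lab logs:

* **KVPs** — any line containing a colon, split at the first colon,
  key and value trimmed, order preserved. First-colon (not last, not
  all) so clock times and URLs survive as values.
* **Tags** — lines between a `tags:` header (case-insensitive) and the
  first blank line.
* **Tables** — maximal runs of ≥2 consecutive lines each containing
  the same positive number of tabs; the first line is the header; a
  non-blank, non-tabbed line immediately above names the table, else
  `table_{k}` by block occurrence. Ragged runs are skipped with a
  warning, not fatal.
* **Description** — the value of a `Description` KVP, consumed so it
  does not double as a pair.

Within `extract_metadata` these are staged — tag block first, table
blocks next, KVP scan only over the remaining lines — so a table cell
containing a colon never leaks into the pair list. The standalone
functions (`parse_kvp_lines` etc.) remain deliberately line-local. The
whole rule-set lives in a `ParserRules` record (delimiter, header
pattern, file globs), so a lab with a different dialect overrides
patterns without subclassing; a wholly different format supplies its
own parser object instead.

Aggregation of several extractors joins non-empty descriptions with a
blank line, takes an order-preserving union of tags, concatenates KVPs
dropping only *exact* duplicate pairs (the same key with two values is
information, not noise), and disambiguates colliding table names with
`_2`, `_3`, … suffixes. These merge rules are associative over tags
and KVPs, which a property test confirms.

## HDF5 attachments and the manifest

Each table becomes one `.h5` file: a group named after the table, one
variable-length UTF-8 string dataset per column, column order kept in
a group attribute. Cells are stored as strings because the text
dialect carries no type information; consumers get a
`NamedTable.to_dataframe()` view for typed work. The JSON manifest
(`manifest.json` per dataset) records description, tags, KVPs, table
attachment names, and per-image dimensions + channel names — the
machine-readable stand-in for a repository's annotation objects. It
contains no timestamps, so repeated runs on identical input are
byte-identical.

## Synthetic data generator

The generator emulates the acquisition layout itself: the demo layout
(3 positions × 3 timepoints × 3 channels × 1 z of 16×16 planes) and
the full-experiment layout (25 positions × 240 timepoints × 3 channels
× 5 z of 512×512 planes — enumerated by name; small-plane variants are
materialised for deposition runs, with the 25-position deposition
check using 2×2×2 grids of 32×32 planes to keep runs in seconds).

Every plane is filled with the constant
`((p·7 + t)·5 + c)·11 + z + 1` (ranks, 0-based), wrapped into
`[1, dtype-max]`. The formula is injective at small ranks, so a plane
placed into the wrong (t, c, z) slot is guaranteed to change voxels and
be caught by the placement oracle; staying ≥1 means a zero-filled
fabricated plane can never masquerade as a real one. Generation is
fully deterministic — identical specs yield byte-identical trees.

What the generator does **not** emulate: realistic image content
(noise, cells, illumination), vendor container formats, drifting
stage positions, or the exact byte layout of any particular lab's log
files — only their structural features (colon KVPs, tag block,
tab-separated tables). Passing tests therefore demonstrate correct
*plumbing* — placement, dimensional bookkeeping, lossless round trips,
metadata recovery — not robustness to arbitrary real-world logs, which
is exactly what the pluggable parser contract exists for.

The demo metadata bundle mimics a yeast time-lapse log (strain, medium,
imaging interval, a channel-settings table); a seed varies its content
deterministically. The writer refuses bundle content its dialect cannot
represent losslessly (multi-line descriptions, tabs in cells,
single-column or zero-row tables, duplicate tags, exact-duplicate
KVPs), keeping the generate→parse round trip an exact equality.

## Numerical and degenerate-input choices

* Voxel sums in conservation checks accumulate in int64 to avoid
  wrap-around on uint16 data.
* An empty position directory is an assembly-time error (there is
  nothing to size a cube from), not a scan-time one.
* Dataset names are sanitised of path separators; name collisions get
  numeric suffixes rather than overwriting.
* Re-depositing the same position into a dataset is a conflict error;
  the sink never silently replaces an image.
* CLI exit codes: 0 success, 1 input/usage error, 2 deposition error.

## Known limitations

* No remote transport: uploads to a live server require implementing
  the declared broker interface.
* The tab dialect cannot represent single-column or empty tables, and
  typed table cells round-trip as strings.
* Planes are read one file at a time into a dense in-memory array; a
  full 25×240×3×5×512×512 uint16 experiment would need ~37 GB and
  should be processed per position (as the pipeline already does) on a
  machine sized for one cube (~1.5 GB).
* Only greyscale single-plane TIFF/PNG inputs are supported; vendor
  container formats are out of scope.
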