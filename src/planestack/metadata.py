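"""Pluggable metadata extraction from semi-structured experiment logs.

Time-lapse experiments are typically described in free-form text files
written at acquisition time: an acquisition settings file (``*Acq.txt``)
and a running log (``*log.txt``).  The default extractors here recover
four kinds of annotation from such files:

* **key-value pairs** — any line containing a colon, split at the FIRST
  colon so clock times like ``Start time: 12:30:00`` keep their value
  intact;
* **tags** — lines inside a block opened by a ``tags:`` header and
  closed by the first blank line;
* **tables** — maximal runs of two or more consecutive lines that each
  contain the same positive number of tabs; the first line of a run is
  the header, and a non-tabbed line immediately above the run names the
  table;
* **description** — the value of a ``Description`` key-value pair, which
  is consumed (it does not also appear in the pair list).

Every extractor implements a single-method contract,
:meth:`MetadataParser.extract_metadata`, returning a
:class:`MetadataBundle` — so a lab with its own log dialect can swap in
a custom parser at runtime without touching the deposition machinery.
The extraction rules themselves live in a :class:`ParserRules` record
and can be overridden per lab without subclassing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NamedTable:
    """A named rectangular table of string cells."""

    name: str
    columns: tuple[str, ...]
    rows: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self):
        if not self.name:
            raise ValueError("table name must be non-empty")
        self.columns = tuple(self.columns)
        self.rows = [tuple(r) for r in self.rows]
        for r in self.rows:
            if len(r) != len(self.columns):
                raise ValueError(
                    f"table {self.name!r}: row has {len(r)} cells, expected {len(self.columns)}")

    def to_dataframe(self) -> pd.DataFrame:
        """The table as a pandas DataFrame with ``df.attrs['name']`` set."""
        df = pd.DataFrame(list(self.rows), columns=list(self.columns), dtype=object)
        df.attrs["name"] = self.name
        return df


@dataclass
class MetadataBundle:
    """The parser-contract record: what one extractor recovered.

    Always exactly these four fields, each possibly empty.
    """

    description: str = ""
    tags: list[str] = field(default_factory=list)
    kvps: list[tuple[str, str]] = field(default_factory=list)
    tables: list[NamedTable] = field(default_factory=list)

    def to_dict(self) -> dict:
        """The contract shape: ``{"description", "tags", "kvps", "tables"}``."""
        return {
            "description": self.description,
            "tags": list(self.tags),
            "kvps": [list(kv) for kv in self.kvps],
            "tables": [t.to_dataframe() for t in self.tables],
        }


@dataclass(frozen=True)
class ParserRules:
    """Configurable extraction dialect.

    Labs that deviate from the default log format override patterns here
    instead of writing a new parser class.
    """

    kvp_delimiter: str = ":"
    tag_header: str = r"tags:"
    description_key: str = "Description"
    acq_glob: str = "*Acq.txt"
    log_glob: str = "*log.txt"

    def is_tag_header(self, line: str) -> bool:
        return re.fullmatch(self.tag_header, line.strip(), re.IGNORECASE) is not None


DEFAULT_RULES = ParserRules()


def parse_kvp_lines(text: str, rules: ParserRules = DEFAULT_RULES) -> list[tuple[str, str]]:
    """Extract ``key: value`` pairs, one per delimited line, in order.

    The split is at the first delimiter; key and value are trimmed;
    lines without the delimiter yield nothing.  Line-local by design.
    """
    pairs = []
    for line in text.splitlines():
        if rules.kvp_delimiter in line:
            key, _, value = line.partition(rules.kvp_delimiter)
            pairs.append((key.strip(), value.strip()))
    return pairs


def _tag_block_lines(lines: Sequence[str], rules: ParserRules) -> list[int]:
    """Indices of the tag block (header included), or empty if none."""
    for i, line in enumerate(lines):
        if rules.is_tag_header(line):
            block = [i]
            for j in range(i + 1, len(lines)):
                if not lines[j].strip():
                    break
                block.append(j)
            return block
    return []


def parse_tags(text: str, rules: ParserRules = DEFAULT_RULES) -> list[str]:
    """Tags from the first ``tags:`` block; duplicates preserved here."""
    lines = text.splitlines()
    block = _tag_block_lines(lines, rules)
    return [lines[i].strip() for i in block[1:]]


@dataclass(frozen=True)
class _TableRun:
    name_line: int | None  # index of the naming line, if any
    start: int             # first block line (header)
    stop: int              # one past the last block line
    ragged: bool


def _table_runs(lines: Sequence[str], skip: frozenset[int] = frozenset()) -> list[_TableRun]:
    """Locate maximal runs of consecutive tab-bearing lines."""
    runs = []
    i = 0
    n = len(lines)
    while i < n:
        if i in skip or "\t" not in lines[i]:
            i += 1
            continue
        j = i
        while j < n and j not in skip and "\t" in lines[j]:
            j += 1
        if j - i >= 2:
            counts = {lines[k].count("\t") for k in range(i, j)}
            name_line = None
            if i > 0 and (i - 1) not in skip and lines[i - 1].strip() and "\t" not in lines[i - 1]:
                name_line = i - 1
            runs.append(_TableRun(name_line, i, j, ragged=len(counts) > 1))
        i = j
    return runs


def parse_tables(text: str, rules: ParserRules = DEFAULT_RULES) -> list[NamedTable]:
    """Tables from tab-separated blocks; ragged blocks skipped with a warning."""
    lines = text.splitlines()
    tables = []
    for k, run in enumerate(_table_runs(lines), start=1):
        if run.ragged:
            logger.warning("skipping ragged table block at lines %d-%d", run.start + 1, run.stop)
            continue
        name = lines[run.name_line].strip() if run.name_line is not None else f"table_{k}"
        columns = tuple(cell.strip() for cell in lines[run.start].split("\t"))
        rows = [tuple(cell.strip() for cell in lines[i].split("\t"))
                for i in range(run.start + 1, run.stop)]
        tables.append(NamedTable(name=name, columns=columns, rows=rows))
    return tables


class MetadataParser:
    """Abstract parser contract: one mandated operation.

    Any object whose ``extract_metadata(source)`` returns a
    :class:`MetadataBundle` is substitutable at runtime.
    """

    def extract_metadata(self, source: Path | str) -> MetadataBundle:
        raise NotImplementedError


class TextDialectParser(MetadataParser):
    """Default extractor for one semi-structured text file.

    Section extraction is staged so sections do not bleed into one
    another: the tag block is located first, table blocks next (never
    inside the tag block), and only the remaining lines are scanned for
    key-value pairs — a table cell containing a colon never becomes a
    spurious pair.
    """

    def __init__(self, rules: ParserRules = DEFAULT_RULES):
        self.rules = rules

    def extract_metadata(self, source: Path | str) -> MetadataBundle:
        source = Path(source)
        if not source.is_file():
            raise FileNotFoundError(f"metadata source not found: {source}")
        return self.parse_text(source.read_text(encoding="utf-8"))

    def parse_text(self, text: str) -> MetadataBundle:
        lines = text.splitlines()
        consumed: set[int] = set()

        tag_block = _tag_block_lines(lines, self.rules)
        tags = [lines[i].strip() for i in tag_block[1:]]
        consumed.update(tag_block)

        tables = []
        runs = _table_runs(lines, skip=frozenset(consumed))
        for k, run in enumerate(runs, start=1):
            consumed.update(range(run.start, run.stop))
            if run.name_line is not None:
                consumed.add(run.name_line)
            if run.ragged:
                logger.warning("skipping ragged table block at lines %d-%d",
                               run.start + 1, run.stop)
                continue
            name = lines[run.name_line].strip() if run.name_line is not None else f"table_{k}"
            columns = tuple(cell.strip() for cell in lines[run.start].split("\t"))
            rows = [tuple(cell.strip() for cell in lines[i].split("\t"))
                    for i in range(run.start + 1, run.stop)]
            tables.append(NamedTable(name=name, columns=columns, rows=rows))

        remaining = "\n".join(lines[i] for i in range(len(lines)) if i not in consumed)
        kvps = parse_kvp_lines(remaining, self.rules)

        description = ""
        kept = []
        for key, value in kvps:
            if key == self.rules.description_key and not description:
                description = value
            else:
                kept.append((key, value))
        return MetadataBundle(description=description, tags=tags, kvps=kept, tables=tables)


class AcqMetadataParser(TextDialectParser):
    """Default parser for the acquisition settings file (``*Acq.txt``)."""


class LogMetadataParser(TextDialectParser):
    """Default parser for the experiment log file (``*log.txt``)."""


def aggregate(bundles: Sequence[MetadataBundle]) -> MetadataBundle:
    """Merge bundles from several extractors into one.

    Descriptions are joined with a blank line (empty ones skipped); tags
    become an order-preserving union; key-value pairs are concatenated
    with exact-duplicate pairs removed (the same key with differing
    values keeps both); tables are concatenated, with colliding names
    disambiguated by ``_2``, ``_3``, ... suffixes.
    """
    if not bundles:
        raise ValueError("aggregate requires at least one bundle")
    description = "\n\n".join(b.description for b in bundles if b.description)

    tags: list[str] = []
    for b in bundles:
        for tag in b.tags:
            if tag not in tags:
                tags.append(tag)

    kvps: list[tuple[str, str]] = []
    for b in bundles:
        for pair in b.kvps:
            if pair not in kvps:
                kvps.append(pair)

    tables: list[NamedTable] = []
    seen_names: set[str] = set()
    for b in bundles:
        for table in b.tables:
            name = table.name
            suffix = 2
            while name in seen_names:
                name = f"{table.name}_{suffix}"
                suffix += 1
            seen_names.add(name)
            tables.append(replace(table, name=name) if name != table.name else table)
    return MetadataBundle(description=description, tags=tags, kvps=kvps, tables=tables)


class MetadataAggregator(MetadataParser):
    """Combine acquisition-file and log-file extraction over a tree root.

    ``source`` is the data directory; the acquisition and log files are
    located by the configured glob patterns.  Missing files contribute
    empty bundles, so a tree with no metadata yields an empty bundle
    rather than an error.
    """

    def __init__(self, parsers: Iterable[tuple[str, MetadataParser]] | None = None,
                 rules: ParserRules = DEFAULT_RULES):
        self.rules = rules
        if parsers is None:
            parsers = [(rules.acq_glob, AcqMetadataParser(rules)),
                       (rules.log_glob, LogMetadataParser(rules))]
        self.parsers = list(parsers)

    def extract_metadata(self, source: Path | str) -> MetadataBundle:
        root = Path(source)
        if not root.is_dir():
            raise FileNotFoundError(f"data directory not found: {root}")
        bundles = []
        for pattern, parser in self.parsers:
            for path in sorted(root.glob(pattern)):
                bundles.append(parser.extract_metadata(path))
        if not bundles:
            return MetadataBundle()
        return aggregate(bundles)
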