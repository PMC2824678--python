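"""Mapper backend over tab-delimited annotation files.

A flat mapping file has one column per data source and one row per
biological entity; a row is an equivalence statement, so every pair of
non-empty cells in it becomes a symmetric mapping. This is the "custom
annotation table" scenario: a lab maps its custom probe identifiers to one
well-known gene identifier and relies on transitive stacking for the rest.

Dialect (kept deliberately minimal):

* delimiter is TAB, no quoting; cells are trimmed of surrounding whitespace;
* the first line is a header of syscodes by default; headerless files take a
  positional ``columns`` assignment instead;
* a cell may hold several identifiers separated by ``,``, which expand
  combinatorially within the row;
* an empty cell means the entity has no identifier in that column's source;
* duplicate rows (and duplicate links) deduplicate silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from .core import DataSource, DataSourceRegistry, Xref
from .errors import FlatFileParseError, MapperConnectionError
from .mapper import IDMapper, MemoryLinkMapper, register_provider


def load_flatfile(
    path: str | Path,
    registry: DataSourceRegistry,
    columns: Optional[Sequence[str]] = None,
    header: bool = True,
) -> MemoryLinkMapper:
    """Load a tab-delimited mapping file into a mapper handle.

    Parameters
    ----------
    path:
        The TSV file.
    registry:
        Resolves column syscodes to :class:`DataSource` records.
    columns:
        Positional syscode assignment. Required for headerless files; when
        given for a file with a header it overrides the header.
    header:
        Whether the first line is a header of syscodes.

    Raises
    ------
    FlatFileParseError
        Ragged row (with its line number), fewer than two columns, or no
        column assignment at all.
    UnknownDataSourceError
        A column syscode absent from the registry.
    """
    path = Path(path)
    if not path.exists():
        raise MapperConnectionError(f"no such mapping file: {path}")
    with open(path, encoding="utf-8") as fh:
        # "##" lines are comments (fixture emitters record their seed there);
        # true file line numbers are kept for error messages
        numbered = [
            (no, ln)
            for no, ln in enumerate(fh.read().splitlines(), start=1)
            if not ln.startswith("##")
        ]

    if header:
        if not numbered:
            raise FlatFileParseError(f"{path}: empty file, expected a header line")
        if columns is None:
            columns = [c.strip() for c in numbered[0][1].split("\t")]
        numbered = numbered[1:]
    if columns is None:
        raise FlatFileParseError(f"{path}: headerless file needs a columns assignment")
    if len(columns) < 2:
        raise FlatFileParseError(f"{path}: a mapping file needs at least 2 columns")
    sources: list[DataSource] = [registry.by_syscode(c) for c in columns]

    mapper = MemoryLinkMapper(links=[])
    for lineno, line in numbered:
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != len(sources):
            raise FlatFileParseError(
                f"{path}:{lineno}: expected {len(sources)} cells, got {len(cells)}"
            )
        row_xrefs: list[Xref] = []
        for ds, cell in zip(sources, cells):
            if not cell:
                continue
            for token in cell.split(","):
                token = token.strip()
                if token:
                    row_xrefs.append(Xref(ds, token))
        # the row asserts co-reference: link every pair of its identifiers
        for i in range(len(row_xrefs)):
            for j in range(i + 1, len(row_xrefs)):
                if row_xrefs[i] != row_xrefs[j]:
                    mapper.add_link(row_xrefs[i], row_xrefs[j])
    return mapper


def dump_flatfile(mapper: MemoryLinkMapper, path: str | Path, columns: Sequence[str]) -> None:
    """Write a mapper's link set back to a TSV file, one row per link.

    Each row fills exactly the two cells of one stored link, so reloading
    reproduces the link set exactly (ingest is idempotent).
    """
    index = {c: i for i, c in enumerate(columns)}
    rows = []
    for pair in sorted(mapper.links, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        cells = [""] * len(columns)
        cells[index[a.syscode]] = a.identifier
        cells[index[b.syscode]] = b.identifier
        rows.append("\t".join(cells))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        fh.write("\n".join(rows))
        if rows:
            fh.write("\n")


def _connect_text(rest: str, registry: DataSourceRegistry) -> IDMapper:
    """Provider for ``idmapper-text:<path>[?columns=a,b,...][&header=false]``."""
    path, _, query = rest.partition("?")
    columns: Optional[list[str]] = None
    header = True
    if query:
        for part in query.split("&"):
            key, _, value = part.partition("=")
            if key == "columns":
                columns = value.split(",")
            elif key == "header":
                header = value.lower() not in {"false", "0", "no"}
            else:
                raise MapperConnectionError(f"unknown connection parameter {key!r}")
    return load_flatfile(path, registry, columns=columns, header=header)


register_provider("idmapper-text", _connect_text)
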