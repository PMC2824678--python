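"""Single-file embedded relational mapping database.

A mapping database is one file holding three tables plus a provenance
record:

* ``datanode`` — local identifiers, each tagged with its data-source
  syscode;
* ``link`` — cross-references between datanodes, stored once with a left
  and a right part and queried bidirectionally;
* ``attribute`` — symbols and other annotation for datanodes (the canonical
  attribute name for gene symbols and metabolite names is ``Symbol``);
* ``dbinfo`` — schema version, species (or ``"metabolites"``), build
  timestamp and a free-text provenance note.

Single-file databases can be copied and shipped easily, give the fastest
local access, and freeze a mapping snapshot so long-running analyses stay
reproducible. The physical engine here is SQLite; the three-table logical
schema is the contract, not the byte format. Files conventionally use the
``.xdb`` extension (documented, not enforced).
"""

from __future__ import annotations

import datetime
import os
import sqlite3
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .core import DataSource, DataSourceRegistry, Xref
from .errors import (
    DatabaseOpenError,
    MapperConnectionError,
    ReferentialIntegrityError,
    SchemaVersionError,
)
from .mapper import IDMapper, MappingCapabilities, register_provider

SCHEMA_VERSION = 1
SYMBOL_ATTR = "Symbol"


@dataclass(frozen=True)
class DataNodeRecord:
    identifier: str
    syscode: str


@dataclass(frozen=True)
class LinkRecord:
    left_id: str
    left_syscode: str
    right_id: str
    right_syscode: str

    @property
    def left(self) -> tuple[str, str]:
        return (self.left_id, self.left_syscode)

    @property
    def right(self) -> tuple[str, str]:
        return (self.right_id, self.right_syscode)


@dataclass(frozen=True)
class AttributeRecord:
    identifier: str
    syscode: str
    attr_name: str
    attr_value: str


@dataclass(frozen=True)
class DbInfo:
    schema_version: int = SCHEMA_VERSION
    species_name: str = "unspecified"
    build_timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    provenance: str = ""


_SCHEMA = """
CREATE TABLE datanode (
    identifier TEXT NOT NULL,
    syscode    TEXT NOT NULL,
    PRIMARY KEY (identifier, syscode)
);
CREATE TABLE link (
    left_id       TEXT NOT NULL,
    left_syscode  TEXT NOT NULL,
    right_id      TEXT NOT NULL,
    right_syscode TEXT NOT NULL,
    PRIMARY KEY (left_id, left_syscode, right_id, right_syscode)
);
CREATE INDEX ix_link_left  ON link (left_id, left_syscode);
CREATE INDEX ix_link_right ON link (right_id, right_syscode);
CREATE TABLE attribute (
    rowid_order INTEGER PRIMARY KEY AUTOINCREMENT,
    identifier  TEXT NOT NULL,
    syscode     TEXT NOT NULL,
    attr_name   TEXT NOT NULL,
    attr_value  TEXT NOT NULL
);
CREATE INDEX ix_attr_node ON attribute (identifier, syscode);
CREATE TABLE dbinfo (
    schema_version  INTEGER NOT NULL,
    species_name    TEXT NOT NULL,
    build_timestamp TEXT NOT NULL,
    provenance      TEXT NOT NULL
);
"""


def write_db(
    path: str | Path,
    datanodes: Iterable[DataNodeRecord],
    links: Iterable[LinkRecord],
    attributes: Iterable[AttributeRecord] = (),
    dbinfo: Optional[DbInfo] = None,
) -> Path:
    """Write a mapping database to ``path`` atomically.

    Records are validated first: every link endpoint and every attribute
    owner must exist in the datanode set. The database is built in a
    temporary file and moved into place, so a crash never leaves a partial
    file that opens as a valid database.

    Raises
    ------
    ReferentialIntegrityError
        A link or attribute references an identifier not in ``datanodes``.
    """
    path = Path(path)
    datanodes = list(dict.fromkeys(datanodes))
    links = list(dict.fromkeys(links))
    attributes = list(attributes)
    dbinfo = dbinfo or DbInfo()

    node_keys = {(n.identifier, n.syscode) for n in datanodes}
    for link in links:
        for end in (link.left, link.right):
            if end not in node_keys:
                raise ReferentialIntegrityError(
                    f"link endpoint {end!r} missing from datanode table"
                )
    for attr in attributes:
        if (attr.identifier, attr.syscode) not in node_keys:
            raise ReferentialIntegrityError(
                f"attribute owner {(attr.identifier, attr.syscode)!r} missing"
                " from datanode table"
            )

    fd, tmp_name = tempfile.mkstemp(dir=path.parent, suffix=".xdb.partial")
    os.close(fd)
    try:
        con = sqlite3.connect(tmp_name)
        try:
            con.executescript(_SCHEMA)
            con.executemany(
                "INSERT INTO datanode VALUES (?,?)",
                [(n.identifier, n.syscode) for n in datanodes],
            )
            con.executemany(
                "INSERT INTO link VALUES (?,?,?,?)",
                [(l.left_id, l.left_syscode, l.right_id, l.right_syscode) for l in links],
            )
            con.executemany(
                "INSERT INTO attribute (identifier, syscode, attr_name, attr_value)"
                " VALUES (?,?,?,?)",
                [(a.identifier, a.syscode, a.attr_name, a.attr_value) for a in attributes],
            )
            con.execute(
                "INSERT INTO dbinfo VALUES (?,?,?,?)",
                (
                    dbinfo.schema_version,
                    dbinfo.species_name,
                    dbinfo.build_timestamp,
                    dbinfo.provenance,
                ),
            )
            con.commit()
        finally:
            con.close()
        os.replace(tmp_name, path)
    except BaseException:
        if os.path.exists(tmp_name):
            os.unlink(tmp_name)
        raise
    return path


class SqliteMapper(IDMapper):
    """Mapper handle over an opened mapping-database file.

    ``map_id`` returns the right parts of links whose left part equals the
    query plus the left parts of links whose right part equals it
    (bidirectional query of links stored once). ``free_search`` consults the
    identifier column (case-insensitive exact) and ``Symbol`` attributes
    (case-insensitive substring).
    """

    def __init__(self, path: str | Path, registry: DataSourceRegistry) -> None:
        super().__init__()
        self._path = Path(path)
        self._registry = registry
        self._con = sqlite3.connect(f"file:{self._path}?mode=ro", uri=True)

    def close(self) -> None:
        if not self._closed:
            self._con.close()
        super().close()

    @property
    def path(self) -> Path:
        return self._path

    def dbinfo(self) -> DbInfo:
        self._check_open()
        row = self._con.execute(
            "SELECT schema_version, species_name, build_timestamp, provenance FROM dbinfo"
        ).fetchone()
        return DbInfo(*row)

    # -- record extraction (round-trip support) ----------------------------

    def read_datanodes(self) -> list[DataNodeRecord]:
        self._check_open()
        rows = self._con.execute("SELECT identifier, syscode FROM datanode").fetchall()
        return [DataNodeRecord(*r) for r in rows]

    def read_links(self) -> list[LinkRecord]:
        self._check_open()
        rows = self._con.execute(
            "SELECT left_id, left_syscode, right_id, right_syscode FROM link"
        ).fetchall()
        return [LinkRecord(*r) for r in rows]

    def read_attributes(self) -> list[AttributeRecord]:
        self._check_open()
        rows = self._con.execute(
            "SELECT identifier, syscode, attr_name, attr_value FROM attribute"
            " ORDER BY rowid_order"
        ).fetchall()
        return [AttributeRecord(*r) for r in rows]

    # -- contract ----------------------------------------------------------

    def _map_id_open(self, x: Xref, targets: frozenset[DataSource]) -> Iterable[Xref]:
        hits: set[Xref] = set()
        for sql, args in (
            (
                "SELECT right_id, right_syscode FROM link"
                " WHERE left_id=? AND left_syscode=?",
                (x.identifier, x.syscode),
            ),
            (
                "SELECT left_id, left_syscode FROM link"
                " WHERE right_id=? AND right_syscode=?",
                (x.identifier, x.syscode),
            ),
        ):
            for identifier, syscode in self._con.execute(sql, args):
                # x itself can only appear here via an explicitly stored
                # self-link row, which is then returned as stored
                hits.add(Xref(self._registry.by_syscode(syscode), identifier))
        if targets:
            hits = {h for h in hits if h.datasource in targets}
        return hits

    def _free_search_open(self, query: str) -> Iterable[Xref]:
        for identifier, syscode in self._con.execute(
            "SELECT identifier, syscode FROM datanode WHERE identifier = ? COLLATE NOCASE",
            (query,),
        ):
            yield Xref(self._registry.by_syscode(syscode), identifier)
        for identifier, syscode in self._con.execute(
            "SELECT DISTINCT identifier, syscode FROM attribute"
            " WHERE attr_name = ? AND instr(lower(attr_value), lower(?)) > 0",
            (SYMBOL_ATTR, query),
        ):
            yield Xref(self._registry.by_syscode(syscode), identifier)

    def _attributes_open(self, x: Xref) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, value in self._con.execute(
            "SELECT attr_name, attr_value FROM attribute"
            " WHERE identifier=? AND syscode=? ORDER BY rowid_order",
            (x.identifier, x.syscode),
        ):
            out.setdefault(name, []).append(value)
        return out

    def _iter_xrefs_open(self, datasource: Optional[DataSource]):
        if datasource is None:
            sql, args = "SELECT identifier, syscode FROM datanode ORDER BY syscode, identifier", ()
        else:
            sql, args = (
                "SELECT identifier, syscode FROM datanode WHERE syscode=? ORDER BY identifier",
                (datasource.syscode,),
            )
        for identifier, syscode in self._con.execute(sql, args):
            yield Xref(self._registry.by_syscode(syscode), identifier)

    def capabilities(self) -> MappingCapabilities:
        self._check_open()
        codes = {
            c
            for (c,) in self._con.execute(
                "SELECT left_syscode FROM link UNION SELECT right_syscode FROM link"
            )
        }
        present = frozenset(self._registry.by_syscode(c) for c in codes)
        return MappingCapabilities(
            source_datasources=present,
            target_datasources=present,
            supports_free_search=True,
        )


def open_db(path: str | Path, registry: Optional[DataSourceRegistry] = None) -> SqliteMapper:
    """Open a mapping-database file as a mapper handle.

    Raises
    ------
    DatabaseOpenError
        Missing file, or a file that is not a mapping database.
    SchemaVersionError
        A database with a schema version this code does not support.
    """
    path = Path(path)
    if registry is None:
        from .core import default_registry

        registry = default_registry()
    if not path.exists():
        raise DatabaseOpenError(f"no such database file: {path}")
    mapper = SqliteMapper(path, registry)
    try:
        row = mapper._con.execute("SELECT schema_version FROM dbinfo").fetchone()
    except sqlite3.DatabaseError as exc:
        mapper.close()
        raise DatabaseOpenError(f"{path} is not a mapping database: {exc}") from exc
    if row is None or row[0] != SCHEMA_VERSION:
        mapper.close()
        raise SchemaVersionError(
            f"{path}: schema version {row[0] if row else 'missing'},"
            f" expected {SCHEMA_VERSION}"
        )
    return mapper


def _connect_db(rest: str, registry: DataSourceRegistry) -> IDMapper:
    """Provider for ``idmapper-db:<path to .xdb file>``."""
    try:
        return open_db(rest, registry)
    except (DatabaseOpenError, SchemaVersionError) as exc:
        raise MapperConnectionError(str(exc)) from exc


register_provider("idmapper-db", _connect_db)


# -- convenience builders --------------------------------------------------


def records_from_links(
    link_pairs: Iterable[tuple[Xref, Xref]],
    attributes: Optional[dict[Xref, dict[str, list[str]]]] = None,
) -> tuple[list[DataNodeRecord], list[LinkRecord], list[AttributeRecord]]:
    """Derive table records from Xref link pairs (endpoints become nodes)."""
    nodes: dict[tuple[str, str], DataNodeRecord] = {}
    links: list[LinkRecord] = []
    seen: set[frozenset[Xref]] = set()
    for left, right in link_pairs:
        key = frozenset((left, right))
        for x in (left, right):
            nodes.setdefault((x.identifier, x.syscode), DataNodeRecord(x.identifier, x.syscode))
        if key in seen:
            continue
        seen.add(key)
        a, b = sorted((left, right))
        links.append(LinkRecord(a.identifier, a.syscode, b.identifier, b.syscode))
    attr_records: list[AttributeRecord] = []
    for x, attrs in (attributes or {}).items():
        nodes.setdefault((x.identifier, x.syscode), DataNodeRecord(x.identifier, x.syscode))
        for name, values in attrs.items():
            for value in values:
                attr_records.append(AttributeRecord(x.identifier, x.syscode, name, value))
    return list(nodes.values()), links, attr_records
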