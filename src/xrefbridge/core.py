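"""Data-source registry and the Xref global-identifier type.

The mapping problem starts from a simple observation: an *internal*
identifier (``1234``, ``P62158``) is only meaningful within the namespace of
one data source, and the same string may be a valid identifier in several
sources at once. A *global* identifier is therefore the pair (data source,
internal identifier), here modelled by :class:`Xref`. Global identifiers are
serialised as MIRIAM URNs of the form ``urn:miriam:<namespace>:<identifier>``
(e.g. ``urn:miriam:uniprot:P62158``).

Data sources themselves are described by :class:`DataSource` records held in
a :class:`DataSourceRegistry`. A default registry covering the common gene,
protein, probe and metabolite databases ships with the package as an editable
TSV file (``data/datasources.tsv``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional
from urllib.parse import quote

from .errors import (
    NoUrnAvailableError,
    RegistrationConflictError,
    UnknownDataSourceError,
    UrnParseError,
)

URN_PREFIX = "urn:miriam:"
URL_PLACEHOLDER = "$id"

ENTITY_CATEGORIES = frozenset({"gene", "protein", "metabolite", "probe", "other"})


@dataclass(frozen=True)
class DataSource:
    """One identifier namespace: a database of biological entities.

    Parameters
    ----------
    syscode:
        Short unique code for the source, 1-3 characters (``"En"`` for
        Ensembl, ``"L"`` for Entrez Gene, ...).
    full_name:
        Human-readable name, unique within a registry.
    miriam_base:
        Lowercase MIRIAM namespace token (``"uniprot"``), or ``None`` when
        the source has no registered URN namespace.
    url_pattern:
        Link-out template containing exactly one ``$id`` placeholder, or
        ``None``.
    entity_category:
        One of ``gene``, ``protein``, ``metabolite``, ``probe``, ``other``.
    id_example:
        Optional example identifier, for display and documentation.
    """

    syscode: str
    full_name: str
    miriam_base: Optional[str] = None
    url_pattern: Optional[str] = None
    entity_category: str = "other"
    id_example: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.syscode) <= 3):
            raise ValueError(f"syscode must be 1-3 characters, got {self.syscode!r}")
        if not self.full_name:
            raise ValueError("full_name must be non-empty")
        if self.miriam_base is not None:
            if not self.miriam_base or self.miriam_base != self.miriam_base.lower():
                raise ValueError(
                    f"miriam_base must be non-empty lowercase, got {self.miriam_base!r}"
                )
        if self.url_pattern is not None and self.url_pattern.count(URL_PLACEHOLDER) != 1:
            raise ValueError(
                f"url_pattern must contain exactly one {URL_PLACEHOLDER!r} placeholder"
            )
        if self.entity_category not in ENTITY_CATEGORIES:
            raise ValueError(f"unknown entity_category {self.entity_category!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DataSource({self.syscode}:{self.full_name})"


class Xref:
    """Global identifier: a (data source, internal identifier) pair.

    Equality and hashing use the ``(syscode, identifier)`` pair — never the
    identifier alone, since the same internal identifier may be valid in two
    different sources. Identifiers are opaque tokens: comparison is
    case-sensitive and whitespace-exact.
    """

    __slots__ = ("datasource", "identifier")

    def __init__(self, datasource: DataSource, identifier: str) -> None:
        if not identifier:
            raise ValueError("identifier must be non-empty")
        object.__setattr__(self, "datasource", datasource)
        object.__setattr__(self, "identifier", identifier)

    def __setattr__(self, name: str, value: object) -> None:
        raise AttributeError("Xref is immutable")

    @property
    def syscode(self) -> str:
        return self.datasource.syscode

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Xref):
            return NotImplemented
        return (self.datasource.syscode, self.identifier) == (
            other.datasource.syscode,
            other.identifier,
        )

    def __hash__(self) -> int:
        return hash((self.datasource.syscode, self.identifier))

    def __lt__(self, other: "Xref") -> bool:
        return (self.syscode, self.identifier) < (other.syscode, other.identifier)

    def __repr__(self) -> str:
        return f"Xref({self.datasource.syscode}:{self.identifier})"

    def to_miriam_urn(self) -> str:
        """Serialise as ``urn:miriam:<namespace>:<identifier>``.

        Raises
        ------
        NoUrnAvailableError
            If the data source has no MIRIAM namespace.
        """
        base = self.datasource.miriam_base
        if base is None:
            raise NoUrnAvailableError(
                f"data source {self.datasource.full_name!r} has no MIRIAM namespace"
            )
        return f"{URN_PREFIX}{base}:{self.identifier}"

    def link_out_url(self) -> Optional[str]:
        """Web link to the entity page, or ``None`` if no template exists.

        URL-reserved characters in the identifier are percent-encoded.
        """
        pattern = self.datasource.url_pattern
        if pattern is None:
            return None
        return pattern.replace(URL_PLACEHOLDER, quote(self.identifier, safe=""))


def to_miriam_urn(x: Xref) -> str:
    """Functional alias for :meth:`Xref.to_miriam_urn`."""
    return x.to_miriam_urn()


def link_out_url(x: Xref) -> Optional[str]:
    """Functional alias for :meth:`Xref.link_out_url`."""
    return x.link_out_url()


class DataSourceRegistry:
    """Mutable registry of :class:`DataSource` records.

    Both syscode and full name are unique keys. Re-registering an identical
    record is a no-op; registering a conflicting record under an existing key
    raises :class:`RegistrationConflictError`.
    """

    def __init__(self, sources: Optional[list[DataSource]] = None) -> None:
        self._by_syscode: dict[str, DataSource] = {}
        self._by_full_name: dict[str, DataSource] = {}
        self._by_miriam: dict[str, DataSource] = {}
        for ds in sources or []:
            self.register(ds)

    def register(self, ds: DataSource) -> "DataSourceRegistry":
        existing = self._by_syscode.get(ds.syscode)
        if existing is not None:
            if existing == ds:
                return self
            raise RegistrationConflictError(
                f"syscode {ds.syscode!r} already registered as {existing.full_name!r}"
            )
        by_name = self._by_full_name.get(ds.full_name)
        if by_name is not None:
            raise RegistrationConflictError(
                f"full name {ds.full_name!r} already registered under syscode"
                f" {by_name.syscode!r}"
            )
        self._by_syscode[ds.syscode] = ds
        self._by_full_name[ds.full_name] = ds
        if ds.miriam_base is not None:
            self._by_miriam[ds.miriam_base] = ds
        return self

    def by_syscode(self, syscode: str) -> DataSource:
        try:
            return self._by_syscode[syscode]
        except KeyError:
            raise UnknownDataSourceError(f"unknown syscode {syscode!r}") from None

    def by_full_name(self, full_name: str) -> DataSource:
        try:
            return self._by_full_name[full_name]
        except KeyError:
            raise UnknownDataSourceError(f"unknown data source {full_name!r}") from None

    def by_miriam_base(self, base: str) -> DataSource:
        try:
            return self._by_miriam[base]
        except KeyError:
            raise UnknownDataSourceError(f"unknown MIRIAM namespace {base!r}") from None

    def __contains__(self, syscode: str) -> bool:
        return syscode in self._by_syscode

    def __iter__(self) -> Iterator[DataSource]:
        return iter(self._by_syscode.values())

    def __len__(self) -> int:
        return len(self._by_syscode)

    def xref(self, syscode: str, identifier: str) -> Xref:
        """Build an Xref, resolving the syscode through the registry."""
        return Xref(self.by_syscode(syscode), identifier)

    def parse_miriam_urn(self, urn: str) -> Xref:
        """Parse ``urn:miriam:<namespace>:<identifier>`` back to an Xref.

        The identifier part is everything after the third colon, so
        identifiers containing colons survive a round trip.
        """
        if not urn.startswith(URN_PREFIX):
            raise UrnParseError(f"not a MIRIAM URN: {urn!r}")
        rest = urn[len(URN_PREFIX):]
        base, sep, identifier = rest.partition(":")
        if not sep or not base or not identifier:
            raise UrnParseError(f"malformed MIRIAM URN: {urn!r}")
        return Xref(self.by_miriam_base(base), identifier)


def register_datasource(registry: DataSourceRegistry, ds: DataSource) -> DataSourceRegistry:
    """Register ``ds`` in ``registry`` and return the registry."""
    return registry.register(ds)


def parse_miriam_urn(registry: DataSourceRegistry, urn: str) -> Xref:
    """Functional alias for :meth:`DataSourceRegistry.parse_miriam_urn`."""
    return registry.parse_miriam_urn(urn)


def load_registry(path: str | Path) -> DataSourceRegistry:
    """Load a registry from a tab-delimited config file.

    Columns: ``syscode``, ``full_name``, ``miriam_base``, ``url_pattern``,
    ``entity_category``, ``id_example``; empty cells mean "absent". Lines
    starting with ``#`` are comments.
    """
    registry = DataSourceRegistry()
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = rows[0]
    for row in rows[1:]:
        rec = dict(zip(header, row))
        registry.register(
            DataSource(
                syscode=rec["syscode"],
                full_name=rec["full_name"],
                miriam_base=rec.get("miriam_base") or None,
                url_pattern=rec.get("url_pattern") or None,
                entity_category=rec.get("entity_category") or "other",
                id_example=rec.get("id_example") or None,
            )
        )
    return registry


def default_registry() -> DataSourceRegistry:
    """The registry shipped with the package (common gene, protein, probe
    and metabolite databases). Returns a fresh mutable copy each call."""
    ref = resources.files("xrefbridge").joinpath("data/datasources.tsv")
    with resources.as_file(ref) as path:
        return load_registry(path)
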