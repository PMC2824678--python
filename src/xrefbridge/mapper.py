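"""The uniform mapper contract and connection-string dispatch.

Every mapping backend — a flat annotation file, an embedded database, a
stack of other mappers, a remote-service adapter — implements the same
:class:`IDMapper` contract: ``map_id`` translates one global identifier into
the set of identifiers it cross-references, ``free_search`` finds
identifiers by text, and ``capabilities`` reports which source→target
datasource pairs the backend can translate. Callers never branch on backend
type; to switch services they change a connection string:

>>> mapper = connect("idmapper-text:/path/to/annotations.tsv")

Connection strings have the form ``<provider>:<rest>`` (split at the first
colon). Providers register themselves in a dispatch table at import time;
third-party backends can call :func:`register_provider`.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional

from .core import DataSource, DataSourceRegistry, Xref, default_registry
from .errors import (
    ClosedHandleError,
    InvalidQueryError,
    UnknownProviderError,
)


@dataclass(frozen=True)
class MappingCapabilities:
    """Introspection record for one mapper.

    ``is_mapping_supported(s, t)`` defaults to membership of ``s`` in the
    source set and ``t`` in the target set; backends with a finer-grained
    predicate may override it, but only to be more restrictive.
    """

    source_datasources: frozenset[DataSource]
    target_datasources: frozenset[DataSource]
    supports_free_search: bool = True

    def is_mapping_supported(self, source: DataSource, target: DataSource) -> bool:
        return source in self.source_datasources and target in self.target_datasources


class IDMapper(ABC):
    """Abstract mapper handle.

    Subclasses implement :meth:`_map_id_open`, :meth:`_free_search_open` and
    :meth:`capabilities`; the base class enforces the open/closed state and
    argument contracts shared by all backends.
    """

    def __init__(self) -> None:
        self._closed = False

    # -- lifecycle ---------------------------------------------------------

    @property
    def closed(self) -> bool:
        return self._closed

    def close(self) -> None:
        self._closed = True

    def _check_open(self) -> None:
        if self._closed:
            raise ClosedHandleError(f"{type(self).__name__} handle is closed")

    def __enter__(self) -> "IDMapper":
        return self

    def __exit__(self, *exc: object) -> None:
        self.close()

    # -- contract ----------------------------------------------------------

    def map_id(self, x: Xref, targets: frozenset[DataSource] = frozenset()) -> frozenset[Xref]:
        """All Xrefs this backend maps ``x`` to, restricted to ``targets``.

        An empty ``targets`` set means no restriction. The result never
        contains ``x`` itself unless the backend stores an explicit
        self-link.
        """
        self._check_open()
        targets = frozenset(targets)
        return frozenset(self._map_id_open(x, targets))

    def map_ids(
        self,
        xs: Iterable[Xref],
        targets: frozenset[DataSource] = frozenset(),
    ) -> dict[Xref, frozenset[Xref]]:
        """Batch form of :meth:`map_id`; result equals a per-item loop."""
        self._check_open()
        targets = frozenset(targets)
        return {x: self.map_id(x, targets) for x in set(xs)}

    def free_search(self, query: str, limit: int = 100) -> frozenset[Xref]:
        """Xrefs whose identifier equals ``query`` (case-insensitive) or
        whose Symbol attribute contains it (case-insensitive substring), at
        most ``limit`` results.

        When the match count exceeds ``limit``, results are truncated after
        sorting by ``(syscode, identifier)`` so output is deterministic.
        """
        self._check_open()
        if not query:
            raise InvalidQueryError("free_search query must be non-empty")
        if limit < 1:
            raise InvalidQueryError("limit must be a positive integer")
        hits = sorted(set(self._free_search_open(query)))
        return frozenset(hits[:limit])

    def get_attributes(
        self, x: Xref, attr_name: Optional[str] = None
    ) -> "list[str] | dict[str, list[str]]":
        """Attribute values for ``x``: a list for one ``attr_name``, or a
        name→values dict for all. Backends without attributes return empty."""
        self._check_open()
        all_attrs = self._attributes_open(x)
        if attr_name is None:
            return all_attrs
        return all_attrs.get(attr_name, [])

    def iter_xrefs(self, datasource: Optional[DataSource] = None) -> Iterator[Xref]:
        """Iterate all Xrefs known to the backend (optionally one source).

        Supported by local backends; used for query sampling.
        """
        self._check_open()
        yield from self._iter_xrefs_open(datasource)

    @abstractmethod
    def capabilities(self) -> MappingCapabilities:
        """Supported source/target datasources and free-search support."""

    # -- backend hooks -----------------------------------------------------

    @abstractmethod
    def _map_id_open(self, x: Xref, targets: frozenset[DataSource]) -> Iterable[Xref]:
        ...

    @abstractmethod
    def _free_search_open(self, query: str) -> Iterable[Xref]:
        ...

    def _attributes_open(self, x: Xref) -> dict[str, list[str]]:
        return {}

    def _iter_xrefs_open(self, datasource: Optional[DataSource]) -> Iterator[Xref]:
        raise NotImplementedError(f"{type(self).__name__} cannot enumerate its Xrefs")


class MemoryLinkMapper(IDMapper):
    """In-memory mapper over an explicit symmetric link set.

    The workhorse behind the flat-file backend, stacks of parsed fixtures
    and mock remote services: links are stored once as unordered Xref pairs
    and queried bidirectionally.
    """

    def __init__(
        self,
        links: Iterable[tuple[Xref, Xref]],
        attributes: Optional[dict[Xref, dict[str, list[str]]]] = None,
    ) -> None:
        super().__init__()
        self._adjacency: dict[Xref, set[Xref]] = {}
        self._links: set[frozenset[Xref]] = set()
        for left, right in links:
            self.add_link(left, right)
        self._attributes: dict[Xref, dict[str, list[str]]] = attributes or {}
        for x in self._attributes:
            self._adjacency.setdefault(x, set())

    def add_link(self, left: Xref, right: Xref) -> None:
        self._adjacency.setdefault(left, set()).add(right)
        self._adjacency.setdefault(right, set()).add(left)
        self._links.add(frozenset((left, right)))

    @property
    def links(self) -> frozenset[frozenset[Xref]]:
        """The stored link set, as unordered pairs."""
        return frozenset(self._links)

    def _map_id_open(self, x: Xref, targets: frozenset[DataSource]) -> Iterable[Xref]:
        hits = self._adjacency.get(x, set())
        if targets:
            hits = {h for h in hits if h.datasource in targets}
        return hits

    def _free_search_open(self, query: str) -> Iterable[Xref]:
        q = query.lower()
        for x in self._adjacency:
            if x.identifier.lower() == q:
                yield x
                continue
            for value in self._attributes.get(x, {}).get("Symbol", []):
                if q in value.lower():
                    yield x
                    break

    def _attributes_open(self, x: Xref) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._attributes.get(x, {}).items()}

    def _iter_xrefs_open(self, datasource: Optional[DataSource]) -> Iterator[Xref]:
        for x in sorted(self._adjacency):
            if datasource is None or x.datasource == datasource:
                yield x

    def capabilities(self) -> MappingCapabilities:
        self._check_open()
        # Links are queried bidirectionally, so every datasource touching a
        # link is both a valid query source and a reachable target.
        present = frozenset(x.datasource for pair in self._links for x in pair)
        return MappingCapabilities(
            source_datasources=present,
            target_datasources=present,
            supports_free_search=True,
        )


# -- connection-string dispatch -------------------------------------------

ProviderFactory = Callable[[str, DataSourceRegistry], IDMapper]

_PROVIDERS: dict[str, ProviderFactory] = {}


def register_provider(name: str, factory: ProviderFactory) -> None:
    """Register a backend under a connection-string provider name."""
    _PROVIDERS[name] = factory


def registered_providers() -> tuple[str, ...]:
    return tuple(sorted(_PROVIDERS))


def connect(
    connection_string: str,
    registry: Optional[DataSourceRegistry] = None,
) -> IDMapper:
    """Open a mapper from a ``<provider>:<params>`` connection string.

    To access a different mapping service only the connection string needs
    to change; the handle returned always satisfies the same contract.

    Raises
    ------
    UnknownProviderError
        If the provider prefix is not registered.
    MapperConnectionError
        If the provider rejects its parameters (missing file, bad schema...).
    """
    provider, sep, rest = connection_string.partition(":")
    if not sep or provider not in _PROVIDERS:
        raise UnknownProviderError(
            f"unknown provider in connection string {connection_string!r};"
            f" registered providers: {', '.join(registered_providers()) or 'none'}"
        )
    if registry is None:
        registry = default_registry()
    return _PROVIDERS[provider](rest, registry)
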