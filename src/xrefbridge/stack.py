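"""Stack several mapping services behind one handle.

Stacking presents a list of member mappers as a single mapper. Two modes:

* **non-transitive** — the stack's answer is the plain union of each
  member's answer;
* **transitive** — the stack additionally infers second- and third-degree
  mappings: if one member maps custom probe C1 to an Entrez Gene identifier
  and another maps that Entrez Gene identifier to an Ensembl gene, then
  C1 ↔ Ensembl is inferred even though no single member stores it. This is
  what lets a minimal custom annotation file (custom id → one gene id)
  piggyback on a comprehensive gene database for everything else.

Inference is a breadth-first traversal of at most ``max_degree`` mapping
steps; each step may use any member, and intermediate identifiers may
belong to any data source, including ones not requested as targets (they
are traversal-only). A visited set guarantees termination on cyclic mapping
graphs. Results are sets — duplicates across members and paths collapse.

:func:`transitive_closure_oracle` is an independent brute-force check:
it pools all member links into one undirected graph and asks networkx for
the shortest-path reachable set, bypassing the stack's own traversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .core import DataSource, Xref
from .errors import InvalidStackError
from .mapper import IDMapper, MappingCapabilities

MAX_DEGREE_LIMIT = 3
DEFAULT_MAX_DEGREE = 2


@dataclass(frozen=True)
class MappingResult:
    """A mapped Xref with display-only provenance.

    ``provenance`` is ``"direct"`` when some member stores the link in one
    step and ``"inferred"`` when only a multi-step path produced it; it
    never affects set membership.
    """

    xref: Xref
    provenance: str  # "direct" | "inferred"


class StackMapper(IDMapper):
    """One mapper handle over an ordered list of member handles."""

    def __init__(
        self,
        members: Sequence[IDMapper],
        transitive: bool = False,
        max_degree: int = DEFAULT_MAX_DEGREE,
    ) -> None:
        super().__init__()
        members = list(members)
        if not members:
            raise InvalidStackError("a stack needs at least one member")
        if not (1 <= max_degree <= MAX_DEGREE_LIMIT):
            raise InvalidStackError(
                f"max_degree must be in 1..{MAX_DEGREE_LIMIT}, got {max_degree}"
            )
        for m in members:
            if m.closed:
                raise InvalidStackError("all stack members must be open")
        self.members = members
        self.transitive = transitive
        self.max_degree = max_degree

    # -- traversal ---------------------------------------------------------

    def _neighbours(self, x: Xref) -> set[Xref]:
        out: set[Xref] = set()
        for member in self.members:
            out |= member.map_id(x)
        return out

    def _reachable(self, x: Xref, max_degree: int) -> set[Xref]:
        """All Xrefs within ``max_degree`` mapping steps of ``x`` (x excluded)."""
        visited = {x}
        frontier = {x}
        found: set[Xref] = set()
        for _ in range(max_degree):
            nxt: set[Xref] = set()
            for y in frontier:
                nxt |= self._neighbours(y)
            nxt -= visited
            visited |= nxt
            found |= nxt
            frontier = nxt
            if not frontier:
                break
        return found

    def _map_id_open(self, x: Xref, targets: frozenset[DataSource]) -> Iterable[Xref]:
        if self.transitive:
            hits = self._reachable(x, self.max_degree)
        else:
            hits = self._neighbours(x)
        hits.discard(x)
        if targets:
            hits = {h for h in hits if h.datasource in targets}
        return hits

    def map_id_with_provenance(
        self, x: Xref, targets: frozenset[DataSource] = frozenset()
    ) -> frozenset[MappingResult]:
        """Like :meth:`map_id` but tags each hit direct vs inferred."""
        self._check_open()
        direct = self._neighbours(x)
        return frozenset(
            MappingResult(h, "direct" if h in direct else "inferred")
            for h in self.map_id(x, targets)
        )

    # -- rest of the contract ---------------------------------------------

    def _free_search_open(self, query: str) -> Iterable[Xref]:
        for member in self.members:
            yield from member.free_search(query, limit=10**9)

    def _attributes_open(self, x: Xref) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member in self.members:
            attrs = member.get_attributes(x)
            for name, values in attrs.items():
                bucket = out.setdefault(name, [])
                for v in values:
                    if v not in bucket:
                        bucket.append(v)
        return out

    def _iter_xrefs_open(self, datasource: Optional[DataSource]) -> Iterator[Xref]:
        seen: set[Xref] = set()
        for member in self.members:
            try:
                for x in member.iter_xrefs(datasource):
                    if x not in seen:
                        seen.add(x)
                        yield x
            except NotImplementedError:
                continue

    def capabilities(self) -> MappingCapabilities:
        self._check_open()
        sources: set[DataSource] = set()
        targets: set[DataSource] = set()
        edges: set[tuple[DataSource, DataSource]] = set()
        free = False
        for member in self.members:
            caps = member.capabilities()
            sources |= caps.source_datasources
            targets |= caps.target_datasources
            free = free or caps.supports_free_search
            for s in caps.source_datasources:
                for t in caps.target_datasources:
                    if caps.is_mapping_supported(s, t):
                        edges.add((s, t))
        if not self.transitive:
            return _PairCapabilities(
                frozenset(sources), frozenset(targets), free, frozenset(edges)
            )
        # transitive closure at the datasource level: s→t supported if a
        # chain of <= max_degree member-supported steps connects them
        composed: set[tuple[DataSource, DataSource]] = set(edges)
        reach: dict[DataSource, set[DataSource]] = {}
        for s, t in edges:
            reach.setdefault(s, set()).add(t)
        for s in list(reach):
            frontier_s = set(reach[s])
            for _ in range(self.max_degree - 1):
                nxt: set[DataSource] = set()
                for mid in frontier_s:
                    nxt |= reach.get(mid, set())
                nxt -= reach[s]
                if not nxt:
                    break
                reach[s] |= nxt
                frontier_s = nxt
            for t in reach[s]:
                composed.add((s, t))
        all_sources = frozenset(s for s, _ in composed) | frozenset(sources)
        all_targets = frozenset(t for _, t in composed) | frozenset(targets)
        return _PairCapabilities(all_sources, all_targets, free, frozenset(composed))


class _PairCapabilities(MappingCapabilities):
    """Capabilities with an explicit supported-pair set (more restrictive
    than the source x target cross product, as the contract allows)."""

    def __init__(
        self,
        sources: frozenset[DataSource],
        targets: frozenset[DataSource],
        free: bool,
        pairs: frozenset[tuple[DataSource, DataSource]],
    ) -> None:
        super().__init__(sources, targets, free)
        object.__setattr__(self, "supported_pairs", pairs)

    def is_mapping_supported(self, source: DataSource, target: DataSource) -> bool:
        return (source, target) in self.supported_pairs


def stack(
    members: Sequence[IDMapper],
    transitive: bool = False,
    max_degree: int = DEFAULT_MAX_DEGREE,
) -> StackMapper:
    """Combine ``members`` into one mapper handle."""
    return StackMapper(members, transitive=transitive, max_degree=max_degree)


def map_id_stack(
    stack_handle: StackMapper,
    x: Xref,
    targets: frozenset[DataSource] = frozenset(),
) -> frozenset[Xref]:
    """Functional alias for ``stack_handle.map_id(x, targets)``."""
    return stack_handle.map_id(x, targets)


def transitive_closure_oracle(
    links: Iterable[tuple[Xref, Xref]],
    x: Xref,
    max_degree: int,
) -> frozenset[Xref]:
    """Brute-force reference answer for transitive stacking.

    Pools all links into one undirected graph and returns every Xref within
    ``max_degree`` hops of ``x`` (``x`` itself excluded), using networkx
    shortest paths — a route independent of the stack's frontier traversal.
    Intended for small instances (<= 1e4 links).
    """
    graph: nx.Graph = nx.Graph()
    graph.add_edges_from(links)
    if x not in graph:
        return frozenset()
    depths = nx.single_source_shortest_path_length(graph, x, cutoff=max_degree)
    return frozenset(node for node, depth in depths.items() if depth > 0)
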