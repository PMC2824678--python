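"""Deterministic synthetic mapping worlds for testing and evaluation.

A *world* emulates the situation every mapping service samples from: a set
of ground-truth biological entities (genes or metabolites), each carrying
one identifier in a random subset of data sources. The ground truth links
all identifiers of an entity pairwise; each mapper *shard* is an imperfect
copy of the ground truth that independently drops each link with a fixed
probability, the way real services differ in coverage. Worlds are fully
reproducible from ``(spec, seed)``, and emitters write them out in every
format the package reads: flat annotation files, embedded databases, and
metabolite card files.

Identifier strings are cosmetic (``En00042``-style); each entity also gets
a symbol (``GN00042``) plus one synonym, attached as ``Symbol`` attributes
by the database emitter so free search is exercised end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core import DataSource, DataSourceRegistry, Xref, default_registry
from .errors import InvalidSpecError
from .metabocard import MetaboCard, format_metabocard
from .store import DbInfo, records_from_links, write_db

# preferred draw order for generated worlds, by entity category
GENE_SOURCE_CODES = ("En", "L", "S", "U", "Q", "Mb", "X", "Ag", "Il")
METABOLITE_SOURCE_CODES = ("Ch", "Ca", "Ce", "Cp", "Ck")

LinkPair = tuple[Xref, Xref]


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Parameters of a synthetic mapping world."""

    n_datasources: int = 4
    n_entities: int = 50
    xrefs_per_entity_range: tuple[int, int] = (2, 4)
    missing_edge_prob: float = 0.1
    n_shards: int = 2
    seed: int = 0
    entity_category: str = "gene"  # "gene" or "metabolite"

    def __post_init__(self) -> None:
        if self.n_datasources < 1 or self.n_entities < 1 or self.n_shards < 1:
            raise InvalidSpecError("counts must be positive")
        lo, hi = self.xrefs_per_entity_range
        if not (1 <= lo <= hi):
            raise InvalidSpecError("xrefs_per_entity_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.missing_edge_prob <= 1.0):
            raise InvalidSpecError("missing_edge_prob must be a probability")
        if self.entity_category not in ("gene", "metabolite"):
            raise InvalidSpecError("entity_category must be 'gene' or 'metabolite'")


@dataclass
class MappingWorld:
    """A generated world: ground truth plus imperfect mapper shards."""

    spec: SyntheticGraphSpec
    datasources: list[DataSource]
    entities: list[list[Xref]]          # one identifier list per entity
    entity_symbols: list[list[str]]     # [name, synonym, ...] per entity
    ground_truth: list[LinkPair]
    shards: list[list[LinkPair]]

    @property
    def syscodes(self) -> list[str]:
        return [ds.syscode for ds in self.datasources]

    def symbol_attributes(self) -> dict[Xref, dict[str, list[str]]]:
        """Symbol attributes for every identifier, keyed by Xref."""
        out: dict[Xref, dict[str, list[str]]] = {}
        for xrefs, symbols in zip(self.entities, self.entity_symbols):
            for x in xrefs:
                out[x] = {"Symbol": list(symbols)}
        return out


def _identifier(ds: DataSource, entity_index: int) -> str:
    return f"{ds.syscode}{entity_index:05d}"


def generate_mapping_world(
    spec: SyntheticGraphSpec,
    registry: Optional[DataSourceRegistry] = None,
) -> MappingWorld:
    """Generate a reproducible world from a spec.

    Each entity receives one identifier in a random subset of the world's
    data sources (subset size drawn from ``xrefs_per_entity_range``); the
    ground truth links all identifiers of an entity pairwise; each shard
    keeps each ground-truth link independently with probability
    ``1 - missing_edge_prob``.
    """
    if registry is None:
        registry = default_registry()
    codes = (
        GENE_SOURCE_CODES if spec.entity_category == "gene" else METABOLITE_SOURCE_CODES
    )
    if spec.n_datasources > len(codes):
        raise InvalidSpecError(
            f"at most {len(codes)} {spec.entity_category} data sources available,"
            f" requested {spec.n_datasources}"
        )
    datasources = [registry.by_syscode(c) for c in codes[: spec.n_datasources]]
    rng = random.Random(spec.seed)

    sym_prefix = "GN" if spec.entity_category == "gene" else "MB"
    entities: list[list[Xref]] = []
    entity_symbols: list[list[str]] = []
    ground_truth: list[LinkPair] = []
    for i in range(spec.n_entities):
        lo, hi = spec.xrefs_per_entity_range
        k = min(rng.randint(lo, hi), spec.n_datasources)
        chosen = sorted(rng.sample(datasources, k), key=lambda d: d.syscode)
        xrefs = [Xref(ds, _identifier(ds, i)) for ds in chosen]
        entities.append(xrefs)
        entity_symbols.append([f"{sym_prefix}{i:05d}", f"{sym_prefix}{i:05d}-alt"])
        for a in range(len(xrefs)):
            for b in range(a + 1, len(xrefs)):
                ground_truth.append((xrefs[a], xrefs[b]))

    shards: list[list[LinkPair]] = []
    for _ in range(spec.n_shards):
        shard = [
            link for link in ground_truth if rng.random() >= spec.missing_edge_prob
        ]
        shards.append(shard)

    return MappingWorld(
        spec=spec,
        datasources=datasources,
        entities=entities,
        entity_symbols=entity_symbols,
        ground_truth=ground_truth,
        shards=shards,
    )


def world_to_flatfile(world: MappingWorld, shard_index: int, path: str | Path) -> Path:
    """Write one shard as a tab-delimited mapping file.

    One row per link, filling exactly the two cells of the link's data
    sources, so reloading reproduces the shard link set exactly. The
    generation seed is recorded in a ``##`` comment header.
    """
    path = Path(path)
    columns = world.syscodes
    index = {c: i for i, c in enumerate(columns)}
    rows = []
    for left, right in sorted(world.shards[shard_index], key=lambda p: sorted(p)):
        a, b = sorted((left, right))
        cells = [""] * len(columns)
        cells[index[a.syscode]] = a.identifier
        cells[index[b.syscode]] = b.identifier
        rows.append("\t".join(cells))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"## synthetic mapping shard; seed={world.spec.seed}"
                 f" shard={shard_index}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(row + "\n")
    return path


def world_to_db(
    world: MappingWorld,
    shard_index: int,
    path: str | Path,
    with_symbols: bool = True,
) -> Path:
    """Write one shard as an embedded mapping database."""
    attributes = world.symbol_attributes() if with_symbols else None
    if attributes is not None:
        # only nodes that survive in this shard's links carry attributes
        present = {x for pair in world.shards[shard_index] for x in pair}
        attributes = {x: attrs for x, attrs in attributes.items() if x in present}
    datanodes, links, attr_records = records_from_links(
        world.shards[shard_index], attributes
    )
    species = "metabolites" if world.spec.entity_category == "metabolite" else "synthetic"
    return write_db(
        path,
        datanodes,
        links,
        attr_records,
        DbInfo(
            species_name=species,
            provenance=f"synthetic world seed={world.spec.seed} shard={shard_index}",
        ),
    )


def world_to_metabocards(world: MappingWorld, path: str | Path) -> Path:
    """Write the world's ground-truth entities as a metabolite card file.

    Cards force all-pairs linkage within an entity, so this emitter works
    from the ground truth (per-link dropout is not expressible in cards).
    Requires a metabolite-category world.
    """
    if world.spec.entity_category != "metabolite":
        raise InvalidSpecError("metabolite cards need a metabolite-category world")
    path = Path(path)
    blocks = [f"## synthetic metabolite cards; seed={world.spec.seed}"]
    for xrefs, symbols in zip(world.entities, world.entity_symbols):
        card = MetaboCard(
            primary_name=symbols[0],
            synonyms=symbols[1:],
            identifiers={x.syscode: x.identifier for x in xrefs},
        )
        blocks.append(format_metabocard(card))
    path.write_text("\n".join(blocks) + "\n", encoding="utf-8")
    return path


def world_to_cards(world: MappingWorld) -> list[MetaboCard]:
    """The world's entities as in-memory metabolite cards (ground truth)."""
    return [
        MetaboCard(
            primary_name=symbols[0],
            synonyms=symbols[1:],
            identifiers={x.syscode: x.identifier for x in xrefs},
        )
        for xrefs, symbols in zip(world.entities, world.entity_symbols)
    ]
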