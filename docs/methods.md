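# Methods

## Model

The package treats identifier mapping as a relation over *global
identifiers* (Xrefs): pairs of a data source and an internal identifier.
Equality of Xrefs is by the `(syscode, identifier)` pair; identifiers are
opaque tokens compared case-sensitively and whitespace-exactly, because a
mapping service's identifiers are keys, not names. Human-readable symbols
(gene names, metabolite names, synonyms) are deliberately *not* part of
identity — they are ambiguous and unstable — and live as `Symbol`
attributes, searchable but never used as keys.

A *mapper* is anything answering the uniform contract (`map_id`,
`map_ids`, `free_search`, `capabilities`, `get_attributes`). Backends are
selected by a connection string `"<provider>:<params>"` split at the first
colon; providers self-register in a dispatch table at import time. A
closed handle fails loudly (`ClosedHandleError`) rather than returning
empty results, so a dropped connection cannot silently empty a pipeline.

### MIRIAM URNs

Serialisation is `"urn:miriam:" + namespace + ":" + identifier`; parsing
takes the namespace as the token between the second and third colon and
the identifier as *everything after the third colon*, so identifiers that
themselves contain colons (`CHEBI:17234`) round-trip. Namespace tokens are
required lowercase. The shipped data-source registry
(`src/xrefbridge/data/datasources.tsv`) is an editable TSV covering the
common gene/protein/probe/metabolite databases with plausible namespace
tokens and link-out templates; it is a practical default, not a mirror of
any registry release. Link-out URLs substitute the identifier into a
`$id` template (exactly one occurrence enforced) with percent-encoding.

## Backends

**Flat files.** One column per data source, one row per entity; a row is
an equivalence statement, so every pair of non-empty cells becomes one
symmetric link. Dialect choices: TAB delimiter, no quoting, cells trimmed;
first line is a syscode header (headerless files take a positional column
assignment); a cell may carry comma-separated identifiers which expand
combinatorially; `##` lines are comments (fixture emitters record their
generation seed there); duplicate rows deduplicate. Mapping direction is
not meaningful for co-reference, so flat-file links are symmetric.

**Embedded database.** Three logical tables (`datanode`, `link`,
`attribute`) plus a `dbinfo` provenance row (schema version, species or
`"metabolites"`, build timestamp, note). The logical schema is the
contract; the physical engine is SQLite, chosen because it gives
single-file databases that are trivially copied and frozen. Links are
stored once and queried bidirectionally through indexes on both endpoint
columns; symmetric semantics match the flat-file backend, and the two
backends are required (and tested) to answer identical queries when
loaded from the same link set. Writes are atomic: the database is built
in a temporary file and `os.replace`d into place, and referential
integrity (every link endpoint and attribute owner present in
`datanode`) is validated before any byte is written. Schema version
mismatch is a hard error, never a silent fallback.

## Transitive stacking

A stack holds an ordered member list, a `transitive` flag and
`max_degree` ∈ {1, 2, 3} (default 2 — the custom-annotation scenario
needs exactly two steps, and a third degree is available for chains such
as gene → transcript → protein). Non-transitive mode returns the union of
member answers. Transitive mode runs a breadth-first frontier expansion:
at each of ≤ `max_degree` rounds, every frontier Xref is expanded through
*every* member (steps are not member-alternating), a visited set
guarantees each Xref expands once (hence termination on cyclic mapping
graphs), and the query itself is excluded from the result. Intermediate
Xrefs may belong to any data source, including ones not requested as
targets — they are traversal-only; the target filter applies to the final
result. No restriction to designated "bridge" sources is imposed.
Results are sets; a display-only provenance flag (`direct`/`inferred`)
is available via `map_id_with_provenance` but never affects membership.
No scoring or conflict resolution between disagreeing members is
attempted.

Correctness is checked against an independent oracle,
`transitive_closure_oracle`, which pools all member links into one
undirected networkx graph and takes the shortest-path-bounded reachable
set — a different algorithm and code path from the stack's traversal.
Capability introspection composes at the data-source level: s→t is
supported transitively if a chain of ≤ `max_degree` member-supported
steps connects them. Because local backends answer bidirectionally, a
backend's capability sources and targets are both "all data sources
touching any link"; this keeps the capability/`map_id` consistency
invariant exact.

## Metabolite card ETL

The card dialect is defined by this package (`#BEGIN_METABOCARD <id>`
delimiter carrying the accession, `# field:` headers, one value per
line, `#END_METABOCARD` terminator): a minimal flat-text shape for
"name + synonyms + one cross-reference per chemical database". The
accession is itself a first-class identifier node, so a card with a
single external reference still contributes one mapping. Within a card,
all identifiers are co-referent → all pairs linked (k·(k−1)/2 stored
links); name and synonyms become `Symbol` attributes on every identifier
node of the card. Cross-card transitivity is *not* applied at build time
— co-reference is asserted per card only; cross-card chains arise only
through stacking if the user opts in. An identifier claimed by two cards
is logged as a conflict and both cards' links and symbols are kept,
since neither claim can be adjudicated locally. Parsing real current
HMDB releases (XML) is out of scope.

## REST layer

Routes follow `/{organism}/{command}/{args...}` with commands `search`
(the canonical route shape), and `xrefs` and `properties` as documented
extensions using the same grammar. Bodies are
`identifier<TAB>data source full name` rows, sorted by
(full name, identifier), `text/plain; charset=utf-8`, `\n`-joined with no
trailing newline — fixed so responses are byte-deterministic. An empty
result is `200` with an empty body ("no mapping" is an answer); `404` is
reserved for an unknown organism and `400` for malformed requests or
unknown syscodes. URL segments are percent-decoded before lookup. The
application is a plain stdlib WSGI callable served by `wsgiref` from the
CLI and invoked in-process (no sockets) by the tests, which assert that
parsing a body reproduces the corresponding library call exactly — the
HTTP layer adds nothing.

## Agreement statistics

`agreement_stats` feeds one query set to ≥ 2 labelled mappers and
reports, per mapper, the fraction of queries with a non-empty answer,
plus the fraction of queries for which *all* mappers return the *same
non-empty set* (set equality after deduplication). An all-empty query
counts as unmapped, not as agreement, which makes
`identical_fraction ≤ min(mapped_fraction)` an invariant rather than an
observation. Set equality (not top-hit equality) is used because results
are sets throughout the package. `sample_queries` draws uniformly
without replacement from a backend's identifiers of one data source,
reproducibly per seed. The comparison runs against local mappers built
from synthetic shards; benchmarking live third-party services is out of
scope.

## Synthetic worlds

The generator emulates the population every mapping service samples
from: `n_entities` ground-truth entities each carrying one identifier in
a random subset of `n_datasources` sources (subset size drawn from
`xrefs_per_entity_range`); ground truth links an entity's identifiers
pairwise; each of `n_shards` services keeps each link independently with
probability `1 − missing_edge_prob`. Defaults (4 sources, 50 entities,
2–4 identifiers per entity, 10% dropout, 2 shards) are sized so that
exhaustive per-node oracle checks stay fast while graphs are large
enough to contain chains, forks and disagreements. Data sources are
drawn from the shipped registry (gene-category codes for gene worlds,
metabolite codes for metabolite worlds). One identifier per entity per
source keeps ground truth unambiguous for oracle tests; identifier
strings are cosmetic. Everything derives from a single named
`random.Random(seed)`, and emitters write byte-identical text for
identical (spec, seed), recording the seed in `##` headers (flat files,
card files) or the `dbinfo` provenance note (databases).

What the worlds do *not* emulate: paralog/transcript multiplicity
(set-valued many-to-many mapping beyond entity co-reference),
systematically biased rather than independent coverage gaps, identifier
format errors, and retired/merged identifiers. Passing tests therefore
demonstrate contract correctness and algorithmic exactness on clean
co-reference graphs, not robustness to dirty real-world annotation.

## Evaluation script

`scripts/acceptance.py` recomputes every headline quantity from scratch
per run: oracle agreement over 50 random worlds (all nodes × degrees
1–3), union exactness over 50 worlds, backend interchangeability and
REST fidelity on ~40-entity worlds, 50 database round-trips, a 25-card
metabolite ETL, and a four-service comparison over 1000 probe queries
sampled from a 2500-entity world with 5% per-service link dropout.
These sizes keep a full run around one to two minutes on one CPU while
exercising every layer; all randomness flows from `--seed`.

## Known limitations

- Mapping is symmetric co-reference; directional or typed relations
  (gene → transcript → protein as *typed* edges) are not modelled, only
  reachable through transitive chains.
- Transitive inference is unrestricted traversal; with noisy members it
  can propagate a wrong link (no confidence model by design).
- `free_search` over stacks unions member results before applying the
  limit, which is exact but not streamed; very large stacks pay for it.
- The REST service is a development-grade single-threaded server; no
  TLS, authentication or rate limiting.
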