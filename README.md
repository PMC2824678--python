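# xrefbridge

Uniform identifier cross-reference mapping for genes, proteins and
metabolites.

## The problem

Integrating experimental data — merging interaction networks, painting
microarray measurements onto pathways, combining transcriptomics with
metabolomics — almost always starts with deciding which identifiers in one
dataset correspond to which identifiers in another. Many mapping resources
exist (large gene databases, curated chemical registries, lab-specific
annotation tables), each with its own coverage, freshness and access mode.
Tools hard-wired to a single resource are expensive to re-point, and no
single resource covers everything.

`xrefbridge` puts a standard interface between tools and mapping services.
Every backend — a tab-delimited annotation file, a single-file embedded
relational database, a stack of other mappers — answers the same contract,
so switching services is a connection-string change, and services can be
*stacked*: combined as a union, or with **transitive inference** of
indirect mappings. It is a library for bioinformatics tool developers,
with a thin `xrefbridge` command-line front and a REST service for
non-Python callers.

## Core model

* A **data source** is a database of biological entities indexed by unique
  identifiers (Ensembl, UniProt, ChEBI, ...), described by a registry
  record with a short *syscode* (`En`, `S`, `Ce`, ...).
* An internal identifier is only meaningful within one data source; the
  unit of every query and result is the **Xref** — the pair
  (data source, identifier) — serialised as a MIRIAM URN,
  e.g. `urn:miriam:uniprot:P62158`.
* A **mapper** translates Xrefs: `map_id(x, targets)` returns the set of
  Xrefs co-referent with `x`, `free_search(text)` finds identifiers by
  name or symbol, and `capabilities()` reports which source→target pairs
  the backend supports.
* **Stacking** presents several mappers as one. In transitive mode, if one
  member maps custom probe → Entrez Gene and another maps
  Entrez Gene → Ensembl, the probe → Ensembl mapping is inferred
  (second/third-degree chains, bounded by `max_degree`).
* The embedded database uses a three-table schema — `datanode`
  (identifier, syscode), `link` (left/right endpoint pairs, stored once,
  queried bidirectionally) and `attribute` (symbols and other annotation)
  — in a single SQLite file (`.xdb`) that can be copied around and freezes
  a mapping snapshot for reproducible analyses.
* The metabolite ETL parses flat-text metabolite cards (name, synonyms,
  one cross-reference per chemical database) and links all identifiers on
  a card pairwise: k identifiers → k·(k−1)/2 links.

## Worked example

A lab has a custom chip whose annotation file maps each probe to one
Entrez Gene identifier. Stacked transitively with a gene database that
maps Ensembl ↔ Entrez Gene, the probe resolves to Ensembl even though no
single source stores that link:

```python
from pathlib import Path
from xrefbridge import DataSource, MemoryLinkMapper, default_registry, load_flatfile, stack

registry = default_registry()
registry.register(DataSource("Zz", "MyChip", entity_category="probe"))

Path("custom_probes.tsv").write_text("Zz\tL\nPROBE_0007\t3643\n")
annotation = load_flatfile("custom_probes.tsv", registry)

gene_db = MemoryLinkMapper(
    [(registry.xref("En", "ENSG00000171105"), registry.xref("L", "3643"))]
)

combined = stack([annotation, gene_db], transitive=True, max_degree=2)
probe = registry.xref("Zz", "PROBE_0007")
for x in sorted(combined.map_id(probe)):
    print(f"{x.identifier}\t{x.datasource.full_name}")
```

prints

```
ENSG00000171105	Ensembl
3643	Entrez Gene
```

`3643` is the direct mapping stored in the annotation file; the Ensembl
row is the inferred second-degree mapping. Global identifiers and
link-outs come straight off the Xref:

```python
>>> registry.xref("En", "ENSG00000171105").to_miriam_urn()
'urn:miriam:ensembl:ENSG00000171105'
>>> registry.xref("En", "ENSG00000171105").link_out_url()
'https://www.ensembl.org/id/ENSG00000171105'
```

The same queries are available from the shell
(`xrefbridge map --connect idmapper-text:custom_probes.tsv ...`) and over
HTTP (`GET /Human/search/ENSG00000171105` returns tab-delimited plain
text; see `xrefbridge serve`).

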