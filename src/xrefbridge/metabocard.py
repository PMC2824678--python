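"""Metabolite-card ETL: parse card files and build a metabolite database.

A metabolite card is a flat-text record for one compound, carrying its
official name, synonyms, and at most one cross-reference per external
chemical database (CAS, ChEBI, PubChem Compound, KEGG Compound) next to its
own HMDB-style accession. All identifiers on one card refer to the same
compound, so the card asserts symmetry and transitivity *within itself*:
the built database links every pair of the card's identifiers
(k identifiers → k·(k−1)/2 stored links, queried bidirectionally). The
official name and every synonym are stored as ``Symbol`` attributes on each
of the card's identifier nodes, which makes them findable via free search.

Card dialect (defined and documented by this package; see docs/methods.md):

.. code-block:: text

    #BEGIN_METABOCARD HMDB00001
    # name:
    1-Methylhistidine
    # synonyms:
    1-MHis
    # cas_registry_number:
    332-80-9
    # chebi_id:
    CHEBI:50599
    #END_METABOCARD

Unknown ``# field:`` blocks are ignored with a logged warning. Cross-card
transitivity is *not* applied at build time; chains across cards arise only
through stacking, if the user opts in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import DataSourceRegistry, Xref, default_registry
from .errors import MetaboCardParseError
from .store import (
    AttributeRecord,
    DbInfo,
    DataNodeRecord,
    LinkRecord,
    SYMBOL_ATTR,
    write_db,
)

logger = logging.getLogger(__name__)

CARD_BEGIN = "#BEGIN_METABOCARD"
CARD_END = "#END_METABOCARD"

# field-name → registry syscode for the external cross-reference blocks
FIELD_SYSCODES = {
    "hmdb_id": "Ch",
    "cas_registry_number": "Ca",
    "chebi_id": "Ce",
    "pubchem_compound_id": "Cp",
    "kegg_compound_id": "Ck",
}
NAME_FIELD = "name"
SYNONYM_FIELD = "synonyms"


@dataclass
class MetaboCard:
    """One parsed metabolite card."""

    primary_name: str
    synonyms: list[str] = field(default_factory=list)
    identifiers: dict[str, str] = field(default_factory=dict)  # syscode → identifier

    def __post_init__(self) -> None:
        if not self.primary_name:
            raise MetaboCardParseError("card primary name must be non-empty")

    @property
    def has_links(self) -> bool:
        """Whether the card yields any mapping (needs >= 2 identifiers)."""
        return len(self.identifiers) >= 2

    @property
    def n_links(self) -> int:
        """Stored link count for this card: k·(k−1)/2 for k identifiers."""
        k = len(self.identifiers)
        return k * (k - 1) // 2

    @property
    def symbols(self) -> list[str]:
        return [self.primary_name, *self.synonyms]


def format_metabocard(card: MetaboCard) -> str:
    """Serialise a card in the dialect :func:`parse_metabocard_file` reads."""
    accession = card.identifiers.get("Ch", "")
    lines = [f"{CARD_BEGIN} {accession}".rstrip()]
    lines.append(f"# {NAME_FIELD}:")
    lines.append(card.primary_name)
    if card.synonyms:
        lines.append(f"# {SYNONYM_FIELD}:")
        lines.extend(card.synonyms)
    for fieldname, syscode in FIELD_SYSCODES.items():
        if syscode == "Ch":
            continue  # accession rides on the delimiter line
        if syscode in card.identifiers:
            lines.append(f"# {fieldname}:")
            lines.append(card.identifiers[syscode])
    lines.append(CARD_END)
    return "\n".join(lines)


def parse_metabocard_file(path: str | Path) -> list[MetaboCard]:
    """Parse a card file into a list of :class:`MetaboCard`.

    Cards with no identifiers at all are skipped with a logged warning;
    unknown field blocks are ignored with a logged warning.

    Raises
    ------
    MetaboCardParseError
        Empty file, no card delimiter, or a card without a name.
    """
    cards, _ = parse_metabocard_file_with_stats(path)
    return cards


def parse_metabocard_file_with_stats(path: str | Path) -> tuple[list[MetaboCard], int]:
    """As :func:`parse_metabocard_file`, also returning the skipped count."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if CARD_BEGIN not in text:
        raise MetaboCardParseError(f"{path}: no {CARD_BEGIN} delimiter found")

    cards: list[MetaboCard] = []
    n_skipped = 0
    block: Optional[dict[str, list[str]]] = None
    current_field: Optional[str] = None
    accession: Optional[str] = None

    def finish() -> None:
        nonlocal n_skipped
        if block is None:
            return
        names = block.get(NAME_FIELD, [])
        if not names:
            raise MetaboCardParseError(f"{path}: card {accession or '?'} has no name")
        identifiers: dict[str, str] = {}
        if accession:
            identifiers["Ch"] = accession
        for fieldname, syscode in FIELD_SYSCODES.items():
            values = block.get(fieldname, [])
            if len(values) > 1:
                raise MetaboCardParseError(
                    f"{path}: card {accession or '?'} has {len(values)} values"
                    f" for {fieldname}, at most one allowed"
                )
            if values:
                identifiers[syscode] = values[0]
        if not identifiers:
            logger.warning("skipping card %r: no identifiers", names[0])
            n_skipped += 1
            return
        cards.append(
            MetaboCard(
                primary_name=names[0],
                synonyms=block.get(SYNONYM_FIELD, []),
                identifiers=identifiers,
            )
        )

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("##"):  # "##" lines are comments
            continue
        if line.startswith(CARD_BEGIN):
            finish()
            block = {}
            current_field = None
            accession = line[len(CARD_BEGIN):].strip() or None
        elif line == CARD_END:
            finish()
            block = None
            current_field = None
            accession = None
        elif line.startswith("# ") and line.endswith(":"):
            if block is None:
                raise MetaboCardParseError(f"{path}: field header outside a card: {line!r}")
            current_field = line[2:-1].strip()
            if current_field not in FIELD_SYSCODES and current_field not in (
                NAME_FIELD,
                SYNONYM_FIELD,
            ):
                logger.warning("ignoring unknown card field %r", current_field)
            block.setdefault(current_field, [])
        else:
            if block is None or current_field is None:
                raise MetaboCardParseError(f"{path}: stray value line: {line!r}")
            block[current_field].append(line)
    finish()
    return cards, n_skipped


def cards_to_db(
    cards: list[MetaboCard],
    out_path: str | Path,
    registry: Optional[DataSourceRegistry] = None,
    provenance: str = "built from metabolite cards",
) -> Path:
    """Build a metabolite mapping database from parsed cards.

    For each card every unordered pair of its identifiers becomes one
    stored link; every identifier node receives the card's name and
    synonyms as ``Symbol`` attributes. An identifier claimed by two
    different cards is logged as a conflict and both cards' links and
    symbols are kept.
    """
    if registry is None:
        registry = default_registry()
    nodes: dict[tuple[str, str], DataNodeRecord] = {}
    links: dict[tuple, LinkRecord] = {}
    attributes: list[AttributeRecord] = []
    claimed: dict[tuple[str, str], str] = {}

    for card in cards:
        xrefs = sorted(
            Xref(registry.by_syscode(code), ident) for code, ident in card.identifiers.items()
        )
        for x in xrefs:
            key = (x.identifier, x.syscode)
            prior = claimed.get(key)
            if prior is not None and prior != card.primary_name:
                logger.warning(
                    "identifier %s:%s claimed by both %r and %r; keeping both",
                    x.syscode, x.identifier, prior, card.primary_name,
                )
            claimed.setdefault(key, card.primary_name)
            nodes.setdefault(key, DataNodeRecord(x.identifier, x.syscode))
            for symbol in card.symbols:
                attributes.append(
                    AttributeRecord(x.identifier, x.syscode, SYMBOL_ATTR, symbol)
                )
        for i in range(len(xrefs)):
            for j in range(i + 1, len(xrefs)):
                a, b = xrefs[i], xrefs[j]
                links.setdefault(
                    (a.identifier, a.syscode, b.identifier, b.syscode),
                    LinkRecord(a.identifier, a.syscode, b.identifier, b.syscode),
                )

    return write_db(
        out_path,
        datanodes=list(nodes.values()),
        links=list(links.values()),
        attributes=attributes,
        dbinfo=DbInfo(species_name="metabolites", provenance=provenance),
    )
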