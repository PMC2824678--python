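"""Cross-service agreement statistics.

Because every backend answers the same contract, mapping services can be
compared programmatically: feed the same query set to several mappers and
measure (a) what fraction of queries each service maps at all, and (b) for
what fraction of queries *every* service returns the same non-empty result
set. An all-empty query counts as unmapped, not as agreement, so the
identical fraction is always bounded by the smallest mapped fraction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import DataSource, Xref
from .errors import InvalidInputError
from .mapper import IDMapper


@dataclass(frozen=True)
class QueryDetail:
    """Per-query record: each mapper's result set and the agreement flag."""

    query: Xref
    results: dict[str, frozenset[Xref]]  # mapper label → result set
    identical: bool


@dataclass(frozen=True)
class AgreementReport:
    per_mapper_mapped_fraction: dict[str, float]
    identical_fraction: float
    n_queries: int
    details: tuple[QueryDetail, ...]

    @property
    def min_mapped_fraction(self) -> float:
        return min(self.per_mapper_mapped_fraction.values())

    def summary_rows(self) -> list[str]:
        """Tab-delimited summary lines for display."""
        rows = [f"n_queries\t{self.n_queries}"]
        for label in sorted(self.per_mapper_mapped_fraction):
            rows.append(
                f"mapped_fraction\t{label}\t{self.per_mapper_mapped_fraction[label]:.4f}"
            )
        rows.append(f"identical_fraction\t{self.identical_fraction:.4f}")
        return rows


def agreement_stats(
    mappers: Sequence[tuple[str, IDMapper]],
    queries: Sequence[Xref],
    targets: frozenset[DataSource] = frozenset(),
) -> AgreementReport:
    """Coverage and identical-result fractions over a query set.

    Parameters
    ----------
    mappers:
        ``(label, handle)`` pairs; at least two.
    queries:
        Query Xrefs; at least one. Order does not affect the fractions.
    targets:
        Optional restriction applied to every ``map_id`` call.

    Returns
    -------
    AgreementReport
        ``mapped_fraction(m)`` = fraction of queries for which mapper ``m``
        returns a non-empty set; ``identical_fraction`` = fraction of
        queries for which all mappers return the same non-empty set.
    """
    if len(mappers) < 2:
        raise InvalidInputError("agreement_stats needs at least two mappers")
    if not queries:
        raise InvalidInputError("agreement_stats needs at least one query")
    labels = [label for label, _ in mappers]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("mapper labels must be unique")

    mapped_counts = dict.fromkeys(labels, 0)
    identical_count = 0
    details: list[QueryDetail] = []
    for q in queries:
        results = {label: handle.map_id(q, targets) for label, handle in mappers}
        for label, result in results.items():
            if result:
                mapped_counts[label] += 1
        sets = list(results.values())
        identical = bool(sets[0]) and all(s == sets[0] for s in sets[1:])
        if identical:
            identical_count += 1
        details.append(QueryDetail(query=q, results=results, identical=identical))

    n = len(queries)
    return AgreementReport(
        per_mapper_mapped_fraction={label: mapped_counts[label] / n for label in labels},
        identical_fraction=identical_count / n,
        n_queries=n,
        details=tuple(details),
    )


def sample_queries(
    handle: IDMapper,
    datasource: DataSource,
    n: int,
    seed: int,
) -> list[Xref]:
    """Draw ``n`` distinct query Xrefs of one data source from a mapper.

    Sampling is uniform without replacement over the backend's identifiers
    for ``datasource`` and reproducible for a fixed ``seed``.

    Raises
    ------
    InvalidInputError
        ``n`` exceeds the available population, or the data source is not
        present in the backend at all.
    """
    population = sorted(handle.iter_xrefs(datasource))
    if not population:
        raise InvalidInputError(
            f"data source {datasource.full_name!r} has no identifiers in this backend"
        )
    if n > len(population):
        raise InvalidInputError(
            f"requested {n} queries but only {len(population)} identifiers available"
        )
    return random.Random(seed).sample(population, n)
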