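"""Benchmark predicted phenotypes against a curated reference snapshot.

Comparisons happen at the strain level through exact genome-accession
matches.  A strain counts as concordant for a reference phenotype when any
of its predicted terms contains the searched pattern (case-insensitive
substring, which also covers truncated/prefix patterns such as "anaerob"),
and as conflicting when a predicted term matches a conflict pattern while
none matches the searched one.  Strains matching neither are excluded from
the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    category: str  # PHENOTYPE | ISOLATE | MEDIUM
    value: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")


@dataclass
class BenchmarkResult:
    reference_phenotype: str
    searched_pattern: str
    concordant: int
    conflicting: int

    @property
    def n(self) -> int:
        return self.concordant + self.conflicting

    @property
    def accuracy(self) -> float:
        return self.concordant / self.n if self.n else float("nan")


#: Documented default conflict pairs (symmetric closure applied at load).
DEFAULT_CONFLICTS: dict[str, tuple[str, ...]] = {
    "gram negative": ("gram positive",),
    "gram positive": ("gram negative",),
    "aerobic": ("anaerobic",),
    "anaerobic": ("aerobic",),
    "motile": ("non motile",),
    "non motile": ("motile",),
    "thermophilic": ("psychrophilic",),
    "psychrophilic": ("thermophilic",),
}


def symmetric_conflicts(conflicts: dict[str, tuple[str, ...]]) -> dict[str, set[str]]:
    """Symmetric closure of a pattern -> conflicting-patterns table."""
    table: dict[str, set[str]] = {}
    for a, bs in conflicts.items():
        for b in bs:
            table.setdefault(a.casefold(), set()).add(b.casefold())
            table.setdefault(b.casefold(), set()).add(a.casefold())
    return table


def _matches(terms: list[str], pattern: str) -> bool:
    p = pattern.casefold()
    return any(p in t.casefold() for t in terms)


def match_predictions(
    predictions: dict[str, list[str]],
    reference: list[ReferenceRecord],
    conflicts: dict[str, tuple[str, ...]] | None = None,
    patterns: dict[str, str] | None = None,
) -> list[BenchmarkResult]:
    """Score predicted terms per accession against the reference snapshot.

    Parameters
    ----------
    predictions
        Genome accession -> list of predicted entity terms.
    reference
        Curated records; one row per (accession, phenotype value).
    conflicts
        Pattern -> conflicting patterns (made symmetric); defaults to
        :data:`DEFAULT_CONFLICTS`.  Phenotypes without a conflict entry are
        scored on overlap only and flagged in the log.
    patterns
        Optional reference value -> searched pattern map; by default the
        reference value itself is the pattern.
    """
    conflict_table = symmetric_conflicts(
        DEFAULT_CONFLICTS if conflicts is None else conflicts
    )
    patterns = patterns or {}
    by_value: dict[str, list[str]] = {}
    for rec in reference:
        by_value.setdefault(rec.value, []).append(rec.accession)
    results = []
    for value in sorted(by_value):
        pattern = patterns.get(value, value)
        conf_patterns = conflict_table.get(pattern.casefold(), set())
        if not conf_patterns:
            logger.info("no conflict entry for %r; scoring on overlap only", value)
        concordant = conflicting = 0
        for acc in by_value[value]:
            terms = predictions.get(acc, [])
            if _matches(terms, pattern):
                concordant += 1
            elif any(_matches(terms, cp) for cp in conf_patterns):
                conflicting += 1
        if concordant + conflicting:
            results.append(BenchmarkResult(value, pattern, concordant, conflicting))
    return results
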