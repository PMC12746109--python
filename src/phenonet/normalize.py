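"""Strain-term normalization against a canonical catalog and term-variant clustering.

Matching is a two-stage edit-distance procedure: an abbreviation-aware local
(substring-fit) stage for partial strain names, then a full normalized
Levenshtein stage for complete names.  Thresholds are engineering defaults,
exposed in :class:`MatchThresholds`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from phenonet.corpus import replace_hyphens

_WS_RE = re.compile(r"\s+")
_ABBREV_RE = re.compile(r"^[A-Za-z]{1,2}\.$")


@dataclass(frozen=True)
class MatchThresholds:
    #: minimum local (substring-fit) similarity accepted in stage 1
    tau_local: float = 0.90
    #: maximum normalized full Levenshtein distance accepted in stage 2
    tau_full: float = 0.10
    #: maximum normalized distance for single-linkage term clustering
    tau_cluster: float = 0.20


@dataclass(frozen=True)
class StrainCatalogEntry:
    canonical_id: str
    aliases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.aliases:
            raise ValueError("aliases must be non-empty")


@dataclass(frozen=True)
class MappingEntry:
    """Resolution of one term: target id (or None), distance, and match stage."""

    term: str
    canonical_id: str | None
    distance: float
    stage: str  # "local" | "full" | "none"


@dataclass
class TermCluster:
    members: dict[str, int]  # term -> occurrence count
    representative: str = field(init=False)

    def __post_init__(self) -> None:
        # highest occurrence count wins; ties break lexicographically
        self.representative = min(self.members, key=lambda t: (-self.members[t], t))


# ---------------------------------------------------------------------------
# Edit distances
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (insert/delete/substitute, all cost 1)."""
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    cur = np.empty(len(b) + 1, dtype=np.int64)
    for i, ca in enumerate(a, start=1):
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev, cur = cur, prev
    return int(prev[len(b)])


def normalized_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer length (0 for two empties)."""
    m = max(len(a), len(b))
    return levenshtein(a, b) / m if m else 0.0


def fitting_distance(needle: str, haystack: str) -> int:
    """Minimum edit distance between ``needle`` and any substring of ``haystack``.

    Standard fitting alignment: the first DP row is zero (free start anywhere
    in the haystack) and the result is the minimum over the last row (free
    end).
    """
    if not needle:
        return 0
    prev = np.zeros(len(haystack) + 1, dtype=np.int64)
    cur = np.empty(len(haystack) + 1, dtype=np.int64)
    for i, cn in enumerate(needle, start=1):
        cur[0] = i
        for j, ch in enumerate(haystack, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cn != ch))
        prev, cur = cur, prev
    return int(prev.min())


def local_similarity(term: str, alias: str) -> float:
    """Abbreviation-aware substring-fit similarity in [0, 1].

    The shorter string is fit inside the longer one; similarity is
    ``1 - d / len(shorter)``.  When one string opens with an abbreviated
    token ("E." style) whose letters prefix the other's first token, the full
    token is contracted to the abbreviation before alignment, so
    "E. coli MG1655" scores 1.0 against "Escherichia coli MG1655".
    """
    term, alias = _contract_abbreviation(term, alias)
    needle, haystack = (term, alias) if len(term) <= len(alias) else (alias, term)
    if not needle:
        return 0.0
    return 1.0 - fitting_distance(needle, haystack) / len(needle)


def _contract_abbreviation(a: str, b: str) -> tuple[str, str]:
    ta, tb = a.split(" ", 1), b.split(" ", 1)
    if _ABBREV_RE.match(ta[0]) and not _ABBREV_RE.match(tb[0]):
        if tb[0].lower().startswith(ta[0][:-1].lower()):
            b = " ".join([ta[0]] + tb[1:])
    elif _ABBREV_RE.match(tb[0]) and not _ABBREV_RE.match(ta[0]):
        if ta[0].lower().startswith(tb[0][:-1].lower()):
            a = " ".join([tb[0]] + ta[1:])
    return a, b


def preprocess(term: str) -> str:
    """Case-fold, collapse whitespace, and apply the corpus hyphen rule."""
    return _WS_RE.sub(" ", replace_hyphens(term)).strip().casefold()


# ---------------------------------------------------------------------------
# Catalog matching
# ---------------------------------------------------------------------------


def normalize_strain_term(
    term: str,
    catalog: list[StrainCatalogEntry],
    thresholds: MatchThresholds = MatchThresholds(),
    overrides: dict[str, str] | None = None,
) -> MappingEntry:
    """Resolve one STRAIN term to a canonical catalog identity.

    Stage 1 takes the best local (substring-fit) match over all aliases and
    accepts it when local similarity >= ``tau_local``; stage 2 falls back to
    the best full normalized Levenshtein match, accepted when the distance
    <= ``tau_full``; otherwise the term is left unmapped.  Ties break on
    smaller distance, then lexicographic canonical id.  ``overrides`` is an
    optional curated term -> term rewrite applied before matching.
    """
    if not term:
        raise ValueError("term must be non-empty")
    if not catalog:
        raise ValueError("catalog must be non-empty")
    raw = term
    if overrides:
        term = overrides.get(term, term)
    q = preprocess(term)

    best_local: tuple[float, str] | None = None  # (distance = 1 - sim, id)
    best_full: tuple[float, str] | None = None
    for entry in catalog:
        for alias in entry.aliases:
            p = preprocess(alias)
            d_local = 1.0 - local_similarity(q, p)
            cand = (d_local, entry.canonical_id)
            if best_local is None or cand < best_local:
                best_local = cand
            d_full = normalized_distance(q, p)
            cand = (d_full, entry.canonical_id)
            if best_full is None or cand < best_full:
                best_full = cand
    assert best_local is not None and best_full is not None
    if 1.0 - best_local[0] >= thresholds.tau_local:
        return MappingEntry(raw, best_local[1], best_local[0], "local")
    if best_full[0] <= thresholds.tau_full:
        return MappingEntry(raw, best_full[1], best_full[0], "full")
    return MappingEntry(raw, None, min(best_local[0], best_full[0]), "none")


def normalize_terms(
    terms, catalog, thresholds: MatchThresholds = MatchThresholds(), overrides=None
) -> dict[str, MappingEntry]:
    """Vectorized convenience wrapper over :func:`normalize_strain_term`."""
    return {
        t: normalize_strain_term(t, catalog, thresholds, overrides)
        for t in dict.fromkeys(terms)
    }


# ---------------------------------------------------------------------------
# Term-variant clustering
# ---------------------------------------------------------------------------


def _cluster_key(term: str) -> str:
    key = preprocess(term)
    if key.endswith("s") and len(key) > 3:  # crude plural stripping
        key = key[:-1]
    return key


def cluster_terms(
    counts: dict[str, int], tau_cluster: float = MatchThresholds().tau_cluster
) -> list[TermCluster]:
    """Single-linkage grouping of term variants (plurals, typos).

    Terms are compared after case-folding and plural-s stripping; two terms
    link when their normalized Levenshtein distance is <= ``tau_cluster``.
    The representative of each cluster is its highest-count member (ties
    break lexicographically).  Output order is deterministic (by
    representative) and independent of input order.
    """
    if any(c < 1 for c in counts.values()):
        raise ValueError("occurrence counts must be >= 1")
    terms = sorted(counts)
    keys = {t: _cluster_key(t) for t in terms}
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if normalized_distance(keys[a], keys[b]) <= tau_cluster:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, dict[str, int]] = {}
    for t in terms:
        groups.setdefault(find(t), {})[t] = counts[t]
    clusters = [TermCluster(members=g) for g in groups.values()]
    clusters.sort(key=lambda c: c.representative)
    return clusters
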